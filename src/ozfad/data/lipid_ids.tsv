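systematic_name	database_id	common_name
9Z-octadecenoic acid	LMFA01030002	oleic acid
9E-octadecenoic acid	LMFA01030073	elaidic acid
hexadecanoic acid	LMFA01010001	palmitic acid
octadecanoic acid	LMFA01010018	stearic acid
9Z-hexadecenoic acid	LMFA01030056	palmitoleic acid
6Z-hexadecenoic acid	LMFA01030057	sapienic acid
5Z,8Z,11Z-eicosatrienoic acid	LMFA01030158	mead acid
8Z,11Z,14Z-eicosatrienoic acid	LMFA01030158	dihomo-gamma-linolenic acid
5Z,11Z,14Z-eicosatrienoic acid	LMFA01030379	sciadonic acid
5Z,11Z-eicosadienoic acid	LMFA01030381	keteleeronic acid
4Z,7Z,10Z,13Z,16Z,19Z-docosahexaenoic acid	LMFA01030185	DHA
7Z,10Z,13Z,16Z,19Z-docosapentaenoic acid	LMFA01030166	DPA
5Z,8Z,11Z,14Z,17Z-eicosapentaenoic acid	LMFA01030759	EPA
9Z,12Z-octadecadienoic acid	LMFA01030120	linoleic acid
9Z,12Z,15Z-octadecatrienoic acid	LMFA01030152	alpha-linolenic acid
6Z,9Z,12Z-octadecatrienoic acid	LMFA01030141	gamma-linolenic acid
5Z,8Z,11Z,14Z-eicosatetraenoic acid	LMFA01030001	arachidonic acid
13Z-docosenoic acid	LMFA01030089	erucic acid
15Z-tetracosenoic acid	LMFA01030094	nervonic acid
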
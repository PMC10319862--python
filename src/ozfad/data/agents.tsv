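code	formula	charge
AMPP	C12H13N2	1
IAMP	C12H12IN2	1
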
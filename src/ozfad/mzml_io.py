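"""Centroided mzML reading and writing.

Profile-mode spectra are rejected since the whole pipeline operates on
centroid arrays. The reader handles the subset of mzML relevant here
(centroided MS1/MS2 spectra, 32/64-bit float arrays, zlib or no
compression); the writer emits a minimal but valid centroided document
(64-bit float arrays, no compression).
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from xml.sax.saxutils import quoteattr

import numpy as np

from .lcms import LcmsRun, RunFormatError, Spectrum

__all__ = ["read_run", "write_run"]


def _encode(array: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{array.size}d", *np.asarray(array, dtype=float))).decode()


_SPECTRUM_TEMPLATE = """\
   <spectrum index="{index}" id="scan={index}" defaultArrayLength="{n}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>
    <cvParam cvRef="MS" accession="{kind_acc}" name="{kind_name}" value=""/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
     <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
     <scan>
      <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
     </scan>
    </scanList>
{precursor}    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{mz_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{mz_b64}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{i_len}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{i_b64}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""

_PRECURSOR_TEMPLATE = """\
    <precursorList count="1">
     <precursor>
      <isolationWindow>
       <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{target:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      </isolationWindow>
      <selectedIonList count="1">
       <selectedIon>
        <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{target:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
       </selectedIon>
      </selectedIonList>
     </precursor>
    </precursorList>
"""


def write_run(run: LcmsRun, path) -> None:
    """Write a centroided run to mzML."""
    parts = []
    for i, s in enumerate(run.spectra):
        mz_b64 = _encode(s.mz)
        i_b64 = _encode(s.intensity)
        precursor = ""
        if s.ms_level == 2:
            precursor = _PRECURSOR_TEMPLATE.format(target=s.isolation_target)
        parts.append(
            _SPECTRUM_TEMPLATE.format(
                index=i,
                n=s.mz.size,
                level=s.ms_level,
                kind_acc="MS:1000579" if s.ms_level == 1 else "MS:1000580",
                kind_name="MS1 spectrum" if s.ms_level == 1 else "MSn spectrum",
                rt=s.rt,
                precursor=precursor,
                mz_len=len(mz_b64),
                mz_b64=mz_b64,
                i_len=len(i_b64),
                i_b64=i_b64,
            )
        )
    meta = " ".join(f"{k}={v}" for k, v in run.metadata.items())
    with open(path, "w") as fh:
        fh.write(
            '<?xml version="1.0" encoding="utf-8"?>\n'
            '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
            ' <cvList count="2">\n'
            '  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
            '  <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>\n'
            ' </cvList>\n'
            f' <run id={quoteattr(run.mode)} sampleRef={quoteattr(meta or "sample")}>\n'
            f'  <spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="dp">\n'
        )
        fh.writelines(parts)
        fh.write("  </spectrumList>\n </run>\n</mzML>\n")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict:
    out = {}
    for child in element.iter():
        if _local(child.tag) == "cvParam":
            out.setdefault(child.get("name"), child)
    return out


def _decode_array(bda_element) -> np.ndarray:
    params = _cv_params(bda_element)
    binary = None
    for child in bda_element:
        if _local(child.tag) == "binary":
            binary = child.text or ""
    raw = base64.b64decode(binary)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(element) -> Spectrum:
    params = _cv_params(element)
    if "profile spectrum" in params:
        raise RunFormatError(
            "profile-mode spectra are unsupported; centroid the data upstream"
        )
    level = int(params["ms level"].get("value"))
    rt = None
    target = None
    arrays = {}
    for sub in element.iter():
        tag = _local(sub.tag)
        if tag == "scan" and rt is None:
            for p in sub:
                if _local(p.tag) == "cvParam" and p.get("name") == "scan start time":
                    rt = float(p.get("value"))
                    if "second" in (p.get("unitName") or "minute"):
                        rt /= 60.0
        elif tag == "isolationWindow":
            for p in sub:
                if _local(p.tag) == "cvParam" and p.get("name") == "isolation window target m/z":
                    target = float(p.get("value"))
        elif tag == "binaryDataArray":
            sub_params = _cv_params(sub)
            key = "mz" if "m/z array" in sub_params else (
                "intensity" if "intensity array" in sub_params else None
            )
            if key:
                arrays[key] = _decode_array(sub)
    if level == 2 and target is None:
        raise RunFormatError("MS2 scan without an isolation window target in a DDA file")
    return Spectrum(
        rt=rt if rt is not None else 0.0,
        ms_level=level,
        mz=arrays.get("mz", np.empty(0)),
        intensity=arrays.get("intensity", np.empty(0)),
        isolation_target=target,
    )


def read_run(path, mode: str | None = None) -> LcmsRun:
    """Read a centroided mzML file.

    ``mode`` may be given by the caller; otherwise it is inferred from the MS
    levels present (any MS2 scan implies DDA, else DIA). Profile spectra and
    DDA MS2 scans without isolation windows are rejected.
    """
    spectra = []
    for _, element in ET.iterparse(str(path), events=("end",)):
        if _local(element.tag) == "spectrum":
            spectra.append(_parse_spectrum(element))
            element.clear()
    if mode is None:
        mode = "DDA" if any(s.ms_level == 2 for s in spectra) else "DIA"
    return LcmsRun(mode=mode, spectra=spectra)
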
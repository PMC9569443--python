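"""mzML input/output for targeted PRM runs.

Both directions are self-contained ElementTree implementations covering
the centroided-MSn subset this package needs: per-spectrum MS level, scan
start time (minute or second units), the selection path from the
precursor list (two-level precursor annotation for MS3) and 32/64-bit
float peak arrays, zlib-compressed or plain, base64-encoded.  Writing
emits 64-bit zlib arrays; read(write(run)) is exact, which the test suite
asserts.

Run metadata (sample id, loaded protein, spike amounts) travels in a JSON
sidecar next to the mzML file (``<stem>.meta.json``) so it survives tools
that rewrite mzML headers.
"""

from __future__ import annotations

import base64
import json
import struct
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .quant import PRMRun, RunMetadata, Scan

__all__ = ["write_mzml", "read_mzml", "write_run", "read_run", "meta_path"]

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession: str, name: str, value: str = "", **unit) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(unit)
    ET.SubElement(parent, "cvParam", attrs)


def _encode(arr: np.ndarray) -> str:
    raw = struct.pack(f"<{len(arr)}d", *map(float, arr))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _binary_array(parent, arr: np.ndarray, kind: str) -> None:
    b = ET.SubElement(parent, "binaryDataArray")
    _cv(b, "MS:1000523", "64-bit float")
    _cv(b, "MS:1000574", "zlib compression")
    if kind == "mz":
        _cv(b, "MS:1000514", "m/z array", unitCvRef="MS",
            unitAccession="MS:1000040", unitName="m/z")
    else:
        _cv(b, "MS:1000515", "intensity array", unitCvRef="MS",
            unitAccession="MS:1000131", unitName="number of detector counts")
    payload = _encode(arr)
    b.set("encodedLength", str(len(payload)))
    ET.SubElement(b, "binary").text = payload


def write_mzml(run: PRMRun, path: str | Path) -> None:
    """Write a PRM run as centroided mzML."""
    path = Path(path)
    root = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0"})
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cvlist, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cvlist, "cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(soft, "software", {"id": "laminprm", "version": "0.1.0"})
    iconf = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(iconf, "instrumentConfiguration", {"id": "IC1"})
    dplist = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dplist, "dataProcessing", {"id": "dp1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "laminprm"})
    _cv(pm, "MS:1000544", "Conversion to mzML")
    runel = ET.SubElement(root, "run", {
        "id": run.metadata.run_id or "run",
        "defaultInstrumentConfigurationRef": "IC1"})
    slist = ET.SubElement(runel, "spectrumList", {
        "count": str(len(run.scans)), "defaultDataProcessingRef": "dp1"})
    for i, scan in enumerate(run.scans):
        sp = ET.SubElement(slist, "spectrum", {
            "index": str(i), "id": f"scan={i + 1}",
            "defaultArrayLength": str(len(scan.mz))})
        level = "2" if scan.stage == "MS2" else "3"
        _cv(sp, "MS:1000511", "ms level", level)
        _cv(sp, "MS:1000580", "MSn spectrum")
        _cv(sp, "MS:1000127", "centroid spectrum")
        scanlist = ET.SubElement(sp, "scanList", {"count": "1"})
        _cv(scanlist, "MS:1000795", "no combination")
        scel = ET.SubElement(scanlist, "scan")
        _cv(scel, "MS:1000016", "scan start time", repr(scan.rt),
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute")
        plist = ET.SubElement(sp, "precursorList",
                              {"count": str(len(scan.selection_path))})
        for sel_mz in scan.selection_path:
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", repr(sel_mz),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            sil = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            si = ET.SubElement(sil, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", repr(sel_mz),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        blist = ET.SubElement(sp, "binaryDataArrayList", {"count": "2"})
        _binary_array(blist, scan.mz, "mz")
        _binary_array(blist, scan.intensity, "intensity")
    tree = ET.ElementTree(root)
    ET.indent(tree, space=" ")
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> dict[str, tuple[str, dict]]:
    out = {}
    for child in elem:
        if _local(child.tag) == "cvParam":
            out[child.get("accession")] = (child.get("value", ""), child.attrib)
    return out


def _decode_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    payload = ""
    for child in bda:
        if _local(child.tag) == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(sp) -> Scan:
    params = _cv_params(sp)
    if "MS:1000511" not in params:
        raise ValueError(f"spectrum {sp.get('id')!r} lacks an ms level")
    level = int(params["MS:1000511"][0])
    stage = "MS2" if level == 2 else "MS3"
    rt = 0.0
    sel: list[float] = []
    mz = inten = None
    for node in sp.iter():
        tag = _local(node.tag)
        if tag == "scan":
            p = _cv_params(node)
            if "MS:1000016" in p:  # scan start time
                value, attrs = p["MS:1000016"]
                rt = float(value)
                if attrs.get("unitName", "minute") == "second":
                    rt /= 60.0
        elif tag == "selectedIon":
            p = _cv_params(node)
            if "MS:1000744" in p:  # selected ion m/z
                sel.append(float(p["MS:1000744"][0]))
        elif tag == "binaryDataArray":
            p = _cv_params(node)
            if "MS:1000514" in p:
                mz = _decode_array(node)
            elif "MS:1000515" in p:
                inten = _decode_array(node)
    if mz is None or inten is None:
        raise ValueError(f"spectrum {sp.get('id')!r} lacks peak arrays")
    order = np.argsort(mz, kind="stable")
    return Scan(rt, stage, tuple(sel), mz[order], inten[order])


def read_mzml(path: str | Path, metadata: RunMetadata | None = None) -> PRMRun:
    """Read centroided targeted scans from mzML into a :class:`PRMRun`.

    The selection path is assembled from the precursor list in document
    order (one entry for MS2 scans, two for MS3).  When ``metadata`` is not
    given, the JSON sidecar is loaded if present.
    """
    path = Path(path)
    scans = []
    for _event, elem in ET.iterparse(str(path), events=("end",)):
        if _local(elem.tag) == "spectrum":
            scans.append(_parse_spectrum(elem))
            elem.clear()
    scans.sort(key=lambda s: s.rt)
    if metadata is None:
        mp = meta_path(path)
        metadata = _read_meta(mp) if mp.exists() else RunMetadata(run_id=path.stem)
    return PRMRun(scans, metadata)


def meta_path(mzml_path: str | Path) -> Path:
    return Path(mzml_path).with_suffix(".meta.json")


def _read_meta(path: Path) -> RunMetadata:
    d = json.loads(path.read_text())
    return RunMetadata(
        run_id=d.get("run_id", ""),
        sample_id=d.get("sample_id", ""),
        protein_ug=d.get("protein_ug"),
        spike_fmol=d.get("spike_fmol", {}),
    )


def write_run(run: PRMRun, path: str | Path) -> None:
    """Write the mzML file plus its metadata sidecar."""
    path = Path(path)
    write_mzml(run, path)
    meta = {
        "run_id": run.metadata.run_id,
        "sample_id": run.metadata.sample_id,
        "protein_ug": run.metadata.protein_ug,
        "spike_fmol": run.metadata.spike_fmol,
    }
    meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_run(path: str | Path) -> PRMRun:
    return read_mzml(path)
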
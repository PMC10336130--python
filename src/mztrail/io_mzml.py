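"""Reading and writing centroided mzML.

The pipeline consumes centroided MS1 data only. Profile-mode spectra are
rejected outright — centroiding belongs upstream (vendor software,
ThermoRawFileParser, msConvert). Scan times are normalized to seconds on
read regardless of the unit declared in the file.
"""

from __future__ import annotations

import base64
import gzip
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

__all__ = [
    "SampleRun",
    "ProfileDataError",
    "read_centroid_mzml",
    "write_mzml",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"


class ProfileDataError(ValueError):
    """Raised when a spectrum is not flagged as centroided."""


@dataclass
class SampleRun:
    """One sample's centroided scans.

    Attributes
    ----------
    sample_id : str
        Identifier, usually the file stem.
    scan_times : np.ndarray
        Strictly increasing scan start times in seconds.
    scans : list of (mz, intensity) array pairs
        Per-scan centroid lists; m/z in Th, intensities >= 0.
    """

    sample_id: str
    scan_times: np.ndarray
    scans: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self.scan_times = np.asarray(self.scan_times, dtype=float)
        self.validate()

    @property
    def n_scans(self) -> int:
        return len(self.scan_times)

    def validate(self) -> None:
        if self.n_scans < 1:
            raise ValueError("a SampleRun needs at least one scan")
        if len(self.scans) != self.n_scans:
            raise ValueError("scan_times and scans length mismatch")
        if np.any(np.diff(self.scan_times) <= 0):
            raise ValueError("scan_times must be strictly increasing")
        for i, (mz, inten) in enumerate(self.scans):
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise ValueError(f"scan {i}: m/z and intensity length mismatch")
            if mz.size and np.any(mz <= 0):
                raise ValueError(f"scan {i}: m/z values must be positive")
            if inten.size and np.any(inten < 0):
                raise ValueError(f"scan {i}: intensities must be non-negative")
            self.scans[i] = (mz, inten)

    @property
    def median_scan_interval(self) -> float:
        if self.n_scans < 2:
            return 1.0
        return float(np.median(np.diff(self.scan_times)))


_TIME_FACTOR = {"second": 1.0, "s": 1.0, "minute": 60.0, "min": 60.0,
                "millisecond": 1e-3, "ms": 1e-3}


def _decode_binary(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    accs = {cv.get("accession") for cv in bda.findall(f"{{{_MZML_NS}}}cvParam")}
    text = bda.findtext(f"{{{_MZML_NS}}}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accs:  # zlib
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(spec):
    """Return (ms_level, centroided, time_s, mz, intensity) for one <spectrum>."""
    ns = f"{{{_MZML_NS}}}"
    params = {cv.get("accession"): cv for cv in spec.findall(f"{ns}cvParam")}
    level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1
    centroided = "MS:1000127" in params and "MS:1000128" not in params
    time_s = None
    for scan in spec.iter(f"{ns}scan"):
        for cv in scan.findall(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":
                unit = cv.get("unitName") or "second"
                time_s = float(cv.get("value")) * _TIME_FACTOR[unit]
        break
    mz = inten = np.empty(0)
    for bda in spec.iter(f"{ns}binaryDataArray"):
        accs = {cv.get("accession") for cv in bda.findall(f"{ns}cvParam")}
        if "MS:1000514" in accs:
            mz = _decode_binary(bda)
        elif "MS:1000515" in accs:
            inten = _decode_binary(bda)
    return level, centroided, time_s, mz, inten


def read_centroid_mzml(path, ms_level: int = 1) -> SampleRun:
    """Read a centroided mzML file into a :class:`SampleRun`.

    Only spectra of the requested MS level are kept (default MS1), in
    scan-time order regardless of file order. Scan times are converted to
    seconds whatever unit the file declares. Zero-intensity centroids are
    dropped. ``.mzML.gz`` is accepted.

    Raises
    ------
    ProfileDataError
        If any selected spectrum is in profile mode (or not flagged as
        centroided), naming the spectrum index.
    ValueError
        If the file holds no spectra at the requested level, or is not mzML.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    times: list[float] = []
    scans: list[tuple[np.ndarray, np.ndarray]] = []
    with opener(path, "rb") as fh:
        try:
            tree = etree.parse(fh)
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"{path.name}: malformed mzML ({exc})") from exc
    root = tree.getroot()
    if etree.QName(root).localname == "indexedmzML":
        root = root.find(f"{{{_MZML_NS}}}mzML")
    if root is None or etree.QName(root).localname != "mzML":
        raise ValueError(f"{path.name}: not an mzML document")
    for idx, spec in enumerate(root.iter(f"{{{_MZML_NS}}}spectrum")):
        level, centroided, t, mz, inten = _parse_spectrum(spec)
        if level != ms_level:
            continue
        if not centroided:
            raise ProfileDataError(
                f"spectrum index {idx} in {path.name} is not centroided; "
                "centroid the data upstream"
            )
        if t is None:
            raise ValueError(f"{path.name}: spectrum {idx} lacks a scan start time")
        keep = inten > 0
        times.append(t)
        scans.append((mz[keep], inten[keep]))
    if not times:
        raise ValueError(f"{path.name}: no MS{ms_level} spectra found")
    order = np.argsort(times, kind="stable")
    sample_id = path.name
    for suf in (".gz", ".mzML", ".mzml"):
        if sample_id.endswith(suf):
            sample_id = sample_id[: -len(suf)]
    return SampleRun(
        sample_id=sample_id,
        scan_times=np.asarray(times)[order],
        scans=[scans[i] for i in order],
    )


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    el = etree.SubElement(parent, "cvParam")
    el.set("cvRef", "MS" if accession.startswith("MS") else "UO")
    el.set("accession", accession)
    el.set("name", name)
    el.set("value", value)
    for k, v in attrs.items():
        el.set(k, v)


def _encode(array: np.ndarray) -> str:
    raw = struct.pack(f"<{array.size}d", *np.asarray(array, dtype=np.float64))
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def write_mzml(run: SampleRun, path, time_unit: str = "second", centroid: bool = True):
    """Write a :class:`SampleRun` as mzML (64-bit, zlib-compressed arrays).

    ``time_unit`` controls the unit the file declares for scan start times
    ('second' or 'minute'); internal times are always seconds.
    ``centroid=False`` flags spectra as profile mode — only useful for
    building negative test fixtures.
    """
    run.validate()
    if time_unit not in ("second", "minute"):
        raise ValueError("time_unit must be 'second' or 'minute'")
    root = etree.Element("mzML", nsmap={None: _MZML_NS})
    root.set("version", "1.1.0")
    root.set("id", run.sample_id)

    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cvlist, "cv", id="UO", fullName="Unit Ontology",
        URI="http://ontologies.berkeleybop.org/uo.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127" if centroid else "MS:1000128",
        "centroid spectrum" if centroid else "profile spectrum")

    soft = etree.SubElement(root, "softwareList", count="1")
    s = etree.SubElement(soft, "software", id="mztrail", version="0.1.0")
    _cv(s, "MS:1000799", "custom unreleased software tool", "mztrail")

    iconf = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(iconf, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")

    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="mztrail")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    runel = etree.SubElement(root, "run", id=run.sample_id,
                             defaultInstrumentConfigurationRef="IC1")
    slist = etree.SubElement(runel, "spectrumList", count=str(run.n_scans),
                             defaultDataProcessingRef="DP1")
    unit_acc = "UO:0000010" if time_unit == "second" else "UO:0000031"
    for i, ((mz, inten), t) in enumerate(zip(run.scans, run.scan_times)):
        spec = etree.SubElement(
            slist, "spectrum", index=str(i),
            id=f"controllerType=0 controllerNumber=1 scan={i + 1}",
            defaultArrayLength=str(mz.size),
        )
        _cv(spec, "MS:1000579", "MS1 spectrum")
        _cv(spec, "MS:1000511", "ms level", "1")
        _cv(spec, "MS:1000127" if centroid else "MS:1000128",
            "centroid spectrum" if centroid else "profile spectrum")
        scanlist = etree.SubElement(spec, "scanList", count="1")
        _cv(scanlist, "MS:1000795", "no combination")
        scan = etree.SubElement(scanlist, "scan")
        tval = t if time_unit == "second" else t / 60.0
        _cv(scan, "MS:1000016", "scan start time", repr(float(tval)),
            unitCvRef="UO", unitAccession=unit_acc, unitName=time_unit)
        bdal = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z")),
            (inten, "MS:1000515", "intensity array", ("MS:1000131", "number of detector counts")),
        ):
            payload = _encode(arr)
            bda = etree.SubElement(bdal, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000574", "zlib compression")
            _cv(bda, acc, name, unitCvRef="MS", unitAccession=unit[0], unitName=unit[1])
            etree.SubElement(bda, "binary").text = payload

    path = Path(path)
    data = etree.tostring(root, xml_declaration=True, encoding="utf-8", pretty_print=True)
    if path.suffix == ".gz":
        # fixed mtime keeps identical runs byte-identical
        with gzip.GzipFile(path, "wb", mtime=0) as fh:
            fh.write(data)
    else:
        path.write_bytes(data)
    return path
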
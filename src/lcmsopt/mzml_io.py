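"""Read and write SRM/MRM chromatogram data as mzML 1.1.

The optimization loop is instrument-independent: every analysis, simulated or
real, is exchanged as an mzML file holding one chromatogram per monitored
transition (precursor m/z -> product m/z).  Reading goes through
:mod:`pyteomics.mzml`; writing emits a minimal, schema-valid mzML 1.1
document with uncompressed 64-bit float arrays and retention times in
minutes, so files round-trip bit-exactly and make stable test fixtures.

Two mzML dialects are accepted on input:

* chromatogram-typed files (the SRM native representation), and
* spectrum-typed files, from which a transition trace is assembled by
  binning MS2 product-ion intensities in +/-0.5 Th windows per precursor
  isolation target.

Both reader and writer operate on the mzML XML directly through lxml:
controlled vocabulary (CV) accessions identify array types, units,
encodings and isolation windows, and binary arrays are decoded from
base64-encoded little-endian 32/64-bit floats (zlib compression accepted
on input, never produced on output).
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from lxml import etree

__all__ = [
    "Chromatogram",
    "RunData",
    "MzmlError",
    "EmptyRunError",
    "TimeUnitError",
    "read_run",
    "write_run",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"

#: width of the product-ion extraction window (Th) when assembling a
#: transition trace from MS2 spectra
XIC_HALF_WIDTH_TH = 0.5


class MzmlError(ValueError):
    """Base class for mzML I/O failures."""


class EmptyRunError(MzmlError):
    """The file contains no usable SRM chromatogram or MS2 spectra."""


class TimeUnitError(MzmlError):
    """A time axis carries no recognizable unit annotation."""


@dataclass(frozen=True)
class Chromatogram:
    """One transition's intensity-versus-retention-time trace.

    Times are always in minutes; intensities are detector counts
    (arbitrary units).
    """

    id: str
    precursor_mz: float
    product_mz: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        intensities = np.asarray(self.intensities, dtype=np.float64)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        if times.ndim != 1 or intensities.ndim != 1:
            raise ValueError("times and intensities must be 1-D")
        if len(times) != len(intensities):
            raise ValueError(
                f"chromatogram {self.id!r}: times ({len(times)}) and "
                f"intensities ({len(intensities)}) differ in length"
            )
        if len(times) < 2:
            raise ValueError(f"chromatogram {self.id!r}: need >= 2 points")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"chromatogram {self.id!r}: times must be strictly increasing")
        if np.any(intensities < 0):
            raise ValueError(f"chromatogram {self.id!r}: negative intensity")
        if not (self.precursor_mz > 0 and self.product_mz > 0):
            raise ValueError(f"chromatogram {self.id!r}: m/z values must be positive")

    @property
    def n_points(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class RunData:
    """All chromatograms from a single LC-MS/MS analysis (one mzML file)."""

    run_id: str
    chromatograms: tuple[Chromatogram, ...]
    source_path: Path | None = None
    max_time: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.run_id:
            raise ValueError("run_id must be non-empty")
        object.__setattr__(self, "chromatograms", tuple(self.chromatograms))
        if self.chromatograms:
            true_max = max(float(c.times[-1]) for c in self.chromatograms)
            object.__setattr__(self, "max_time", true_max)


# ---------------------------------------------------------------------------
# reading


def _unit_to_minutes(values: np.ndarray, unit: str | None) -> np.ndarray:
    if unit is None:
        raise TimeUnitError("time array lacks a unit annotation (expected minute or second)")
    u = unit.lower()
    if u in ("minute", "min", "uo:0000031"):
        return values
    if u in ("second", "s", "sec", "uo:0000010"):
        return values / 60.0
    raise TimeUnitError(f"unrecognized time unit {unit!r}")


def _tag(elem: etree._Element) -> str:
    """Element tag without namespace."""
    return etree.QName(elem).localname


def _cv_params(elem: etree._Element) -> dict[str, tuple[str | None, str | None]]:
    """Direct-child cvParams as accession -> (value, unitName)."""
    out = {}
    for child in elem:
        if _tag(child) == "cvParam":
            out[child.get("accession", "")] = (child.get("value"), child.get("unitName"))
    return out


def _first(elem: etree._Element, localname: str) -> etree._Element | None:
    for child in elem.iter():
        if _tag(child) == localname:
            return child
    return None


def _isolation_target(parent: etree._Element | None) -> float | None:
    """Isolation window target m/z (MS:1000827) under a precursor/product
    element; falls back to the selected-ion m/z (MS:1000744)."""
    if parent is None:
        return None
    for elem in parent.iter():
        if _tag(elem) == "cvParam" and elem.get("accession") in ("MS:1000827", "MS:1000744"):
            v = elem.get("value")
            if v not in (None, ""):
                return float(v)
    return None


def _decode_binary_arrays(elem: etree._Element) -> dict[str, tuple[np.ndarray, str | None]]:
    """Decode every binaryDataArray under ``elem``.

    Returns array-type accession -> (values, unitName).  Supports 64/32-bit
    floats, optionally zlib-compressed.
    """
    arrays: dict[str, tuple[np.ndarray, str | None]] = {}
    for bda in elem.iter():
        if _tag(bda) != "binaryDataArray":
            continue
        params = _cv_params(bda)
        fmt = "d" if "MS:1000523" in params else ("f" if "MS:1000521" in params else None)
        if fmt is None:
            raise MzmlError("binaryDataArray lacks a float-type cvParam")
        binary = _first(bda, "binary")
        raw = base64.b64decode(binary.text or "") if binary is not None else b""
        if "MS:1000574" in params:  # zlib compression
            raw = zlib.decompress(raw)
        values = np.frombuffer(raw, dtype=np.dtype(f"<{fmt}")).astype(np.float64)
        for acc in ("MS:1000595", "MS:1000515", "MS:1000514"):  # time/intensity/mz
            if acc in params:
                arrays[acc] = (values, params[acc][1])
                break
    return arrays


def _read_chromatogram_entries(path: Path) -> list[Chromatogram]:
    chroms: list[Chromatogram] = []
    for _, elem in etree.iterparse(str(path), tag=f"{{{_MZML_NS}}}chromatogram"):
        # TIC / pressure traces carry no precursor+product annotation: skip
        q1 = _isolation_target(_first(elem, "precursor"))
        q3 = _isolation_target(_first(elem, "product"))
        if q1 is None or q3 is None:
            elem.clear()
            continue
        arrays = _decode_binary_arrays(elem)
        if "MS:1000595" not in arrays or "MS:1000515" not in arrays:
            elem.clear()
            continue
        times, time_unit = arrays["MS:1000595"]
        intensities, _ = arrays["MS:1000515"]
        chroms.append(
            Chromatogram(
                id=elem.get("id", f"chromatogram_{len(chroms)}"),
                precursor_mz=q1,
                product_mz=q3,
                times=_unit_to_minutes(times, time_unit),
                intensities=np.clip(intensities, 0.0, None),
            )
        )
        elem.clear()
    return chroms


def _read_spectrum_entries(path: Path) -> list[Chromatogram]:
    """Assemble per-transition XICs from MS2 spectra.

    A trace is built for each distinct (precursor isolation target, product
    bin) pair by summing intensity within +/-0.5 Th of each product-ion
    cluster.  Targeted MS2 data carry one narrow product region per
    precursor, which this recovers exactly; callers apply their own m/z
    tolerance when matching transitions downstream.
    """
    by_key: dict[tuple[float, float], list[tuple[float, float]]] = {}
    for _, spec in etree.iterparse(str(path), tag=f"{{{_MZML_NS}}}spectrum"):
        params = _cv_params(spec)
        if params.get("MS:1000511", (None, None))[0] != "2":  # ms level
            spec.clear()
            continue
        q1 = _isolation_target(_first(spec, "precursor"))
        if q1 is None:
            spec.clear()
            continue
        scan = _first(spec, "scan")
        rt_param = _cv_params(scan).get("MS:1000016") if scan is not None else None
        if rt_param is None or rt_param[0] in (None, ""):
            raise TimeUnitError("MS2 spectrum lacks a scan start time")
        rt_min = float(_unit_to_minutes(np.asarray([float(rt_param[0])]), rt_param[1])[0])
        arrays = _decode_binary_arrays(spec)
        if "MS:1000514" not in arrays or "MS:1000515" not in arrays:
            spec.clear()
            continue
        mzs, _ = arrays["MS:1000514"]
        ints, _ = arrays["MS:1000515"]
        if len(mzs) == 0:
            spec.clear()
            continue
        # one bin per distinct rounded product-ion cluster center
        width = 2 * XIC_HALF_WIDTH_TH
        for center in np.unique(np.round(mzs / width) * width):
            mask = np.abs(mzs - center) <= XIC_HALF_WIDTH_TH
            if mask.any():
                by_key.setdefault((q1, float(center)), []).append(
                    (rt_min, float(ints[mask].sum()))
                )
        spec.clear()
    chroms = []
    for (q1, q3), pts in sorted(by_key.items()):
        pts.sort()
        t = np.asarray([p[0] for p in pts])
        i = np.asarray([p[1] for p in pts])
        if len(t) < 2 or not np.all(np.diff(t) > 0):
            continue
        chroms.append(
            Chromatogram(
                id=f"XIC Q1={q1:g} Q3={q3:g}",
                precursor_mz=q1,
                product_mz=q3,
                times=t,
                intensities=np.clip(i, 0.0, None),
            )
        )
    return chroms


def read_run(path: str | Path, run_id: str | None = None) -> RunData:
    """Read one LC-MS/MS analysis from mzML.

    Returns one :class:`Chromatogram` per distinct transition, with times in
    minutes regardless of the file's declared unit.  Chromatogram-typed
    files are preferred; spectrum-typed files fall back to XIC assembly.

    Raises
    ------
    MzmlError
        On malformed XML (message includes the parser's position) or when
        the file yields no usable transition trace.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        chroms = _read_chromatogram_entries(path)
    except etree.XMLSyntaxError as exc:
        raise MzmlError(f"malformed mzML {path}: {exc}") from exc
    except TimeUnitError:
        raise
    if not chroms:
        try:
            chroms = _read_spectrum_entries(path)
        except etree.XMLSyntaxError as exc:  # pragma: no cover - same path as above
            raise MzmlError(f"malformed mzML {path}: {exc}") from exc
    if not chroms:
        raise EmptyRunError(f"{path}: no SRM chromatograms or MS2 spectra found")
    return RunData(run_id=run_id or path.stem, chromatograms=tuple(chroms), source_path=path)


# ---------------------------------------------------------------------------
# writing


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=np.float64))
    return base64.b64encode(raw).decode("ascii")


def _cv(parent: etree._Element, accession: str, name: str, value: str = "",
        unit: tuple[str, str, str] | None = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit is not None:
        attrs.update(
            unitCvRef=unit[0], unitAccession=unit[1], unitName=unit[2]
        )
    etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", attrs)


_UNIT_MINUTE = ("UO", "UO:0000031", "minute")
_UNIT_MZ = ("MS", "MS:1000040", "m/z")
_UNIT_COUNTS = ("MS", "MS:1000131", "number of detector counts")


def write_run(run: RunData, path: str | Path) -> Path:
    """Write a run as minimal schema-valid mzML 1.1.

    One ``<chromatogram>`` element per transition; precursor/product
    isolation targets recorded as CV params; arrays as uncompressed 64-bit
    floats; time unit minutes.  The output is readable by :func:`read_run`
    with exact reproduction of ids and m/z values and times/intensities to
    binary precision.
    """
    if not run.chromatograms:
        raise ValueError("refusing to write a run with no chromatograms")
    path = Path(path)

    E = lambda tag, parent=None, **attrs: (
        etree.SubElement(parent, f"{{{_MZML_NS}}}{tag}", attrs)
        if parent is not None
        else etree.Element(f"{{{_MZML_NS}}}{tag}", attrs, nsmap={None: _MZML_NS})
    )

    root = E(
        "mzML",
        version="1.1.0",
        id=run.run_id,
    )
    cv_list = E("cvList", root, count="2")
    etree.SubElement(cv_list, f"{{{_MZML_NS}}}cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    })
    etree.SubElement(cv_list, f"{{{_MZML_NS}}}cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    })
    fdesc = E("fileDescription", root)
    fcontent = E("fileContent", fdesc)
    _cv(fcontent, "MS:1001473", "selected reaction monitoring chromatogram")

    sw_list = E("softwareList", root, count="1")
    sw = E("software", sw_list, id="lcmsopt", version="0.1.0")
    _cv(sw, "MS:1000799", "custom unreleased software tool", value="lcmsopt")

    ic_list = E("instrumentConfigurationList", root, count="1")
    ic = E("instrumentConfiguration", ic_list, id="IC1")
    _cv(ic, "MS:1000031", "instrument model")

    dp_list = E("dataProcessingList", root, count="1")
    dp = E("dataProcessing", dp_list, id="DP1")
    pm = E("processingMethod", dp, order="0", softwareRef="lcmsopt")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = E("run", root, id=run.run_id, defaultInstrumentConfigurationRef="IC1")
    chrom_list = E(
        "chromatogramList", run_el,
        count=str(len(run.chromatograms)), defaultDataProcessingRef="DP1",
    )
    for idx, chrom in enumerate(run.chromatograms):
        c_el = E(
            "chromatogram", chrom_list,
            index=str(idx), id=chrom.id, defaultArrayLength=str(chrom.n_points),
        )
        _cv(c_el, "MS:1001473", "selected reaction monitoring chromatogram")
        prec = E("precursor", c_el)
        iso = E("isolationWindow", prec)
        _cv(iso, "MS:1000827", "isolation window target m/z",
            value=repr(chrom.precursor_mz), unit=_UNIT_MZ)
        prod = E("product", c_el)
        iso = E("isolationWindow", prod)
        _cv(iso, "MS:1000827", "isolation window target m/z",
            value=repr(chrom.product_mz), unit=_UNIT_MZ)
        bda_list = E("binaryDataArrayList", c_el, count="2")
        for accession, name, unit, values in (
            ("MS:1000595", "time array", _UNIT_MINUTE, chrom.times),
            ("MS:1000515", "intensity array", _UNIT_COUNTS, chrom.intensities),
        ):
            payload = _b64_doubles(values)
            bda = E("binaryDataArray", bda_list, encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, accession, name, unit=unit)
            bin_el = E("binary", bda)
            bin_el.text = payload

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
    return path
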
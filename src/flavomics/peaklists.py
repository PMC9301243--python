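"""Peak-list readers and writers.

Three input dialects are supported:

* **MGF** — one ``BEGIN IONS``/``END IONS`` block per MS/MS-bearing
  precursor (``PEPMASS``, ``RTINSECONDS`` and/or ``RTINMINUTES``, ``TITLE``).
* **CSV** — one feature per row with columns ``feature_id``,
  ``precursor_mz``, ``rt_min``, ``ms2_mz``, ``ms2_intensity`` (pipe-separated
  lists) and optional ``sample_id``.
* **mzML** — centroided spectra; MS2 spectra are grouped under their
  selected-ion precursor m/z.  Only the subset of mzML needed for centroided
  peak lists is parsed (64/32-bit float arrays, optional zlib compression).
"""

from __future__ import annotations

import base64
import csv
import logging
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrumRecord",
    "read_peaklists",
    "read_mgf",
    "write_mgf",
    "read_csv_peaklist",
    "write_csv_peaklist",
    "read_mzml",
]


@dataclass
class SpectrumRecord:
    """One MS1 feature together with its (possibly empty) MS/MS peak list."""

    feature_id: str
    precursor_mz: float
    retention_time: float | None = None  # minutes
    ms2_peaks: list[tuple[float, float]] = field(default_factory=list)
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.feature_id}: precursor m/z must be positive")
        for mz, _ in self.ms2_peaks:
            if mz <= 0:
                raise ValueError(f"{self.feature_id}: non-positive MS2 m/z {mz}")


def read_peaklists(path: str | Path, format: str | None = None) -> list[SpectrumRecord]:
    """Dispatch to the reader named by ``format`` (or the file suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        return read_mgf(path)
    if fmt == "csv":
        return read_csv_peaklist(path)
    if fmt == "mzml":
        return read_mzml(path)
    raise ValueError(f"unknown peak-list format {fmt!r}")


# ---------------------------------------------------------------------------
# MGF


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    records: list[SpectrumRecord] = []
    title = None
    pepmass = None
    rt_min = None
    peaks: list[tuple[float, float]] = []
    in_block = False
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block, title, pepmass, rt_min, peaks = True, None, None, None, []
                continue
            if line == "END IONS":
                if pepmass is None:
                    raise ValueError(f"MGF block without PEPMASS in {path}")
                n += 1
                records.append(
                    SpectrumRecord(
                        feature_id=title or f"spectrum_{n}",
                        precursor_mz=pepmass,
                        retention_time=rt_min,
                        ms2_peaks=peaks,
                    )
                )
                in_block = False
                continue
            if not in_block:
                continue
            if "=" in line:
                key, _, val = line.partition("=")
                key = key.upper()
                if key == "PEPMASS":
                    pepmass = float(val.split()[0])
                elif key == "RTINSECONDS":
                    rt_min = float(val) / 60.0
                elif key == "RTINMINUTES":
                    rt_min = float(val)
                elif key == "TITLE":
                    title = val.strip()
            else:
                parts = line.split()
                peaks.append((float(parts[0]), float(parts[1]) if len(parts) > 1 else 0.0))
    if not records:
        logger.warning("no spectra found in %s", path)
    return records


def write_mgf(records: list[SpectrumRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={rec.feature_id}\n")
            fh.write(f"PEPMASS={rec.precursor_mz:.6f}\n")
            if rec.retention_time is not None:
                fh.write(f"RTINMINUTES={rec.retention_time:.4f}\n")
            for mz, inten in rec.ms2_peaks:
                fh.write(f"{mz:.6f} {inten:.1f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# CSV dialect

_CSV_COLUMNS = ["feature_id", "precursor_mz", "rt_min", "ms2_mz", "ms2_intensity", "sample_id"]


def read_csv_peaklist(path: str | Path) -> list[SpectrumRecord]:
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("empty peak-list file %s", path)
            return []
        missing = {"feature_id", "precursor_mz"} - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row in reader:
            mzs = [float(x) for x in (row.get("ms2_mz") or "").split("|") if x]
            ints = [float(x) for x in (row.get("ms2_intensity") or "").split("|") if x]
            if ints and len(ints) != len(mzs):
                raise ValueError(f"{path}: ms2_mz/ms2_intensity length mismatch "
                                 f"for {row['feature_id']}")
            if not ints:
                ints = [0.0] * len(mzs)
            rt = row.get("rt_min")
            records.append(
                SpectrumRecord(
                    feature_id=row["feature_id"],
                    precursor_mz=float(row["precursor_mz"]),
                    retention_time=float(rt) if rt else None,
                    ms2_peaks=list(zip(mzs, ints)),
                    sample_id=row.get("sample_id") or None,
                )
            )
    return records


def write_csv_peaklist(records: list[SpectrumRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for rec in records:
            w.writerow([
                rec.feature_id,
                f"{rec.precursor_mz:.6f}",
                "" if rec.retention_time is None else f"{rec.retention_time:.4f}",
                "|".join(f"{mz:.6f}" for mz, _ in rec.ms2_peaks),
                "|".join(f"{i:.1f}" for _, i in rec.ms2_peaks),
                rec.sample_id or "",
            ])


# ---------------------------------------------------------------------------
# mzML (minimal, centroided)

_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary(elem: ET.Element) -> list[float]:
    precision = 64
    compressed = False
    for cv in elem.iter(f"{_NS}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            precision = 32
        elif acc == "MS:1000523":
            precision = 64
        elif acc == "MS:1000574":
            compressed = True
    node = elem.find(f"{_NS}binary")
    if node is None or not (node.text or "").strip():
        return []
    raw = base64.b64decode(node.text.strip())
    if compressed:
        raw = zlib.decompress(raw)
    fmt = "d" if precision == 64 else "f"
    count = len(raw) // struct.calcsize(fmt)
    return list(struct.unpack(f"<{count}{fmt}", raw))


def _cv_value(elem: ET.Element, accession: str) -> str | None:
    for cv in elem.iter(f"{_NS}cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value")
    return None


def _has_cv(elem: ET.Element, accession: str) -> bool:
    return any(cv.get("accession") == accession for cv in elem.iter(f"{_NS}cvParam"))


def read_mzml(path: str | Path) -> list[SpectrumRecord]:
    """Read centroided spectra; one record per MS2 spectrum's precursor."""
    records: list[SpectrumRecord] = []
    tree = ET.parse(path)
    for spectrum in tree.iter(f"{_NS}spectrum"):
        level = _cv_value(spectrum, "MS:1000511")
        if level != "2":
            continue
        sel = spectrum.find(f".//{_NS}selectedIon")
        if sel is None:
            raise ValueError(f"MS2 spectrum without selected ion in {path}")
        prec_mz = _cv_value(sel, "MS:1000744")
        if prec_mz is None:
            raise ValueError(f"MS2 spectrum without precursor m/z in {path}")
        rt = None
        scan = spectrum.find(f".//{_NS}scan")
        if scan is not None:
            val = _cv_value(scan, "MS:1000016")
            if val is not None:
                unit = None
                for cv in scan.iter(f"{_NS}cvParam"):
                    if cv.get("accession") == "MS:1000016":
                        unit = cv.get("unitName")
                rt = float(val) / 60.0 if unit == "second" else float(val)
        arrays = spectrum.findall(f".//{_NS}binaryDataArray")
        mzs: list[float] = []
        intens: list[float] = []
        for arr in arrays:
            if _has_cv(arr, "MS:1000514"):
                mzs = _decode_binary(arr)
            elif _has_cv(arr, "MS:1000515"):
                intens = _decode_binary(arr)
        if not intens:
            intens = [0.0] * len(mzs)
        records.append(
            SpectrumRecord(
                feature_id=spectrum.get("id", f"spectrum_{len(records) + 1}"),
                precursor_mz=float(prec_mz),
                retention_time=rt,
                ms2_peaks=list(zip(mzs, intens)),
            )
        )
    if not records:
        logger.warning("no MS2 spectra found in %s", path)
    return records
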
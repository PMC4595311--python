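"""Reading, organizing and writing MALDI-TOF spectra.

A :class:`Spectrum` is one replicate acquisition: paired arrays of m/z
(Daltons, strictly increasing) and intensity.  A :class:`Dataset` groups
spectra into samples (replicates of one biological specimen) and samples
into labelled conditions.  Raw spectra are read from mzML/mzXML (via
pyteomics) or two-column CSV; processed artifacts round-trip through CSV.
"""

from __future__ import annotations

import csv as _csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .exceptions import (
    ConflictError,
    EmptySpectrumError,
    ParameterError,
    ParseError,
    StructureError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .matching import ConsensusSpectrum, PeakMatrix

logger = logging.getLogger(__name__)

SPECTRUM_SUFFIXES = {".mzml": "mzml", ".mzxml": "mzxml", ".csv": "csv"}


@dataclass
class Spectrum:
    """One replicate acquisition.

    Parameters
    ----------
    id : str
        Dataset-relative identifier (typically the file stem).
    sample_id : str
        Identifier of the sample this replicate belongs to.
    replicate_index : int
        Zero-based index of the replicate within its sample.
    mz : ndarray
        m/z values in Daltons, strictly increasing.
    intensity : ndarray
        Intensities (arbitrary units), same length as ``mz``.
    metadata : dict
        Free-form source metadata (e.g. profile/centroid mode flag).
    """

    id: str
    sample_id: str
    replicate_index: int
    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ParameterError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise ParameterError(
                f"mz and intensity length mismatch: {len(self.mz)} vs {len(self.intensity)}"
            )
        if len(self.mz) == 0:
            raise EmptySpectrumError(f"spectrum {self.id!r} has no data points")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ParameterError(f"spectrum {self.id!r} contains non-finite values")
        if np.any(np.diff(self.mz) <= 0):
            raise ParameterError(f"spectrum {self.id!r}: mz not strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    def replace_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Return a copy with the same m/z grid and new intensities."""
        return Spectrum(
            self.id, self.sample_id, self.replicate_index,
            self.mz.copy(), np.asarray(intensity, dtype=float),
            dict(self.metadata),
        )


@dataclass
class Dataset:
    """A labelled collection of samples, each with >=1 replicate spectra."""

    conditions: dict[str, list[str]]  # condition label -> sample ids
    samples: dict[str, list[Spectrum]]  # sample id -> replicates

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cond, sample_ids in self.conditions.items():
            for sid in sample_ids:
                if sid in seen:
                    raise ConflictError(
                        f"sample {sid!r} appears in conditions {seen[sid]!r} and {cond!r}"
                    )
                seen[sid] = cond
        for sid, reps in self.samples.items():
            if not reps:
                raise StructureError(f"sample {sid!r} has no replicates")

    @property
    def condition_of(self) -> dict[str, str]:
        return {s: c for c, sids in self.conditions.items() for s in sids}

    @property
    def n_spectra(self) -> int:
        return sum(len(reps) for reps in self.samples.values())

    def all_spectra(self) -> list[Spectrum]:
        out: list[Spectrum] = []
        for sids in self.conditions.values():
            for sid in sids:
                out.extend(self.samples[sid])
        return out


def _sanitize_arrays(
    mz: np.ndarray, intensity: np.ndarray, source: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z (warn) and merge exact duplicate m/z by summing intensity."""
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(mz) == 0:
        raise EmptySpectrumError(f"{source}: no data points")
    order = np.argsort(mz, kind="stable")
    if np.any(order != np.arange(len(mz))):
        logger.warning("%s: m/z values unordered; sorting", source)
        mz, intensity = mz[order], intensity[order]
    dup = np.diff(mz) == 0
    if np.any(dup):
        logger.warning("%s: merging %d duplicate m/z values by summing", source, int(dup.sum()))
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros(len(uniq))
        np.add.at(summed, inverse, intensity)
        mz, intensity = uniq, summed
    return mz, intensity


def _read_csv_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mzs: list[float] = []
    ints: list[float] = []
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        rows = list(reader)
    if not rows:
        raise EmptySpectrumError(f"{path}: empty file")
    start = 0
    first = rows[0]
    try:
        float(first[0]), float(first[1])
    except (ValueError, IndexError):
        start = 1  # header row
    else:
        logger.warning("%s: no header row; assuming columns are mz,intensity", path)
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
        try:
            mzs.append(float(row[0]))
            ints.append(float(row[1]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value ({exc})") from None
    if not mzs:
        raise EmptySpectrumError(f"{path}: no data rows")
    return np.array(mzs), np.array(ints)


def _read_mzxml(path: Path, index: int) -> tuple[np.ndarray, np.ndarray, dict]:
    from pyteomics import mzxml

    meta: dict = {}
    ms1: list[dict] = []
    try:
        with mzxml.read(str(path)) as reader:
            for scan in reader:
                if int(scan.get("msLevel", 1) or 1) == 1:
                    ms1.append(scan)
                    if len(ms1) > index:
                        meta["spectrum_mode"] = (
                            "centroid" if scan.get("centroided") else None
                        )
                        break
    except OSError:
        raise
    except Exception as exc:  # malformed XML etc.
        raise ParseError(f"{path}: cannot parse mzXML file ({exc})") from exc
    if len(ms1) <= index:
        raise EmptySpectrumError(
            f"{path}: no MS1 spectrum at index {index} (found {len(ms1)})"
        )
    scan = ms1[index]
    return np.asarray(scan["m/z array"], float), np.asarray(scan["intensity array"], float), meta


# mzML 1.1 controlled-vocabulary accessions used by the reader
_MZML_ACC = {
    "ms_level": "MS:1000511",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
    "none": "MS:1000576",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
}


def _decode_mzml_binary(elem) -> np.ndarray:
    import base64
    import zlib as _zlib

    accs = {
        cv.get("accession")
        for cv in elem.iter()
        if cv.tag.endswith("cvParam")
    }
    binary = next((c for c in elem.iter() if c.tag.endswith("}binary")), None)
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _MZML_ACC["zlib"] in accs:
        raw = _zlib.decompress(raw)
    dtype = "<f4" if _MZML_ACC["f32"] in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path, index: int) -> tuple[np.ndarray, np.ndarray, dict]:
    """Minimal mzML 1.1 reader: MS1 scans, base64 arrays, no/zlib compression."""
    import xml.etree.ElementTree as ET

    ms1_seen = 0
    try:
        for _, elem in ET.iterparse(str(path), events=("end",)):
            if not elem.tag.endswith("}spectrum"):
                continue
            params = {
                cv.get("accession"): cv.get("value")
                for cv in elem.iter()
                if cv.tag.endswith("cvParam")
            }
            level = int(params.get(_MZML_ACC["ms_level"], 1) or 1)
            if level != 1:
                elem.clear()
                continue
            if ms1_seen == index:
                mz = intensity = None
                for arr in elem.iter():
                    if not arr.tag.endswith("}binaryDataArray"):
                        continue
                    accs = {
                        cv.get("accession")
                        for cv in arr.iter()
                        if cv.tag.endswith("cvParam")
                    }
                    data = _decode_mzml_binary(arr)
                    if _MZML_ACC["mz_array"] in accs:
                        mz = data
                    elif _MZML_ACC["intensity_array"] in accs:
                        intensity = data
                if mz is None or intensity is None:
                    raise ParseError(f"{path}: spectrum lacks m/z or intensity array")
                mode = (
                    "centroid" if _MZML_ACC["centroid"] in params
                    else "profile" if _MZML_ACC["profile"] in params
                    else None
                )
                return mz, intensity, {"spectrum_mode": mode}
            ms1_seen += 1
            elem.clear()
    except ET.ParseError as exc:
        raise ParseError(f"{path}: cannot parse mzML file ({exc})") from exc
    raise EmptySpectrumError(
        f"{path}: no MS1 spectrum at index {index} (found {ms1_seen})"
    )


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    *,
    index: int = 0,
    sample_id: str | None = None,
    replicate_index: int = 0,
    spectrum_id: str | None = None,
) -> Spectrum:
    """Read one spectrum from an mzML, mzXML or two-column CSV file.

    For multi-spectrum mzML/mzXML files the ``index``-th MS1 spectrum is
    returned (default: the first).  Unsorted m/z values are sorted with a
    warning; exact duplicates are merged by summing intensities.
    """
    path = Path(path)
    if format is None:
        try:
            format = SPECTRUM_SUFFIXES[path.suffix.lower()]
        except KeyError:
            raise ParameterError(f"cannot infer format from suffix {path.suffix!r}") from None
    format = format.lower()
    if format not in ("mzml", "mzxml", "csv"):
        raise ParameterError(f"unknown format {format!r}")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    meta: dict = {}
    if format == "csv":
        mz, intensity = _read_csv_spectrum(path)
    elif format == "mzml":
        mz, intensity, meta = _read_mzml(path, index)
    else:
        mz, intensity, meta = _read_mzxml(path, index)
    mz, intensity = _sanitize_arrays(mz, intensity, str(path))
    return Spectrum(
        id=spectrum_id or path.stem,
        sample_id=sample_id if sample_id is not None else path.stem,
        replicate_index=replicate_index,
        mz=mz,
        intensity=intensity,
        metadata=meta,
    )


def _spectrum_files(directory: Path) -> list[Path]:
    return sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in SPECTRUM_SUFFIXES
    )


def load_dataset(root: str | Path, layout: str = "condition_dirs") -> Dataset:
    """Load a labelled dataset of raw spectra from disk.

    Two layouts are supported:

    ``condition_dirs``
        ``root/<condition>/<sample>/<replicate files>`` — names come from
        the directory structure.
    ``manifest``
        ``root`` is a CSV file with columns ``path,condition,sample``
        (paths relative to the manifest or absolute).

    Ordering is deterministic: lexicographic by path.
    """
    root = Path(root)
    if layout == "condition_dirs":
        return _load_condition_dirs(root)
    if layout == "manifest":
        return _load_manifest(root)
    raise ParameterError(f"unknown layout {layout!r}")


def _load_condition_dirs(root: Path) -> Dataset:
    if not root.is_dir():
        raise StructureError(f"not a directory: {root}")
    conditions: dict[str, list[str]] = {}
    samples: dict[str, list[Spectrum]] = {}
    cond_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not cond_dirs:
        raise StructureError(f"{root}: no condition directories")
    for cond_dir in cond_dirs:
        sample_dirs = sorted(p for p in cond_dir.iterdir() if p.is_dir())
        if not sample_dirs:
            raise StructureError(f"{cond_dir}: condition has no sample directories")
        sample_ids = []
        for sample_dir in sample_dirs:
            files = _spectrum_files(sample_dir)
            if not files:
                raise StructureError(f"{sample_dir}: sample has no spectrum files")
            sid = sample_dir.name
            if sid in samples:
                raise ConflictError(f"duplicate sample id {sid!r} (in {cond_dir.name!r})")
            samples[sid] = [
                read_spectrum(f, sample_id=sid, replicate_index=i,
                              spectrum_id=f"{sid}/{f.stem}")
                for i, f in enumerate(files)
            ]
            sample_ids.append(sid)
        conditions[cond_dir.name] = sample_ids
    return Dataset(conditions=conditions, samples=samples)


def _load_manifest(manifest: Path) -> Dataset:
    if not manifest.is_file():
        raise StructureError(f"manifest not found: {manifest}")
    import pandas as pd

    table = pd.read_csv(manifest)
    required = {"path", "condition", "sample"}
    if not required.issubset(table.columns):
        raise StructureError(
            f"{manifest}: manifest needs columns {sorted(required)}, got {list(table.columns)}"
        )
    base = manifest.parent
    rows = sorted(table.itertuples(index=True), key=lambda r: str(r.path))
    conditions: dict[str, list[str]] = {}
    samples: dict[str, list[Spectrum]] = {}
    sample_condition: dict[str, str] = {}
    for row in rows:
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        if not path.is_file():
            raise StructureError(f"{manifest}: row {row.Index + 2}: missing file {row.path}")
        cond, sid = str(row.condition), str(row.sample)
        if sid in sample_condition and sample_condition[sid] != cond:
            raise ConflictError(
                f"sample {sid!r} listed under both {sample_condition[sid]!r} and {cond!r}"
            )
        sample_condition[sid] = cond
        reps = samples.setdefault(sid, [])
        reps.append(
            read_spectrum(path, sample_id=sid, replicate_index=len(reps),
                          spectrum_id=f"{sid}/{path.stem}")
        )
        conditions.setdefault(cond, [])
        if sid not in conditions[cond]:
            conditions[cond].append(sid)
    return Dataset(conditions=conditions, samples=samples)


# --------------------------------------------------------------------------
# CSV export / import of processed artifacts


def write_csv(artifact, path: str | Path) -> None:
    """Write a Spectrum, PeakList, ConsensusSpectrum or PeakMatrix as CSV.

    Spectra and peak lists get a ``mz,intensity`` header; consensus spectra
    add a ``pop`` column; peak matrices are written one sample per row with
    ``sample,condition`` leading columns and matched m/z values (4 decimal
    places) as the remaining column names.
    """
    from .matching import ConsensusSpectrum, PeakMatrix
    from .preprocess import PeakList

    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            writer = _csv.writer(fh)
            if isinstance(artifact, PeakMatrix):
                header = ["sample", "condition"] + [f"{m:.4f}" for m in artifact.mz]
                writer.writerow(header)
                for i, sid in enumerate(artifact.sample_ids):
                    vals = [
                        int(v) if artifact.mode == "binary" else repr(float(v))
                        for v in artifact.values[i]
                    ]
                    writer.writerow([sid, artifact.conditions[i]] + vals)
            elif isinstance(artifact, ConsensusSpectrum):
                writer.writerow(["mz", "intensity", "pop"])
                for m, inten, pop in zip(artifact.mz, artifact.intensity, artifact.pop):
                    writer.writerow([repr(float(m)), repr(float(inten)), repr(float(pop))])
            elif isinstance(artifact, (Spectrum, PeakList)):
                writer.writerow(["mz", "intensity"])
                for m, inten in zip(artifact.mz, artifact.intensity):
                    writer.writerow([repr(float(m)), repr(float(inten))])
            else:
                raise ParameterError(f"cannot export object of type {type(artifact).__name__}")
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_consensus_csv(path: str | Path, sample_id: str | None = None) -> "ConsensusSpectrum":
    """Read a consensus spectrum written by :func:`write_csv`."""
    from .matching import ConsensusSpectrum

    path = Path(path)
    import pandas as pd

    table = pd.read_csv(path)
    for col in ("mz", "intensity", "pop"):
        if col not in table.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return ConsensusSpectrum(
        sample_id=sample_id or path.stem,
        mz=table["mz"].to_numpy(float),
        pop=table["pop"].to_numpy(float),
        intensity=table["intensity"].to_numpy(float),
    )


def read_peak_matrix_csv(path: str | Path) -> "PeakMatrix":
    """Read a peak matrix written by :func:`write_csv`."""
    from .matching import PeakMatrix

    import pandas as pd

    path = Path(path)
    table = pd.read_csv(path, dtype={"sample": str, "condition": str})
    if list(table.columns[:2]) != ["sample", "condition"]:
        raise ParseError(f"{path}: first two columns must be sample,condition")
    mz = np.array([float(c) for c in table.columns[2:]])
    values = table.iloc[:, 2:].to_numpy(float)
    mode = "binary" if np.all(np.isin(values, (0.0, 1.0))) else "intensity"
    return PeakMatrix(
        sample_ids=list(table["sample"]),
        conditions=list(table["condition"]),
        mz=mz,
        values=values,
        mode=mode,
    )
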
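"""Peak matching across spectra and consensus-spectrum construction.

Two matchers align m/z values that represent the same analyte:

* :func:`forward_match` — a sequential forward sliding window: peaks are
  pooled and visited from minimum to maximum m/z; each peak joins the last
  cluster created if it lies within tolerance of that cluster's running
  mean m/z, otherwise it starts a new cluster.  A cluster may never hold
  two peaks of one spectrum; on conflict one of the two is kept and the
  displaced peak seeds a new cluster.
* :func:`bin_match` — a binning matcher that recursively splits the pooled,
  sorted peaks at the largest relative m/z gap until every bin is within
  tolerance of its mean and holds at most one peak per spectrum.

Intra-sample matching of a sample's replicates yields a consensus
spectrum, where each matched m/z carries a POP (percentage of presence:
the share of replicates contributing a peak).  Inter-sample matching of
consensus spectra yields the samples x m/z :class:`PeakMatrix` consumed by
all downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .exceptions import ConflictError, ParameterError
from .preprocess import PeakList

Tolerance = float


@dataclass
class Peak:
    """One pooled peak: where it came from and what was measured."""

    spectrum_id: str
    mz: float
    intensity: float


@dataclass
class MatchCluster:
    """A group of peaks (at most one per spectrum) judged to be one analyte."""

    members: list[Peak] = field(default_factory=list)

    @property
    def center(self) -> float:
        return float(np.mean([p.mz for p in self.members]))

    @property
    def spectrum_ids(self) -> set[str]:
        return {p.spectrum_id for p in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ConsensusSpectrum:
    """Per-sample merged peaks, each with its POP (percentage of presence)."""

    sample_id: str
    mz: np.ndarray
    pop: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.pop = np.asarray(self.pop, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.mz) == len(self.pop) == len(self.intensity)):
            raise ParameterError("consensus arrays must have equal length")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            raise ParameterError("consensus mz must be strictly increasing")
        if len(self.pop) and (np.any(self.pop <= 0) or np.any(self.pop > 100)):
            raise ParameterError("POP values must lie in (0, 100]")

    def __len__(self) -> int:
        return len(self.mz)

    def as_peaklist(self) -> PeakList:
        return PeakList(self.sample_id, self.mz.copy(), self.intensity.copy())


@dataclass
class PeakMatrix:
    """Samples x matched-m/z matrix with condition labels.

    ``mode`` is ``binary`` (cell = 1 iff the sample contributed a peak to
    the column's cluster) or ``intensity`` (the contributed intensity,
    0 where absent).
    """

    sample_ids: list[str]
    conditions: list[str]
    mz: np.ndarray
    values: np.ndarray
    mode: Literal["binary", "intensity"] = "binary"

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.mz)):
            raise ParameterError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.mz)} m/z"
            )
        if len(self.conditions) != len(self.sample_ids):
            raise ParameterError("one condition label per sample required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConflictError("duplicate sample ids in peak matrix")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) <= 0):
            raise ParameterError("mz axis must be strictly increasing")
        if self.mode == "binary" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ParameterError("binary matrix cells must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def condition_labels(self) -> list[str]:
        """Distinct conditions in first-appearance order."""
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[f"{m:.4f}" for m in self.mz])
        df.insert(0, "condition", self.conditions)
        df.insert(0, "sample", self.sample_ids)
        return df


# --------------------------------------------------------------------------


def _tol_window(center: float, tolerance: float, unit: str) -> float:
    if unit == "da":
        return tolerance
    if unit == "ppm":
        return center * tolerance * 1e-6
    raise ParameterError(f"unknown tolerance unit {unit!r} (use 'da' or 'ppm')")


def _pool(peaklists: Sequence[PeakList]) -> list[Peak]:
    pooled = [
        Peak(pl.spectrum_id, float(m), float(i))
        for pl in peaklists
        for m, i in zip(pl.mz, pl.intensity)
    ]
    pooled.sort(key=lambda p: (p.mz, p.spectrum_id))
    return pooled


def forward_match(
    peaklists: Sequence[PeakList],
    tolerance: float = 0.3,
    unit: str = "da",
    conflict: str = "min_spread",
) -> list[MatchCluster]:
    """Match pooled peaks with the forward sliding-window algorithm.

    Peaks are visited from minimum to maximum m/z.  A peak joins the last
    cluster created iff its m/z lies within ``tolerance`` of the cluster's
    mean m/z (recomputed after every insertion); otherwise it starts a new
    cluster.  No cluster may hold two peaks from the same spectrum: on a
    conflict only one of the two peaks is kept and the displaced peak seeds
    a new cluster (which becomes the active one).

    ``conflict`` selects the keeper: ``min_spread`` keeps the member whose
    retention minimizes the cluster's mean absolute deviation from its
    center; ``min_center`` keeps the one minimizing the resulting mean m/z.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    if conflict not in ("min_spread", "min_center"):
        raise ParameterError(f"unknown conflict rule {conflict!r}")
    clusters: list[MatchCluster] = []
    for peak in _pool(peaklists):
        if clusters:
            last = clusters[-1]
            if abs(peak.mz - last.center) <= _tol_window(last.center, tolerance, unit):
                existing = next(
                    (p for p in last.members if p.spectrum_id == peak.spectrum_id), None
                )
                if existing is None:
                    last.members.append(peak)
                else:
                    others = [p for p in last.members if p is not existing]
                    if _keep_incoming(others, existing, peak, conflict):
                        last.members = others + [peak]
                        displaced = existing
                    else:
                        displaced = peak
                    clusters.append(MatchCluster([displaced]))
                continue
        clusters.append(MatchCluster([peak]))
    clusters.sort(key=lambda c: c.center)
    return clusters


def _keep_incoming(
    others: list[Peak], existing: Peak, incoming: Peak, conflict: str
) -> bool:
    with_existing = [p.mz for p in others] + [existing.mz]
    with_incoming = [p.mz for p in others] + [incoming.mz]
    if conflict == "min_center":
        return float(np.mean(with_incoming)) < float(np.mean(with_existing))
    spread_existing = float(np.mean(np.abs(np.array(with_existing) - np.mean(with_existing))))
    spread_incoming = float(np.mean(np.abs(np.array(with_incoming) - np.mean(with_incoming))))
    return spread_incoming < spread_existing


def bin_match(
    peaklists: Sequence[PeakList],
    tolerance: float = 500e-6,
) -> list[MatchCluster]:
    """Match pooled peaks by recursive gap splitting (binning).

    All peaks are pooled and sorted; a bin is accepted when every member
    lies within ``tolerance`` (relative, e.g. 500e-6 = 500 ppm) of the bin
    mean and no two members share a spectrum; a violating bin is split at
    its internal largest relative gap.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    pooled = _pool(peaklists)
    clusters: list[MatchCluster] = []

    def admit(chunk: list[Peak]) -> bool:
        center = float(np.mean([p.mz for p in chunk]))
        if any(abs(p.mz - center) > tolerance * center for p in chunk):
            return False
        ids = [p.spectrum_id for p in chunk]
        return len(set(ids)) == len(ids)

    def split(chunk: list[Peak]) -> None:
        if len(chunk) == 1 or admit(chunk):
            clusters.append(MatchCluster(list(chunk)))
            return
        gaps = [
            (chunk[i + 1].mz - chunk[i].mz) / chunk[i].mz if chunk[i].mz > 0
            else chunk[i + 1].mz - chunk[i].mz
            for i in range(len(chunk) - 1)
        ]
        cut = int(np.argmax(gaps)) + 1
        if max(gaps) == 0:
            cut = len(chunk) // 2  # identical m/z from one spectrum: halve
        split(chunk[:cut])
        split(chunk[cut:])

    if pooled:
        split(pooled)
    clusters.sort(key=lambda c: c.center)
    return clusters


def _run_matcher(
    peaklists: Sequence[PeakList],
    matcher: str,
    tolerance: float,
    unit: str,
) -> list[MatchCluster]:
    if matcher == "forward":
        return forward_match(peaklists, tolerance, unit)
    if matcher in ("bin", "maldiquant"):
        rel = tolerance if unit == "da" else tolerance * 1e-6
        if unit == "da":
            # convert an absolute window to a relative one at the pooled median m/z
            all_mz = np.concatenate([pl.mz for pl in peaklists if len(pl)] or [np.array([1.0])])
            rel = tolerance / max(float(np.median(all_mz)), 1e-9)
        return bin_match(peaklists, rel)
    raise ParameterError(f"unknown matcher {matcher!r}")


def build_consensus(
    replicates: Sequence[PeakList],
    sample_id: str,
    matcher: str = "forward",
    tolerance: float = 0.3,
    unit: str = "da",
    pop_threshold: float = 50.0,
) -> ConsensusSpectrum:
    """Merge a sample's replicates into one consensus spectrum.

    Replicate peak lists are matched intra-sample; each cluster becomes one
    consensus entry (cluster-center m/z, mean member intensity) with
    POP = 100 * members / replicates.  Entries with POP below
    ``pop_threshold`` are dropped (the comparison is ``>=``).  A
    single-replicate sample yields its own peaks, all at POP 100.
    """
    if not replicates:
        raise ParameterError("a sample needs at least one replicate")
    if not 0 < pop_threshold <= 100:
        raise ParameterError("pop_threshold must lie in (0, 100]")
    n_rep = len(replicates)
    if n_rep == 1:
        pl = replicates[0]
        return ConsensusSpectrum(
            sample_id, pl.mz.copy(), np.full(len(pl), 100.0), pl.intensity.copy()
        )
    clusters = _run_matcher(replicates, matcher, tolerance, unit)
    entries = []
    for c in clusters:
        pop = 100.0 * len(c) / n_rep
        if pop >= pop_threshold:
            entries.append((c.center, pop, float(np.mean([p.intensity for p in c.members]))))
    entries.sort()
    mz = np.array([e[0] for e in entries])
    # guard against coincident cluster centers after filtering
    if len(mz) > 1 and np.any(np.diff(mz) <= 0):
        keep = np.concatenate([[True], np.diff(mz) > 0])
        entries = [e for e, k in zip(entries, keep) if k]
        mz = np.array([e[0] for e in entries])
    return ConsensusSpectrum(
        sample_id,
        mz,
        np.array([e[1] for e in entries]),
        np.array([e[2] for e in entries]),
    )


def intersample_match(
    consensus: Sequence[ConsensusSpectrum],
    condition_of: Mapping[str, str],
    matcher: str = "forward",
    tolerance: float = 500.0,
    unit: str = "ppm",
    mode: str = "binary",
) -> PeakMatrix:
    """Match consensus spectra across samples into a :class:`PeakMatrix`.

    Each matched cluster becomes one column at the cluster-center m/z; a
    sample's cell is 1 (binary) or its contributed consensus intensity
    (intensity mode) if the sample has a member in the cluster, else 0.
    """
    if len(consensus) < 2:
        raise ParameterError("inter-sample matching needs >= 2 samples")
    if mode not in ("binary", "intensity"):
        raise ParameterError(f"unknown matrix mode {mode!r}")
    sample_ids = [c.sample_id for c in consensus]
    if len(set(sample_ids)) != len(sample_ids):
        raise ConflictError("duplicate sample ids in consensus list")
    missing = [s for s in sample_ids if s not in condition_of]
    if missing:
        raise ParameterError(f"samples without a condition label: {missing}")
    peaklists = [c.as_peaklist() for c in consensus]
    clusters = _run_matcher(peaklists, matcher, tolerance, unit)
    clusters = [c for c in clusters if len(c)]
    centers = np.array([c.center for c in clusters])
    order = np.argsort(centers, kind="stable")
    # coincident centers would collide as columns; nudge is not meaningful, drop later duplicates
    seen: set[float] = set()
    cols: list[MatchCluster] = []
    for i in order:
        c = clusters[i]
        if c.center in seen:
            cols[-1].members.extend(c.members)
        else:
            seen.add(c.center)
            cols.append(c)
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    values = np.zeros((len(sample_ids), len(cols)))
    for j, c in enumerate(cols):
        for p in c.members:
            values[row_of[p.spectrum_id], j] = 1.0 if mode == "binary" else p.intensity
    return PeakMatrix(
        sample_ids=list(sample_ids),
        conditions=[condition_of[s] for s in sample_ids],
        mz=np.array([c.center for c in cols]),
        values=values,
        mode=mode,
    )
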
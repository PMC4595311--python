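"""Quality control of replicates and samples with Tukey-fence outlier flags.

Replicate-level QC summarizes each spectrum (peak count, m/z range,
intensity range/mean) and flags spectra whose metrics fall outside Tukey
fences computed across the dataset.  Sample-level QC summarizes the
intra-sample matching stage: how many m/z values aligned across a sample's
replicates and how the POP (percentage of presence) values distribute,
with outlier flags per "Count >= XX" category, globally and per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .matching import ConsensusSpectrum
from .preprocess import PeakList

logger = logging.getLogger(__name__)

CANONICAL_THRESHOLDS = (20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class OutlierFlag:
    """One flagged unit: which spectrum/sample, which metric, how severe."""

    unit_id: str
    metric: str
    severity: str  # "outlier" (beyond 1.5*IQR) or "extreme" (beyond 3*IQR)
    value: float
    scope: str = "global"  # "global" or "condition:<label>"


@dataclass(frozen=True)
class BoxplotStats:
    metric: str
    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float


def _tukey_flags(
    values: Sequence[float], ids: Sequence[str], metric: str, scope: str = "global"
) -> list[OutlierFlag]:
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    flags = []
    for uid, v in zip(ids, arr):
        if v < q1 - 3 * iqr or v > q3 + 3 * iqr:
            severity = "extreme"
        elif v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr:
            severity = "outlier"
        else:
            continue
        flags.append(OutlierFlag(uid, metric, severity, float(v), scope))
    return flags


def _box_stats(values: Sequence[float], metric: str) -> BoxplotStats:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    inside = arr[(arr >= q1 - 1.5 * iqr) & (arr <= q3 + 1.5 * iqr)]
    return BoxplotStats(
        metric, float(q1), float(med), float(q3), float(iqr),
        float(inside.min()) if len(inside) else float(q1),
        float(inside.max()) if len(inside) else float(q3),
    )


REPLICATE_METRICS = (
    "peak_count", "mz_min", "mz_max", "intensity_min", "intensity_max", "intensity_mean",
)


def replicate_qc(
    peaklists: Sequence[PeakList],
) -> tuple[pd.DataFrame, dict[str, BoxplotStats], list[OutlierFlag]]:
    """Per-spectrum QC table, boxplot statistics and Tukey outlier flags.

    With fewer than 4 spectra the quartiles are meaningless, so only the
    table is returned (empty stats/flags) with a warning.
    """
    rows = []
    for pl in peaklists:
        empty = len(pl) == 0
        rows.append({
            "spectrum_id": pl.spectrum_id,
            "peak_count": len(pl),
            "mz_min": float(pl.mz.min()) if not empty else np.nan,
            "mz_max": float(pl.mz.max()) if not empty else np.nan,
            "intensity_min": float(pl.intensity.min()) if not empty else np.nan,
            "intensity_max": float(pl.intensity.max()) if not empty else np.nan,
            "intensity_mean": float(pl.intensity.mean()) if not empty else np.nan,
        })
    table = pd.DataFrame(rows)
    if len(peaklists) < 4:
        logger.warning("replicate QC: fewer than 4 spectra; skipping outlier fences")
        return table, {}, []
    stats: dict[str, BoxplotStats] = {}
    flags: list[OutlierFlag] = []
    for metric in REPLICATE_METRICS:
        values = table[metric].to_numpy(float)
        if np.any(np.isnan(values)):
            continue
        stats[metric] = _box_stats(values, metric)
        flags.extend(_tukey_flags(values, table["spectrum_id"], metric))
    return table, stats, flags


def sample_qc(
    consensus: Sequence[ConsensusSpectrum],
    replicate_counts: Mapping[str, int],
    condition_of: Mapping[str, str] | None = None,
    thresholds: Sequence[float] = CANONICAL_THRESHOLDS,
) -> tuple[pd.DataFrame, dict[str, BoxplotStats], list[OutlierFlag]]:
    """Sample-level QC over the intra-sample matching output.

    ``consensus`` must be unfiltered by POP (pop_threshold at its minimum)
    so the full POP distribution is visible.  For each sample the table
    reports the number of aligned masses, the count of entries at each
    attainable POP level (``pop=XX`` columns), and for each threshold t the
    count (``count_ge_t``) and percentage (``split_ge_t``) of entries with
    POP >= t.  Flags are computed per count category across samples,
    globally and — when labels are given — within each condition.
    """
    rows = []
    for cs in consensus:
        n_rep = replicate_counts.get(cs.sample_id)
        if n_rep is None or n_rep < 1:
            raise ParameterError(f"no replicate count for sample {cs.sample_id!r}")
        levels = [round(100.0 * k / n_rep, 1) for k in range(1, n_rep + 1)]
        pops = np.round(cs.pop, 1)
        row: dict = {"sample_id": cs.sample_id, "aligned_masses": len(cs)}
        for lv in levels:
            row[f"pop={lv:g}"] = int(np.sum(pops == lv))
        for t in thresholds:
            count = int(np.sum(cs.pop >= t - 1e-9))
            row[f"count_ge_{t:g}"] = count
            row[f"split_ge_{t:g}"] = 100.0 * count / len(cs) if len(cs) else 0.0
        rows.append(row)
    table = pd.DataFrame(rows).fillna(0)
    count_cols = [f"count_ge_{t:g}" for t in thresholds]
    for c in table.columns:
        if c.startswith(("pop=", "count_ge_")):
            table[c] = table[c].astype(int)
    if len(consensus) < 4:
        logger.warning("sample QC: fewer than 4 samples; skipping outlier fences")
        return table, {}, []
    stats: dict[str, BoxplotStats] = {}
    flags: list[OutlierFlag] = []
    ids = table["sample_id"]
    for col in count_cols:
        values = table[col].to_numpy(float)
        stats[col] = _box_stats(values, col)
        flags.extend(_tukey_flags(values, ids, col))
    if condition_of is not None:
        for cond in sorted(set(condition_of.values())):
            mask = np.array([condition_of.get(s) == cond for s in ids])
            if mask.sum() < 4:
                continue
            for col in count_cols:
                flags.extend(
                    _tukey_flags(
                        table.loc[mask, col].to_numpy(float),
                        ids[mask],
                        col,
                        scope=f"condition:{cond}",
                    )
                )
    return table, stats, flags
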
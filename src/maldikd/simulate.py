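"""Synthetic MALDI-TOF datasets with known ground truth.

Each spectrum is built on a regular m/z grid as an exponentially decaying
baseline (chemical noise is largest at low m/z) plus Gaussian peaks plus
white detector noise.  Peaks come in two kinds: *shared* peaks present in
every condition, and *biomarkers* private to one condition — so every
pipeline stage (preprocessing, matching, consensus, biomarker statistics,
clustering, classification) can be validated against planted truth.
Replicate-to-replicate variation is modelled by m/z jitter, multiplicative
height variation and random per-replicate peak dropout.  Everything is
driven by one seed.
"""

from __future__ import annotations

import json
import string
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np

from .exceptions import ParameterError
from .spectra_io import Dataset, Spectrum


@dataclass
class SimulationConfig:
    """Study-design and signal parameters of the generator.

    Defaults describe a small multi-condition profiling study: 5
    conditions x 5 samples x 3 replicate spots, spectra from 1 to 12 kDa
    on a 1 Da grid, 30 peaks shared by everyone and 5 condition-specific
    biomarkers per condition, with mild replicate variation.
    """

    n_conditions: int = 5
    samples_per_condition: int = 5
    replicates_per_sample: int = 3
    mz_range: tuple[float, float] = (1000.0, 12000.0)
    grid_step: float = 1.0
    n_shared_peaks: int = 30
    n_biomarkers_per_condition: int = 5
    peak_sigma: float = 3.0  # Da
    peak_height_min: float = 50.0
    peak_height_max: float = 150.0
    height_cv: float = 0.2  # lognormal sigma of per-replicate height variation
    baseline_amplitude: float = 60.0
    baseline_decay: float = 2000.0  # Da; exponential decay constant
    noise_sigma: float = 1.0
    dropout: float = 0.1  # per peak per replicate
    mz_jitter_sigma: float = 0.5  # Da
    min_peak_separation: float = 20.0  # Da between planted positions
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not lo < hi:
            raise ParameterError("mz_range must satisfy min < max")
        if self.grid_step <= 0 or (hi - lo) / self.grid_step < 10:
            raise ParameterError("degenerate m/z grid")
        if not 0 <= self.dropout <= 1:
            raise ParameterError("dropout must lie in [0, 1]")
        if self.n_conditions < 1 or self.samples_per_condition < 1 \
                or self.replicates_per_sample < 1:
            raise ParameterError("design counts must be >= 1")


@dataclass
class GroundTruth:
    """What was planted: shared peak positions, per-condition biomarker
    positions, and the per-spectrum realized peak lists (after dropout)."""

    shared_mz: np.ndarray
    biomarkers: dict[str, np.ndarray]  # condition -> m/z array
    peak_heights: dict[float, float]
    realized: dict[str, np.ndarray]  # spectrum id -> m/z actually present

    def all_biomarkers(self) -> np.ndarray:
        if not self.biomarkers:
            return np.array([])
        return np.sort(np.concatenate(list(self.biomarkers.values())))

    def to_json(self) -> str:
        return json.dumps(
            {
                "shared_mz": self.shared_mz.tolist(),
                "biomarkers": {c: v.tolist() for c, v in self.biomarkers.items()},
                "peak_heights": {str(k): v for k, v in self.peak_heights.items()},
                "realized": {k: v.tolist() for k, v in self.realized.items()},
            },
            indent=1,
        )


def _condition_names(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"C{i + 1}" for i in range(n)]


def _draw_positions(
    rng: np.random.Generator, n: int, lo: float, hi: float,
    min_sep: float, existing: list[float],
) -> list[float]:
    """Rejection-sample peak positions keeping a minimum mutual separation."""
    out: list[float] = []
    placed = list(existing)
    attempts = 0
    margin = 3 * min_sep
    while len(out) < n:
        attempts += 1
        if attempts > 100000:
            raise ParameterError("cannot place peaks with the requested separation")
        pos = rng.uniform(lo + margin, hi - margin)
        if all(abs(pos - q) >= min_sep for q in placed):
            placed.append(pos)
            out.append(pos)
    return sorted(out)


def simulate_dataset(cfg: SimulationConfig | None = None) -> tuple[Dataset, GroundTruth]:
    """Generate a labelled raw dataset plus its ground truth."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mz_range
    grid = np.arange(lo, hi + cfg.grid_step / 2, cfg.grid_step)
    conditions = _condition_names(cfg.n_conditions)

    shared = _draw_positions(rng, cfg.n_shared_peaks, lo, hi,
                             cfg.min_peak_separation, [])
    placed = list(shared)
    biomarkers: dict[str, np.ndarray] = {}
    for cond in conditions:
        marks = _draw_positions(rng, cfg.n_biomarkers_per_condition, lo, hi,
                                cfg.min_peak_separation, placed)
        placed.extend(marks)
        biomarkers[cond] = np.array(marks)

    heights = {
        float(pos): float(rng.uniform(cfg.peak_height_min, cfg.peak_height_max))
        for pos in placed
    }
    baseline = cfg.baseline_amplitude * np.exp(-(grid - lo) / cfg.baseline_decay)

    dataset_conditions: dict[str, list[str]] = {}
    samples: dict[str, list[Spectrum]] = {}
    realized: dict[str, np.ndarray] = {}
    for cond in conditions:
        sample_ids = []
        for si in range(cfg.samples_per_condition):
            sid = f"{cond}{si + 1}"
            sample_ids.append(sid)
            positions = np.array(sorted(shared + list(biomarkers[cond])))
            reps: list[Spectrum] = []
            for ri in range(cfg.replicates_per_sample):
                spec_id = f"{sid}-r{ri + 1}"
                keep = rng.random(len(positions)) >= cfg.dropout
                present = positions[keep]
                signal = baseline.copy()
                for pos in present:
                    center = pos + rng.normal(0.0, cfg.mz_jitter_sigma)
                    height = heights[float(pos)] * rng.lognormal(0.0, cfg.height_cv)
                    window = np.abs(grid - center) <= 6 * cfg.peak_sigma
                    signal[window] += height * np.exp(
                        -0.5 * ((grid[window] - center) / cfg.peak_sigma) ** 2
                    )
                if cfg.noise_sigma > 0:
                    signal = signal + rng.normal(0.0, cfg.noise_sigma, len(grid))
                reps.append(
                    Spectrum(
                        id=spec_id, sample_id=sid, replicate_index=ri,
                        mz=grid.copy(), intensity=signal,
                    )
                )
                realized[spec_id] = present
            samples[sid] = reps
        dataset_conditions[cond] = sample_ids
    truth = GroundTruth(
        shared_mz=np.array(shared),
        biomarkers=biomarkers,
        peak_heights=heights,
        realized=realized,
    )
    return Dataset(conditions=dataset_conditions, samples=samples), truth


def write_dataset(dataset: Dataset, truth: GroundTruth, out_dir: str | Path) -> None:
    """Write a simulated dataset in the condition_dirs layout plus
    ``ground_truth.json``."""
    from .spectra_io import write_csv

    out_dir = Path(out_dir)
    for cond, sample_ids in dataset.conditions.items():
        for sid in sample_ids:
            sdir = out_dir / cond / sid
            sdir.mkdir(parents=True, exist_ok=True)
            for spec in dataset.samples[sid]:
                write_csv(spec, sdir / f"r{spec.replicate_index + 1}.csv")
    (out_dir / "ground_truth.json").write_text(truth.to_json())


# --------------------------------------------------------------------------
# End-to-end recovery check


@dataclass
class PipelineConfig:
    """Parameters of the standard discovery pipeline used for recovery
    checks: preprocessing defaults plus matching tolerances sized for a
    1 Da grid with sub-Da jitter (absolute windows of a couple of grid
    steps), POP-50 consensus and BH at q < 0.05."""

    intra_tolerance: float = 2.0  # Da, replicate matching
    inter_tolerance: float = 2.0  # Da, sample matching
    matcher: str = "forward"
    pop_threshold: float = 50.0
    n_rand: int = 10000
    q_threshold: float = 0.05
    match_tolerance: float = 3.0  # Da, tolerance when comparing to planted truth
    preprocess: "object" = None  # PreprocessConfig; default built lazily


def end_to_end_truth_check(
    cfg: SimulationConfig | None = None,
    pipeline: PipelineConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Run the full discovery pipeline on simulated data and score it
    against the planted truth.

    Returns a report with the fraction of planted biomarkers recovered at
    q < threshold (``recall``), the fraction of significant m/z values
    that correspond to a planted biomarker (``precision``), and the raw
    inter-label result table.
    """
    from .biomarker import inter_label
    from .matching import build_consensus, intersample_match
    from .preprocess import PreprocessConfig, preprocess_dataset

    cfg = cfg or SimulationConfig()
    pipeline = pipeline or PipelineConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**asdict(cfg), "seed": seed})
    dataset, truth = simulate_dataset(cfg)
    pre_cfg = pipeline.preprocess or PreprocessConfig()
    peaklists = preprocess_dataset(dataset, pre_cfg)
    consensus = [
        build_consensus(
            reps, sid, matcher=pipeline.matcher,
            tolerance=pipeline.intra_tolerance, unit="da",
            pop_threshold=pipeline.pop_threshold,
        )
        for sid, reps in peaklists.items()
    ]
    matrix = intersample_match(
        consensus, dataset.condition_of,
        matcher=pipeline.matcher, tolerance=pipeline.inter_tolerance,
        unit="da", mode="binary",
    )
    result = inter_label(matrix, n_rand=pipeline.n_rand, seed=cfg.seed)
    significant = result.loc[result["q"] < pipeline.q_threshold, "mz"].to_numpy()
    planted = truth.all_biomarkers()
    if len(planted):
        recovered = sum(
            bool(np.any(np.abs(significant - pos) <= pipeline.match_tolerance))
            for pos in planted
        )
        recall = recovered / len(planted)
    else:
        recall = float("nan")
    if len(significant):
        true_hits = sum(
            bool(len(planted)) and bool(
                np.any(np.abs(planted - mz) <= pipeline.match_tolerance)
            )
            for mz in significant
        )
        precision = true_hits / len(significant)
    else:
        precision = float("nan")
    false_positive_fraction = (
        float(np.mean(result["q"] < pipeline.q_threshold)) if len(planted) == 0 else None
    )
    return {
        "recall": recall,
        "precision": precision,
        "n_significant": int(len(significant)),
        "n_planted": int(len(planted)),
        "n_columns": int(len(result)),
        "false_positive_fraction": false_positive_fraction,
        "significant_mz": significant,
        "matrix": matrix,
        "table": result,
    }
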
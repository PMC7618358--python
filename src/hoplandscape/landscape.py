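"""Sort-fraction-weighted expression-score landscape.

Each sorted integration carries the fluorescence of the gate it was sorted
from, but gates represent unequal fractions of the original cell population.
The per-gate correction factor

    Fsort_P = ((R_P + 1) / T) / S_P * (m / r_P)

(recorded cells R_P with a +1 pseudo-count, total recorded T, sorted cells
S_P, and a replicate-imbalance factor m/r_P) converts each mapped
integration into an estimate of the population fraction it represents. The
windowed expression score is then the Fsort-weighted mean of gate
fluorescences over the integrations in the window, summed over gates P and
replicate experiments E:

    score_W = sum_E sum_P (Fsort_PE * N_WPE * Fluo_PE)
            / sum_E sum_P (Fsort_PE * N_WPE)

Windows are groups of consecutive step-bins; windows with fewer than
``min_integrations`` sorted integrations are masked. Confidence intervals
come from bootstrapping the genome-wide integration list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from hoplandscape.errors import ConfigurationError, DataIntegrityError, InvalidSpecError

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["chrom", "start", "end", "score", "n_integrations", "masked"]


@dataclass(frozen=True)
class SortedPopulation:
    """One FACS gate in one replicate experiment.

    ``fluo`` is the estimated fluorescence of hopped reporters in the gate
    (median of recorded events); ``recorded``/``total_recorded`` are the FACS
    accounting numbers R_P and T; ``sorted_cells`` is S_P; ``n_replicates``
    (r_P) and ``min_replicates`` (m) encode replicate imbalance for this
    cell line.
    """

    experiment: str
    gate: str
    fluo: float
    recorded: int
    total_recorded: int
    sorted_cells: int
    n_replicates: int = 1
    min_replicates: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.recorded <= self.total_recorded:
            raise InvalidSpecError("require 0 <= recorded <= total_recorded")
        if self.sorted_cells < 0:
            raise InvalidSpecError("sorted_cells must be >= 0")
        if not self.n_replicates >= self.min_replicates >= 1:
            raise InvalidSpecError("require n_replicates >= min_replicates >= 1")
        if not np.isfinite(self.fluo):
            raise InvalidSpecError("fluo must be finite")


@dataclass(frozen=True)
class WindowSpec:
    """Binning and windowing: ``step`` bp bins, ``window_bins`` bins per
    window, mask below ``min_integrations``. ``region`` is (chrom, start,
    end), 0-based half-open."""

    step: int
    window_bins: int
    region: tuple[str, int, int]
    min_integrations: int = 3

    def __post_init__(self) -> None:
        if self.step <= 0 or self.window_bins < 1 or self.min_integrations < 1:
            raise InvalidSpecError("step > 0, window_bins >= 1, min_integrations >= 1")
        chrom, start, end = self.region
        if start >= end:
            raise InvalidSpecError(f"empty region {chrom}:{start}-{end}")

    @property
    def n_bins(self) -> int:
        chrom, start, end = self.region
        return (end - start) // self.step

    @property
    def n_windows(self) -> int:
        return max(self.n_bins - self.window_bins + 1, 0)


@dataclass(frozen=True)
class DeletionShift:
    """A deletion interval (1-based inclusive) to fold out before scoring."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidSpecError("deletion start must be <= end")

    @property
    def width(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# population-level quantities


def estimate_gate_fluorescence(
    events: pd.DataFrame, gate_bounds: tuple[float, float], channel: str = "mTurq"
) -> float:
    """Median reporter intensity over recorded events inside the gate.

    Gate membership is half-open [lower, upper). Raises on an empty gate;
    the caller must then supply Fluo externally or drop the gate.
    """
    lo, hi = gate_bounds
    values = events[channel].to_numpy(dtype=float)
    in_gate = values[(values >= lo) & (values < hi)]
    if in_gate.size == 0:
        raise DataIntegrityError(f"no events in gate [{lo}, {hi}) for {channel}")
    return float(np.median(in_gate))


def sort_fraction(pop: SortedPopulation) -> float:
    """Fsort_P = ((R_P + 1) / T) / S_P * (m / r_P)."""
    if pop.total_recorded <= 0:
        raise InvalidSpecError("total_recorded must be positive")
    if pop.sorted_cells <= 0:
        raise InvalidSpecError(
            "sorted_cells must be positive; drop S_P = 0 populations upstream"
        )
    frac = (pop.recorded + 1) / pop.total_recorded / pop.sorted_cells
    return frac * pop.min_replicates / pop.n_replicates


def _population_index(
    populations: list[SortedPopulation],
) -> tuple[dict[tuple[str, str], int], np.ndarray, np.ndarray]:
    """Map (experiment, gate) -> column index, with Fsort and Fluo arrays.

    Populations with zero sorted cells are dropped with a warning: no
    integration can originate from them.
    """
    usable = []
    for pop in populations:
        if pop.sorted_cells == 0:
            logger.warning(
                "dropping population (%s, %s): zero sorted cells", pop.experiment, pop.gate
            )
            continue
        usable.append(pop)
    index: dict[tuple[str, str], int] = {}
    for pop in usable:
        key = (pop.experiment, pop.gate)
        if key in index:
            raise ConfigurationError(f"duplicate population for {key}")
        index[key] = len(index)
    fsort = np.array([sort_fraction(p) for p in usable])
    fluo = np.array([p.fluo for p in usable])
    return index, fsort, fluo


# ---------------------------------------------------------------------------
# counting

def bin_counts(
    integrations: pd.DataFrame, spec: WindowSpec, strand: str = "both"
) -> pd.DataFrame:
    """Count integrations per step-bin per (gate, experiment).

    Bins are half-open [start, start + step) on the 0-based axis; an
    integration's 1-based ``position`` falls in bin ``(position - 1 -
    region_start) // step``. Integrations outside the region are logged and
    counted in no bin. Returns columns bin/experiment/gate/count.
    """
    chrom, rstart, rend = spec.region
    df = integrations
    if strand == "forward":
        df = df[df["orientation"] == "+"]
    elif strand == "reverse":
        df = df[df["orientation"] == "-"]
    elif strand != "both":
        raise ConfigurationError(f"unknown strand selection {strand!r}")

    pos0 = df["position"].to_numpy(dtype=np.int64) - 1
    in_region = (
        (df["chrom"] == chrom).to_numpy() & (pos0 >= rstart) & (pos0 < rstart + spec.n_bins * spec.step)
    )
    n_out = int((~in_region).sum())
    if n_out:
        logger.info("%d integrations outside the scored region were not counted", n_out)
    sub = df[in_region].copy()
    sub["bin"] = (pos0[in_region] - rstart) // spec.step
    counts = (
        sub.groupby(["bin", "replicate", "pool"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"replicate": "experiment", "pool": "gate"})
    )
    return counts


def _counts_matrix(
    counts: pd.DataFrame, spec: WindowSpec, index: dict[tuple[str, str], int]
) -> np.ndarray:
    mat = np.zeros((spec.n_bins, len(index)))
    for _, row in counts.iterrows():
        key = (row["experiment"], row["gate"])
        if key not in index:
            raise DataIntegrityError(f"counts reference unknown population {key}")
        mat[int(row["bin"]), index[key]] += row["count"]
    return mat


def _sliding_sum(arr: np.ndarray, window: int) -> np.ndarray:
    """Sum over each run of ``window`` consecutive leading-axis entries."""
    c = np.cumsum(arr, axis=0)
    c = np.concatenate([np.zeros_like(c[:1]), c], axis=0)
    return c[window:] - c[:-window]


def _score_from_matrix(
    mat: np.ndarray, fsort: np.ndarray, fluo: np.ndarray, window_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed score and integration totals from a bins-x-populations matrix."""
    num = _sliding_sum(mat @ (fsort * fluo), window_bins)
    den = _sliding_sum(mat @ fsort, window_bins)
    n_w = _sliding_sum(mat.sum(axis=1), window_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(den > 0, num / den, np.nan)
    return score, n_w


def _window_frame(spec: WindowSpec, score, n_w) -> pd.DataFrame:
    chrom, rstart, _ = spec.region
    w = np.arange(spec.n_windows)
    starts = rstart + w * spec.step
    ends = starts + spec.window_bins * spec.step
    masked = (n_w < spec.min_integrations) | ~np.isfinite(score)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "score": score,
            "n_integrations": n_w.astype(np.int64),
            "masked": masked,
        }
    )


def expression_score(
    counts: pd.DataFrame,
    populations: list[SortedPopulation],
    spec: WindowSpec,
) -> pd.DataFrame:
    """Windowed expression-score track (score and integration counts).

    A window covers ``window_bins`` consecutive step-bins and slides one bin
    at a time; the reported interval is [first bin start, last bin end),
    half-open. Windows with fewer than ``min_integrations`` integrations (or
    no weighted support) are masked.
    """
    index, fsort, fluo = _population_index(populations)
    mat = _counts_matrix(counts, spec, index)
    score, n_w = _score_from_matrix(mat, fsort, fluo, spec.window_bins)
    return _window_frame(spec, score, n_w)


# ---------------------------------------------------------------------------
# deletion shift


def apply_deletion_shift(
    integrations: pd.DataFrame, shift: DeletionShift
) -> pd.DataFrame:
    """Fold a deletion out of the coordinate axis before scoring.

    Positions strictly after the deletion end move left by the deletion
    width; an integration inside the deleted interval is a data
    inconsistency (the sequence does not exist in that cell line).
    """
    out = integrations.copy()
    on_chrom = out["chrom"] == shift.chrom
    pos = out["position"]
    inside = on_chrom & (pos >= shift.start) & (pos <= shift.end)
    if inside.any():
        raise DataIntegrityError(
            f"{int(inside.sum())} integrations lie inside the deletion {shift}"
        )
    after = on_chrom & (pos > shift.end)
    out.loc[after, "position"] = pos[after] - shift.width
    return out


def unshift_track(track: pd.DataFrame, shift: DeletionShift) -> pd.DataFrame:
    """Restore genomic coordinates of windows computed on shifted positions.

    Windows at or beyond the deletion start move right by the deletion
    width, re-opening the gap in the track.
    """
    out = track.copy()
    start0 = shift.start - 1  # deletion start on the 0-based axis
    on_chrom = out["chrom"] == shift.chrom
    after = on_chrom & (out["start"] >= start0)
    out.loc[after, "start"] = out.loc[after, "start"] + shift.width
    out.loc[after, "end"] = out.loc[after, "end"] + shift.width
    return out


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_track(
    integrations: pd.DataFrame,
    populations: list[SortedPopulation],
    spec: WindowSpec,
    B: int = 5000,
    seed: int = 0,
    strand: str = "both",
) -> pd.DataFrame:
    """Expression track with bootstrap median and 95% interval.

    The genome-wide integration list is resampled with replacement (same
    size, population labels travelling with each integration) ``B`` times;
    the score track is recomputed per resample. Reported per window: the
    observed score, the median of bootstrap scores and their 2.5th/97.5th
    percentiles (linear interpolation). Masking uses the observed counts.
    """
    if B < 1:
        raise InvalidSpecError("B must be >= 1")
    index, fsort, fluo = _population_index(populations)
    counts = bin_counts(integrations, spec, strand=strand)
    mat = _counts_matrix(counts, spec, index)
    score, n_w = _score_from_matrix(mat, fsort, fluo, spec.window_bins)
    track = _window_frame(spec, score, n_w)

    # per-integration (bin, population) ids over the full list; resampling a
    # row outside the region or with a dropped population contributes nothing
    chrom, rstart, _ = spec.region
    df = integrations
    if strand == "forward":
        df = df[df["orientation"] == "+"]
    elif strand == "reverse":
        df = df[df["orientation"] == "-"]
    pos0 = df["position"].to_numpy(dtype=np.int64) - 1
    bin_idx = (pos0 - rstart) // spec.step
    in_region = (
        (df["chrom"] == chrom).to_numpy()
        & (bin_idx >= 0)
        & (bin_idx < spec.n_bins)
    )
    keys = list(zip(df["replicate"], df["pool"]))
    pop_idx = np.array([index.get(k, -1) for k in keys])
    valid = in_region & (pop_idx >= 0)
    flat = np.where(valid, bin_idx * len(index) + pop_idx, -1)

    n_total = len(df)
    n_pop = len(index)
    rng = np.random.default_rng(seed)
    boot_scores = np.empty((B, spec.n_windows))
    size = spec.n_bins * n_pop
    for b in range(B):
        resample = rng.integers(0, n_total, size=n_total) if n_total else np.array([], int)
        ids = flat[resample]
        ids = ids[ids >= 0]
        mat_b = np.bincount(ids, minlength=size).reshape(spec.n_bins, n_pop).astype(float)
        boot_scores[b], _ = _score_from_matrix(mat_b, fsort, fluo, spec.window_bins)

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # windows with no weighted support are NaN in every resample
        warnings.filterwarnings("ignore", message="All-NaN slice")
        track["boot_median"] = np.nanpercentile(boot_scores, 50, axis=0)
        track["ci_low"] = np.nanpercentile(boot_scores, 2.5, axis=0)
        track["ci_high"] = np.nanpercentile(boot_scores, 97.5, axis=0)
    track.loc[track["masked"], ["boot_median", "ci_low", "ci_high"]] = np.nan
    return track


# ---------------------------------------------------------------------------
# pooling


def combine_experiments(
    experiments: list[tuple[pd.DataFrame, list[SortedPopulation]]],
) -> tuple[pd.DataFrame, list[SortedPopulation]]:
    """Pool replicate experiments for a combined score.

    Integration tables are concatenated (identical integrations in multiple
    pools stay separate data points); populations keep their per-experiment
    Fsort and Fluo and are only summed inside the score formula. Experiment
    labels must not collide between tables.
    """
    seen: set[tuple[str, str]] = set()
    all_ints, all_pops = [], []
    for integrations, populations in experiments:
        for pop in populations:
            key = (pop.experiment, pop.gate)
            if key in seen:
                raise ConfigurationError(
                    f"population {key} appears in more than one experiment table"
                )
            seen.add(key)
        all_ints.append(integrations)
        all_pops.extend(populations)
    pooled = pd.concat(all_ints, ignore_index=True) if all_ints else pd.DataFrame()
    return pooled, all_pops
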
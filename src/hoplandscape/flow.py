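"""Flow-cytometry normalization chain.

The comparison of reporter (mTurquoise2) and allele-tagged Sox2 (mCherry,
eGFP) levels across clones and measurement days proceeds as:

1. spectral spillover correction (a fixed fraction of the mTurq signal is
   subtracted from the eGFP channel);
2. autofluorescence correction: subtract the median fluorescence intensity
   (MFI) of a non-fluorescent control line, per channel;
3. normalization by the corrected eGFP of the same sample (adjusts for
   global effects on Sox2 expression);
4. scaling by the same-day measurement of a standard reporter line, yielding
   relative expression comparable between days.

Negative intensities are legitimate (background subtraction); only a
non-positive corrected eGFP is fatal for normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hoplandscape.errors import DataIntegrityError, InvalidSpecError

logger = logging.getLogger(__name__)

CHANNELS = ("mTurq", "eGFP", "mCherry")


@dataclass(frozen=True)
class NormalizationContext:
    """Per-measurement-day normalization inputs.

    ``control_mfis``: MFIs of the non-fluorescent control line (autofluorescence).
    ``reference_mfis``: raw MFIs of the standard reporter line measured the
    same day. ``same_day_control`` is False when the wild-type control had to
    be borrowed from a different day; this is carried explicitly, never
    silently.
    """

    control_mfis: dict[str, float]
    reference_mfis: dict[str, float]
    spillover: float = 0.016
    same_day_control: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.spillover < 1:
            raise InvalidSpecError("spillover must lie in [0, 1)")
        for panel in (self.control_mfis, self.reference_mfis):
            missing = set(CHANNELS) - set(panel)
            if missing:
                raise InvalidSpecError(f"missing channels in context: {sorted(missing)}")


def spillover_correct(events: pd.DataFrame, fraction: float = 0.016) -> pd.DataFrame:
    """Subtract ``fraction`` of the mTurq signal from the eGFP channel."""
    out = events.copy()
    out["eGFP"] = out["eGFP"] - fraction * out["mTurq"]
    return out


def compute_mfi(events: pd.DataFrame, by: str = "sample") -> pd.DataFrame:
    """Median fluorescence intensity per sample per channel."""
    return events.groupby(by, sort=True)[list(CHANNELS)].median().reset_index()


def _corrected(mfis: dict[str, float], ctx: NormalizationContext) -> dict[str, float]:
    return {ch: mfis[ch] - ctx.control_mfis[ch] for ch in CHANNELS}


def normalize_clone(
    mfis: dict[str, float], ctx: NormalizationContext
) -> dict[str, float]:
    """Relative expression of one clone from its channel MFIs.

    Returns ``mTurq_rel`` and ``mCherry_rel`` (eGFP-normalized, then scaled
    to the same-day reference line) plus the not-normalized variants
    (``*_rel_raw``) that skip the eGFP division.
    """
    corr = _corrected(mfis, ctx)
    ref = _corrected(ctx.reference_mfis, ctx)
    if corr["eGFP"] <= 0 or ref["eGFP"] <= 0:
        raise DataIntegrityError("corrected eGFP must be positive for normalization")
    out: dict[str, float] = {}
    for ch in ("mTurq", "mCherry"):
        normalized = corr[ch] / corr["eGFP"]
        ref_normalized = ref[ch] / ref["eGFP"]
        if ref_normalized == 0:
            raise DataIntegrityError(f"reference {ch} is zero; relative value undefined")
        out[f"{ch}_rel"] = normalized / ref_normalized
        if ref[ch] == 0:
            raise DataIntegrityError(f"reference corrected {ch} is zero")
        out[f"{ch}_rel_raw"] = corr[ch] / ref[ch]
    return out


def per_cell_relative_expression(
    events: pd.DataFrame,
    ctx: NormalizationContext,
    gates_kept: set[str] = frozenset({"P2", "P3", "P4"}),
) -> pd.DataFrame:
    """Per-cell relative mTurq and mCherry expression.

    Per cell: subtract the control MFIs, divide mTurq and mCherry by that
    cell's corrected eGFP, then scale to the reference line's corrected,
    eGFP-normalized MFIs. Cells outside ``gates_kept`` are dropped (the top
    and bottom gates are dominated by non-mobilized reporters); cells with
    corrected eGFP <= 0 are dropped with a logged count.
    """
    if "gate" not in events.columns:
        raise DataIntegrityError("per-cell normalization requires a gate column")
    sub = events[events["gate"].isin(gates_kept)].copy()
    for ch in CHANNELS:
        sub[ch] = sub[ch] - ctx.control_mfis[ch]
    bad = sub["eGFP"] <= 0
    if bad.any():
        logger.info("dropping %d cells with non-positive corrected eGFP", int(bad.sum()))
    sub = sub[~bad]
    ref = _corrected(ctx.reference_mfis, ctx)
    if ref["eGFP"] <= 0:
        raise DataIntegrityError("reference corrected eGFP must be positive")
    out = sub[[c for c in ("sample", "gate") if c in sub.columns]].copy()
    for ch in ("mTurq", "mCherry"):
        ref_norm = ref[ch] / ref["eGFP"]
        if ref_norm == 0:
            raise DataIntegrityError(f"reference {ch} is zero; relative value undefined")
        out[f"{ch}_rel"] = (sub[ch] / sub["eGFP"]) / ref_norm
    return out.reset_index(drop=True)


def gate_thresholds(
    wt_events: pd.DataFrame, channels: tuple[str, ...] = ("eGFP", "mCherry")
) -> dict[str, tuple[float, float]]:
    """Negative/positive expression thresholds from a wild-type control.

    Negative threshold: 99th percentile of the WT channel (linear
    interpolation); positive threshold: 1.5 times that value. Warns below
    100 events.
    """
    if wt_events.empty:
        raise DataIntegrityError("empty wild-type control table")
    if len(wt_events) < 100:
        warnings.warn(
            f"only {len(wt_events)} WT events; thresholds may be unstable",
            stacklevel=2,
        )
    out = {}
    for ch in channels:
        neg = float(np.percentile(wt_events[ch].to_numpy(dtype=float), 99))
        out[ch] = (neg, 1.5 * neg)
    return out


def detect_expression_mode(
    events: pd.DataFrame,
    channel: str = "mTurq",
    cofactor: float = 150.0,
    grid_points: int = 512,
    min_events: int = 50,
) -> float:
    """Dominant expression mode of a (possibly bimodal) intensity distribution.

    Intensities are display-transformed with arcsinh(x / cofactor) — a
    biexponential-family transform; the density is estimated with a Gaussian
    kernel (Silverman bandwidth) on a uniform grid, local maxima are located
    by discrete sign change, the two highest-density peaks are kept, and the
    peak at the higher transformed value is returned, back-transformed to
    intensity units.
    """
    values = events[channel].to_numpy(dtype=float)
    if values.size < min_events:
        raise DataIntegrityError(
            f"{values.size} events < required minimum {min_events}"
        )
    x = np.arcsinh(values / cofactor)
    if np.ptp(x) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_points)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])) + 1
    if interior.size == 0:
        interior = np.array([int(np.argmax(dens))])
    top_two = interior[np.argsort(dens[interior])[::-1][:2]]
    chosen = grid[top_two].max()  # the higher-expression peak of the top two
    return float(np.sinh(chosen) * cofactor)


def average_sibling_clones(
    clones: pd.DataFrame,
    keys: tuple[str, ...] = ("position", "orientation", "experiment"),
) -> pd.DataFrame:
    """Average clones presumed to derive from a single hopping event.

    Rows sharing (position, orientation, experiment) are replaced by the
    arithmetic mean of their numeric columns.
    """
    keep = [k for k in keys if k in clones.columns]
    if len(keep) != len(keys):
        raise DataIntegrityError(f"missing key columns: {set(keys) - set(keep)}")
    numeric = clones.select_dtypes(include=[np.number]).columns.difference(keep)
    out = clones.groupby(list(keys), sort=True, as_index=False)[list(numeric)].mean()
    return out
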
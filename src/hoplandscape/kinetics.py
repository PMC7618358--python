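"""RNA decay kinetics and reporter RNA levels from qPCR Ct tables.

After transcription shutoff (actinomycin D), RNA abundance follows one-phase
exponential decay, abundance(t) = Y0 * exp(-k t). Abundances are measured by
qPCR relative to the t = 0 sample as 2^(-dCt); the decay constant k comes
from nonlinear least squares per replicate and the half-life is ln(2)/k.

Reporter steady-state level relative to the two endogenous alleles uses the
mean dCt against both allele targets, with a 1.96-sd normal interval on the
Ct scale back-transformed through 2^(-x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from hoplandscape.errors import DataIntegrityError, InvalidSpecError

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential decay fit: abundance = Y0 * exp(-k t)."""

    y0: float
    k: float
    rss: float
    n_points: int

    @property
    def half_life_hours(self) -> float:
        return half_life(self)


def ct_to_abundance(series: pd.DataFrame, target: str | None = None) -> pd.DataFrame:
    """Relative abundance per timepoint from technical-replicate Cts.

    ``series`` is long-format (timepoint_h, ct[, target]). Technical
    measurements at one timepoint are averaged on the Ct scale; dCt is taken
    against the mean Ct at t = 0 and abundance = 2^(-dCt), so abundance at
    t = 0 is exactly 1.
    """
    df = series
    if target is not None:
        df = df[df["target"] == target]
    if df.empty:
        raise DataIntegrityError("no Ct measurements for the requested target")
    mean_ct = df.groupby("timepoint_h", sort=True)["ct"].mean()
    if 0.0 not in mean_ct.index:
        raise InvalidSpecError("t=0 measurement required as normalization anchor")
    delta = mean_ct - mean_ct.loc[0.0]
    out = pd.DataFrame(
        {"timepoint_h": mean_ct.index.to_numpy(), "abundance": 2.0 ** (-delta.to_numpy())}
    )
    return out.reset_index(drop=True)


def fit_decay(abundances, timepoints) -> DecayFit:
    """Nonlinear least squares fit of Y0 * exp(-k t).

    Initial values are closed-form: Y0 from the earliest timepoint and k
    from the least-squares slope of log-abundance against time. Residuals
    are unweighted, on the abundance scale.
    """
    y = np.asarray(abundances, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if y.size != t.size:
        raise DataIntegrityError("abundances and timepoints differ in length")
    if y.size < 3:
        raise DataIntegrityError("at least 3 timepoints required for the fit")
    if (y <= 0).any():
        raise DataIntegrityError("abundances must be positive")

    order = np.argsort(t)
    t, y = t[order], y[order]
    y0_init = y[0]
    slope = np.polyfit(t, np.log(y), 1)[0]
    k_init = max(-slope, 1e-9)

    def model(tt, y0, k):
        return y0 * np.exp(-k * tt)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=(y0_init, k_init), maxfev=10_000,
            bounds=((0.0, 0.0), (np.inf, np.inf)),
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise DataIntegrityError(
            f"decay fit did not converge (init Y0={y0_init:.4g}, k={k_init:.4g}, "
            f"n={y.size})"
        ) from exc
    y0_hat, k_hat = float(popt[0]), float(popt[1])
    if k_hat * (t[-1] - t[0]) < 1e-6:
        k_hat = 0.0  # decay unresolvable over the observed span: flat

    rss = float(np.sum((y - model(t, y0_hat, k_hat)) ** 2))
    return DecayFit(y0=y0_hat, k=k_hat, rss=rss, n_points=int(y.size))


def half_life(fit: DecayFit) -> float:
    """Half-life in hours, ln(2)/k; undefined for k <= 0."""
    if fit.k <= 0:
        raise DataIntegrityError(f"half-life undefined for k = {fit.k}")
    return LN2 / fit.k


def fit_decay_per_replicate(
    cts: pd.DataFrame, target: str
) -> pd.DataFrame:
    """Fit the decay model independently for every replicate of one target.

    Returns one row per replicate with Y0, k, half-life and RSS, plus the
    across-replicate mean k and mean half-life in ``df.attrs``.
    """
    rows = []
    for rep, sub in cts[cts["target"] == target].groupby("replicate", sort=True):
        ab = ct_to_abundance(sub)
        fit = fit_decay(ab["abundance"], ab["timepoint_h"])
        rows.append(
            {
                "replicate": rep,
                "y0": fit.y0,
                "k_per_hour": fit.k,
                "half_life_h": fit.half_life_hours if fit.k > 0 else np.nan,
                "rss": fit.rss,
                "n_points": fit.n_points,
            }
        )
    if not rows:
        raise DataIntegrityError(f"no Ct data for target {target!r}")
    out = pd.DataFrame(rows)
    out.attrs["mean_k"] = float(out["k_per_hour"].mean())
    out.attrs["mean_half_life_h"] = float(out["half_life_h"].mean())
    return out


def relative_level_delta_ct(
    ct_mturq, ct_gfp, ct_mcherry
) -> tuple[float, float | None, float | None]:
    """Reporter RNA level relative to the two endogenous alleles.

    Per replicate: dCt = ((Ct_mTurq - Ct_GFP) + (Ct_mTurq - Ct_mCherry)) / 2.
    The level is 2^(-mean dCt); the 95% interval is 2^(-(mean +- 1.96 sd))
    over replicates (sd with n-1 denominator). With a single replicate only
    the level is defined.
    """
    turq = np.asarray(ct_mturq, dtype=float)
    gfp = np.asarray(ct_gfp, dtype=float)
    cherry = np.asarray(ct_mcherry, dtype=float)
    if not turq.size == gfp.size == cherry.size:
        raise DataIntegrityError("per-replicate Ct vectors differ in length")
    if turq.size == 0:
        raise DataIntegrityError("at least one replicate required")
    delta = ((turq - gfp) + (turq - cherry)) / 2.0
    mean = float(delta.mean())
    level = float(2.0 ** (-mean))
    if delta.size < 2:
        return level, None, None
    sd = float(delta.std(ddof=1))
    ci_low = float(2.0 ** (-(mean + 1.96 * sd)))
    ci_high = float(2.0 ** (-(mean - 1.96 * sd)))
    return level, ci_low, ci_high
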
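"""Virtual 4C, insulation scores and score-contact correlation.

Operates on symmetric binned contact matrices (e.g. region-capture Micro-C at
1 kb resolution). The diagonal (self-ligation) and viewpoint self-contacts are
excluded from every mean; missing entries (NaN) are treated as absent, not
zero, since balanced matrices carry masked bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from hoplandscape.errors import DataIntegrityError, InvalidSpecError
from hoplandscape.intervals import GenomicInterval


@dataclass
class ContactMatrix:
    """A symmetric binned contact matrix with its genomic bin table.

    ``bins`` has columns chrom/start/end (0-based half-open, uniform width);
    ``values`` is the dense symmetric matrix in arbitrary balanced units.
    """

    bins: pd.DataFrame
    values: np.ndarray
    resolution: int

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.values.shape != (n, n):
            raise InvalidSpecError(
                f"matrix shape {self.values.shape} does not match {n} bins"
            )
        widths = (self.bins["end"] - self.bins["start"]).to_numpy()
        if not (widths == self.resolution).all():
            raise InvalidSpecError("bin widths must all equal the resolution")
        with np.errstate(invalid="ignore"):
            finite = np.isfinite(self.values)
            sym_ok = np.allclose(
                self.values[finite & finite.T & np.isfinite(self.values.T)],
                self.values.T[finite & finite.T & np.isfinite(self.values.T)],
                rtol=1e-6,
            )
            if not sym_ok:
                raise DataIntegrityError("contact matrix is not symmetric")
            if np.nanmin(self.values) < 0:
                raise DataIntegrityError("contact values must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def bin_centers(self) -> np.ndarray:
        return (self.bins["start"].to_numpy() + self.bins["end"].to_numpy()) / 2

    def bins_overlapping(self, interval: GenomicInterval) -> np.ndarray:
        """Indices of bins overlapping a 0-based half-open interval."""
        on_chrom = self.bins["chrom"] == interval.chrom
        overlap = (self.bins["start"] < interval.end) & (self.bins["end"] > interval.start)
        return np.flatnonzero((on_chrom & overlap).to_numpy())

    # -- text I/O (bins BED + triplet TSV) ---------------------------------

    def to_files(self, bins_path: str | Path, triplets_path: str | Path) -> None:
        """Write the bin table (BED) and upper-triangle triplets (TSV)."""
        self.bins.to_csv(bins_path, sep="\t", header=False, index=False)
        iu = np.triu_indices(self.n_bins)
        vals = self.values[iu]
        keep = np.isfinite(vals) & (vals != 0)
        trip = pd.DataFrame(
            {"bin_i": iu[0][keep], "bin_j": iu[1][keep], "value": vals[keep]}
        )
        trip.to_csv(triplets_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, bins_path: str | Path, triplets_path: str | Path) -> "ContactMatrix":
        bins = pd.read_csv(
            bins_path, sep="\t", header=None, names=["chrom", "start", "end"]
        )
        resolution = int(bins["end"].iloc[0] - bins["start"].iloc[0])
        trip = pd.read_csv(triplets_path, sep="\t")
        n = len(bins)
        values = np.zeros((n, n))
        i = trip["bin_i"].to_numpy(dtype=int)
        j = trip["bin_j"].to_numpy(dtype=int)
        v = trip["value"].to_numpy(dtype=float)
        values[i, j] = v
        values[j, i] = v
        return cls(bins=bins, values=values, resolution=resolution)

    @classmethod
    def from_dense(
        cls, bins: pd.DataFrame, dense_path: str | Path
    ) -> "ContactMatrix":
        values = np.loadtxt(dense_path)
        resolution = int(bins["end"].iloc[0] - bins["start"].iloc[0])
        return cls(bins=bins, values=values, resolution=resolution)


def virtual_4c(matrix: ContactMatrix, viewpoint: GenomicInterval) -> pd.DataFrame:
    """One-viewpoint contact profile.

    Per target bin, the mean contact with the viewpoint bins, NaNs excluded.
    Viewpoint bins themselves are flagged and carry no value.
    Returns bins with columns chrom/start/end/contact/is_viewpoint.
    """
    vp_bins = matrix.bins_overlapping(viewpoint)
    if vp_bins.size == 0:
        raise DataIntegrityError(f"viewpoint {viewpoint} overlaps no matrix bin")
    rows = matrix.values[vp_bins, :].astype(float).copy()
    # exclude viewpoint self-contacts (incl. diagonal) from the mean
    rows[:, vp_bins] = np.nan
    defined = np.isfinite(rows)
    n_def = defined.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(n_def > 0, np.nansum(np.where(defined, rows, 0.0), axis=0), np.nan)
        profile = profile / np.where(n_def > 0, n_def, 1)
    out = matrix.bins.copy()
    out["contact"] = profile
    out["is_viewpoint"] = False
    out.loc[out.index[vp_bins], "contact"] = np.nan
    out.loc[out.index[vp_bins], "is_viewpoint"] = True
    return out


def insulation_score(matrix: ContactMatrix, window_bins: int = 20) -> pd.DataFrame:
    """Diamond insulation track, log2-normalized to the region mean.

    ``raw(i)`` is the mean contact between the ``window_bins`` bins upstream
    and the ``window_bins`` bins downstream of bin *i* (the diagonal is never
    inside this window). The track is ``log2(raw / mean(raw))`` over defined
    bins; bins within ``window_bins`` of an edge are undefined (NaN).
    """
    n = matrix.n_bins
    if n <= 2 * window_bins:
        raise InvalidSpecError(
            f"matrix with {n} bins too small for window of {window_bins} bins"
        )
    raw = np.full(n, np.nan)
    v = matrix.values
    for i in range(window_bins, n - window_bins):
        block = v[i - window_bins : i, i + 1 : i + 1 + window_bins]
        with np.errstate(invalid="ignore"):
            raw[i] = np.nanmean(block)
    defined = np.isfinite(raw)
    mean_raw = np.nanmean(raw[defined])
    track = np.full(n, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        track[defined] = np.log2(raw[defined] / mean_raw)
    out = matrix.bins.copy()
    out["insulation"] = track
    return out


def correlate_score_with_contact(
    track: pd.DataFrame,
    profile: pd.DataFrame,
    viewpoint: GenomicInterval,
    min_integrations: int = 3,
) -> tuple[float, float, int]:
    """Spearman correlation of the expression score with contact and distance.

    ``track`` is a bin-level expression track (columns start/end/score/
    n_integrations/masked) on the same bin grid as ``profile`` (the virtual
    4C output). Bins used are unmasked, carry at least ``min_integrations``
    integrations and a defined contact value. Distance is center-to-center
    from each bin to the viewpoint. Returns (rho_contact, rho_distance,
    n_bins_used).
    """
    if len(track) != len(profile):
        raise DataIntegrityError("track and profile are not on the same bin grid")
    if not (track["start"].to_numpy() == profile["start"].to_numpy()).all():
        raise DataIntegrityError("track and profile bin starts differ")

    score = track["score"].to_numpy(dtype=float)
    n_int = track["n_integrations"].to_numpy()
    contact = profile["contact"].to_numpy(dtype=float)
    usable = (
        (n_int >= min_integrations)
        & ~track["masked"].to_numpy(dtype=bool)
        & np.isfinite(contact)
        & np.isfinite(score)
    )
    n_used = int(usable.sum())
    if n_used < 3:
        raise DataIntegrityError(
            f"only {n_used} usable bins; need at least 3 for a correlation"
        )
    centers = (track["start"].to_numpy() + track["end"].to_numpy()) / 2
    distance = np.abs(centers - viewpoint.center)
    rho_contact = stats.spearmanr(score[usable], contact[usable]).statistic
    rho_distance = stats.spearmanr(score[usable], distance[usable]).statistic
    return float(rho_contact), float(rho_distance), n_used
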
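"""Integration calling from junction-read tables.

Turns tagmentation junction reads (one row per read of an ITR-genome
junction) into called integrations per sorted pool, and into insertion or
deletion genotypes per clonal cell line.

Filtering rules, in order:

* reads require mapping quality >= 10;
* reads are grouped by (chrom, position, orientation, pool, replicate); a
  group's unique-read count is the number of distinct fragment ends
  (tagmentation duplicates share fragment ends);
* sorted pools keep integrations with >= 2 unique reads; the top expression
  gate additionally requires support from both ITR sides; large unsorted
  pools keep anything with >= 1 read;
* positions matching known contaminant/launch-pad coordinates are removed,
  except the launch pad the reporter was actually mobilized from;
* clonal libraries require >= 10 unique reads per candidate location, drop
  candidates below 20% (strictly) of the top location's count, and classify:
  exactly one dual-ITR location -> insertion; exactly two single-ITR
  locations, one per side -> hopping-induced deletion; anything else is
  flagged for manual review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hoplandscape.errors import ConfigurationError, DataIntegrityError

READ_COLUMNS = [
    "read_id", "pool", "replicate", "chrom", "position", "orientation",
    "itr_side", "mapq", "fragment_end",
]

INTEGRATION_COLUMNS = [
    "chrom", "position", "orientation", "unique_reads", "reads_itr5",
    "reads_itr3", "pool", "replicate",
]


@dataclass(frozen=True)
class Blacklist:
    """Coordinates excluded as PCR contamination or launch-pad artifacts.

    ``intervals`` are 1-based inclusive; single coordinates are width-1
    intervals. A position equal to ``origin_launchpad`` (the launch pad the
    reporter was mobilized from in this experiment) is never excluded.
    """

    intervals: tuple[tuple[str, int, int], ...]
    origin_launchpad: int | None = None

    def covers(self, chrom: str, position: int) -> bool:
        if self.origin_launchpad is not None and position == self.origin_launchpad:
            return False
        return any(
            c == chrom and start <= position <= end for c, start, end in self.intervals
        )


def default_blacklist(origin_launchpad: int | None = None) -> Blacklist:
    """Known contaminant and launch-pad coordinates on chr3 (mm10)."""
    return Blacklist(
        intervals=(
            ("chr3", 34_721_183, 34_721_192),  # -39 kb launch site
            ("chr3", 25_018_987, 25_018_987),  # earlier-derived hopped clone
            ("chr3", 35_232_946, 35_232_946),  # earlier-derived hopped clone
            ("chr3", 34_598_479, 34_598_479),  # -161 kb launch pad
        ),
        origin_launchpad=origin_launchpad,
    )


@dataclass
class CloneCall:
    """Genotype call for one clonal library."""

    verdict: str  # insertion | deletion | review | fail
    insertion_site: pd.Series | None = None
    deletion_interval: tuple[str, int, int] | None = None
    supporting_locations: pd.DataFrame = field(default_factory=pd.DataFrame)
    reason: str = ""


# ---------------------------------------------------------------------------
# read-level and pool-level filters


def filter_reads(reads: pd.DataFrame, min_mapq: int = 10) -> pd.DataFrame:
    """Keep reads with mapping quality >= ``min_mapq``; order preserved."""
    return reads[reads["mapq"] >= min_mapq].reset_index(drop=True)


def collapse_to_integrations(reads: pd.DataFrame) -> pd.DataFrame:
    """Group reads into integrations.

    Identity is (chrom, position, orientation, pool, replicate). The
    unique-read count is the number of distinct fragment ends in the group;
    ITR-side counts are raw read tallies.
    """
    if reads.empty:
        return pd.DataFrame(columns=INTEGRATION_COLUMNS)
    grouped = reads.groupby(
        ["chrom", "position", "orientation", "pool", "replicate"], sort=True
    )
    out = grouped.agg(
        unique_reads=("fragment_end", "nunique"),
        reads_itr5=("itr_side", lambda s: int((s == "ITR5").sum())),
        reads_itr3=("itr_side", lambda s: int((s == "ITR3").sum())),
    ).reset_index()
    return out[INTEGRATION_COLUMNS]


def filter_pool_integrations(
    integrations: pd.DataFrame, pool_class: str
) -> pd.DataFrame:
    """Apply the per-pool retention rule.

    sorted: >= 2 unique reads. top_gate: additionally >= 1 read from each
    ITR side (guards against deletion clones masquerading as high
    expressors). unsorted: >= 1 read.
    """
    if pool_class == "sorted":
        keep = integrations["unique_reads"] >= 2
    elif pool_class == "top_gate":
        keep = (
            (integrations["unique_reads"] >= 2)
            & (integrations["reads_itr5"] >= 1)
            & (integrations["reads_itr3"] >= 1)
        )
    elif pool_class == "unsorted":
        keep = integrations["unique_reads"] >= 1
    else:
        raise ConfigurationError(f"unknown pool_class {pool_class!r}")
    return integrations[keep].reset_index(drop=True)


def apply_blacklist(integrations: pd.DataFrame, blacklist: Blacklist) -> pd.DataFrame:
    """Remove integrations at blacklisted coordinates (origin pad exempt)."""
    if integrations.empty:
        return integrations.reset_index(drop=True)
    drop = integrations.apply(
        lambda row: blacklist.covers(row["chrom"], int(row["position"])), axis=1
    )
    return integrations[~drop].reset_index(drop=True)


# ---------------------------------------------------------------------------
# clone genotyping


def _clone_candidates(reads: pd.DataFrame, min_unique: int, top_fraction: float):
    """Candidate locations for a clonal library, after both clone filters."""
    if reads.empty:
        return pd.DataFrame(
            columns=["chrom", "position", "unique_reads", "reads_itr5", "reads_itr3"]
        )
    grouped = reads.groupby(["chrom", "position"], sort=True)
    loc = grouped.agg(
        unique_reads=("fragment_end", "nunique"),
        reads_itr5=("itr_side", lambda s: int((s == "ITR5").sum())),
        reads_itr3=("itr_side", lambda s: int((s == "ITR3").sum())),
    ).reset_index()
    loc = loc[loc["unique_reads"] >= min_unique]
    if loc.empty:
        return loc
    top = loc["unique_reads"].max()
    # strictly below the fraction of the top count is discarded
    return loc[loc["unique_reads"] >= top_fraction * top].reset_index(drop=True)


def call_clone(
    reads: pd.DataFrame,
    min_unique_reads: int = 10,
    top_fraction: float = 0.20,
) -> CloneCall:
    """Genotype one clonal library from its junction reads.

    Candidate locations need >= ``min_unique_reads`` unique reads and at
    least ``top_fraction`` of the top candidate's count (strict < removes).
    Exactly one candidate supported by both ITR sides is a confident
    insertion; exactly two candidates, each supported by only one side and
    jointly covering both sides on one chromosome, are a hopping-induced
    deletion spanning between them. Every other configuration is returned
    for manual review with a machine-readable reason.
    """
    loc = _clone_candidates(reads, min_unique_reads, top_fraction)
    if loc.empty:
        return CloneCall(verdict="fail", reason="no candidate location after filtering")

    if len(loc) == 1:
        site = loc.iloc[0]
        if site["reads_itr5"] >= 1 and site["reads_itr3"] >= 1:
            return CloneCall(
                verdict="insertion", insertion_site=site, supporting_locations=loc
            )
        return CloneCall(
            verdict="review",
            supporting_locations=loc,
            reason="single location supported by only one ITR side",
        )

    if len(loc) == 2:
        a, b = loc.iloc[0], loc.iloc[1]
        a5 = a["reads_itr5"] >= 1 and a["reads_itr3"] == 0
        a3 = a["reads_itr3"] >= 1 and a["reads_itr5"] == 0
        b5 = b["reads_itr5"] >= 1 and b["reads_itr3"] == 0
        b3 = b["reads_itr3"] >= 1 and b["reads_itr5"] == 0
        if (a5 and b3) or (a3 and b5):
            if a["chrom"] != b["chrom"]:
                return CloneCall(
                    verdict="review",
                    supporting_locations=loc,
                    reason="single-ITR locations on different chromosomes",
                )
            lo = int(min(a["position"], b["position"]))
            hi = int(max(a["position"], b["position"]))
            if lo == hi:
                return CloneCall(
                    verdict="review",
                    supporting_locations=loc,
                    reason="degenerate deletion: identical endpoints",
                )
            return CloneCall(
                verdict="deletion",
                deletion_interval=(str(a["chrom"]), lo, hi),
                supporting_locations=loc,
            )
        return CloneCall(
            verdict="review",
            supporting_locations=loc,
            reason="two locations but ITR sides do not split cleanly",
        )

    return CloneCall(
        verdict="review",
        supporting_locations=loc,
        reason=f"{len(loc)} candidate locations (possible index swap or second integration)",
    )


def infer_deletion_interval(call: CloneCall) -> tuple[str, int, int, int]:
    """Deletion (chrom, start, end, width); width is 1-based inclusive."""
    if call.verdict != "deletion" or call.deletion_interval is None:
        raise DataIntegrityError(
            f"deletion interval requested for verdict {call.verdict!r}"
        )
    chrom, start, end = call.deletion_interval
    return chrom, start, end, end - start + 1


# ---------------------------------------------------------------------------
# convenience pipeline


def call_pool_integrations(
    reads: pd.DataFrame,
    pool_classes: dict[str, str],
    blacklist: Blacklist | None = None,
    min_mapq: int = 10,
) -> pd.DataFrame:
    """Full pool pipeline: mapq filter, collapse, per-pool rules, blacklist.

    ``pool_classes`` maps each pool label to sorted|top_gate|unsorted.
    """
    reads = filter_reads(reads, min_mapq=min_mapq)
    integrations = collapse_to_integrations(reads)
    parts = []
    for pool, sub in integrations.groupby("pool", sort=True):
        if pool not in pool_classes:
            raise ConfigurationError(f"no pool_class configured for pool {pool!r}")
        parts.append(filter_pool_integrations(sub, pool_classes[pool]))
    integrations = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=INTEGRATION_COLUMNS)
    )
    if blacklist is not None:
        integrations = apply_blacklist(integrations, blacklist)
    return integrations.reset_index(drop=True)
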
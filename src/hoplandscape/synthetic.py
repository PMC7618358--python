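"""Synthetic hopping experiments with known ground truth.

Generates the statistical structure the downstream analysis assumes:

* a positional activation landscape with heavy-tailed peaks inside a
  sharply bounded permissive domain;
* transposon reintegration around a launch pad with a symmetric Laplace
  (two-sided exponential) distance kernel, a non-mobilized fraction and a
  fraction lost to other chromosomes;
* log-normal per-cell fluorescence noise and gate-based sorting with finite
  sorted-cell caps;
* overdispersed (truncated negative-binomial) unique-read counts per
  integration with dual-ITR structure, a mapping-quality mixture and
  PCR-contaminant positions;
* exponential RNA decay observed through noisy qPCR Ct values;
* distance-decay contact matrices with TAD blocks and focal peaks.

All randomness flows from the explicit ``seed`` argument of each function;
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hoplandscape.contacts import ContactMatrix
from hoplandscape.errors import InvalidSpecError

# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class LandscapeSpec:
    """Ground-truth activation landscape.

    The landscape is ``baseline_outside`` everywhere outside the permissive
    domain ``[domain_start, domain_end]`` (1-based inclusive) and
    ``baseline_inside`` plus a sum of peaks inside it. ``peaks`` is a list of
    ``(center, width_bp, amplitude)`` triples; each peak decays as
    ``amplitude * exp(-|x - center| / width_bp)`` — a sharp apex with heavy
    tails, emulating activation that falls off continuously with distance
    from an enhancer. Per-cell noise is multiplicative log-normal with
    log-standard-deviation ``noise_sd_log``.
    """

    domain_start: int
    domain_end: int
    peaks: tuple[tuple[int, float, float], ...] = ()
    baseline_inside: float = 100.0
    baseline_outside: float = 10.0
    noise_sd_log: float = 0.0

    def __post_init__(self) -> None:
        if self.domain_start >= self.domain_end:
            raise InvalidSpecError("domain_start must be < domain_end")
        if any(a < 0 for _, _, a in self.peaks):
            raise InvalidSpecError("peak amplitudes must be >= 0")
        if self.baseline_outside > self.baseline_inside:
            raise InvalidSpecError("baseline_outside must be <= baseline_inside")
        if self.noise_sd_log < 0:
            raise InvalidSpecError("noise_sd_log must be >= 0")


@dataclass(frozen=True)
class HoppingSpec:
    """Transposon mobilization model around a launch pad.

    ``kernel_scale`` is the scale (bp) of the symmetric Laplace reintegration
    kernel, truncated to the simulated region ``[region_start, region_end]``.
    ``p_unhopped`` is the probability the cassette never mobilized (the cell
    keeps ``launch_position``); ``p_trans`` the probability of reintegration
    outside the simulated region (those cells are dropped from the locus
    table); ``strand_prob`` the probability of forward orientation.
    """

    launch_position: int
    n_cells: int
    kernel_scale: float = 200_000.0
    p_unhopped: float = 0.33
    p_trans: float = 0.28
    strand_prob: float = 0.5
    region_start: int = 1
    region_end: int = 10_000_000
    chrom: str = "chr3"

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise InvalidSpecError("n_cells must be positive")
        if not (0 <= self.p_unhopped <= 1 and 0 <= self.p_trans <= 1):
            raise InvalidSpecError("p_unhopped and p_trans must lie in [0, 1]")
        if self.kernel_scale <= 0:
            raise InvalidSpecError("kernel_scale must be positive")
        if not 0 <= self.strand_prob <= 1:
            raise InvalidSpecError("strand_prob must lie in [0, 1]")
        if not self.region_start <= self.launch_position <= self.region_end:
            raise InvalidSpecError("launch_position must lie inside the region")


@dataclass(frozen=True)
class GateScheme:
    """Ordered, non-overlapping fluorescence gates covering the observed range.

    ``gates`` is an ordered list of ``(label, lower, upper)``; membership is
    half-open ``[lower, upper)``. ``sorted_cap`` caps cells sorted per gate.
    """

    gates: tuple[tuple[str, float, float], ...]
    sorted_cap: int = 2000

    def __post_init__(self) -> None:
        if not self.gates:
            raise InvalidSpecError("at least one gate required")
        if self.sorted_cap < 1:
            raise InvalidSpecError("sorted_cap must be >= 1")
        for label, lo, hi in self.gates:
            if not lo < hi:
                raise InvalidSpecError(f"gate {label}: lower bound must be < upper")
        bounds = [(lo, hi) for _, lo, hi in self.gates]
        for (_, hi_prev), (lo, _) in zip(bounds, bounds[1:]):
            if lo < hi_prev:
                raise InvalidSpecError("gates must be ordered and non-overlapping")

    def assign(self, fluorescence: np.ndarray) -> np.ndarray:
        """Gate label per value; raises if any value is uncovered."""
        fluorescence = np.asarray(fluorescence, dtype=float)
        labels = np.full(fluorescence.shape, None, dtype=object)
        for label, lo, hi in self.gates:
            mask = (fluorescence >= lo) & (fluorescence < hi)
            labels[mask] = label
        if (labels == None).any():  # noqa: E711 - elementwise object compare
            bad = fluorescence[labels == None][:3]  # noqa: E711
            raise InvalidSpecError(
                f"fluorescence values not covered by any gate (e.g. {bad.tolist()})"
            )
        return labels


@dataclass(frozen=True)
class ReadSimSpec:
    """Junction-read generation per sorted integration.

    Unique-read counts follow a negative binomial with mean ``mean_reads``
    and variance ``mean_reads * (1 + dispersion * mean_reads)``, truncated at
    >= 1 (every sorted integration yields at least one read). ``dispersion``
    of 0 degenerates to Poisson. ``mapq_dist`` maps mapping-quality value to
    probability. ``contaminant_positions`` are injected across pools at 1-2
    reads each, emulating carry-over PCR contamination.
    """

    mean_reads: float = 3.0
    dispersion: float = 0.6
    p_itr5: float = 0.5
    p_itr3: float = 0.5
    mapq_dist: tuple[tuple[int, float], ...] = ((0, 0.05), (9, 0.05), (20, 0.15), (60, 0.75))
    contaminant_positions: tuple[int, ...] = ()
    chrom: str = "chr3"

    def __post_init__(self) -> None:
        if self.mean_reads <= 0:
            raise InvalidSpecError("mean_reads must be positive")
        if self.dispersion < 0:
            raise InvalidSpecError("dispersion must be >= 0")
        if abs(self.p_itr5 + self.p_itr3 - 1.0) > 1e-9:
            raise InvalidSpecError("p_itr5 + p_itr3 must equal 1")
        total = sum(p for _, p in self.mapq_dist)
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError("mapq_dist probabilities must sum to 1")


# ---------------------------------------------------------------------------
# landscape and hopping


def landscape_value(spec: LandscapeSpec, positions) -> np.ndarray:
    """Noise-free landscape fluorescence at 1-based genomic positions."""
    pos = np.asarray(positions, dtype=float)
    inside = (pos >= spec.domain_start) & (pos <= spec.domain_end)
    value = np.where(inside, spec.baseline_inside, spec.baseline_outside)
    if spec.peaks:
        bump = np.zeros_like(pos)
        for center, width, amplitude in spec.peaks:
            bump += amplitude * np.exp(-np.abs(pos - center) / width)
        value = value + np.where(inside, bump, 0.0)
    return value


def _truncated_laplace(rng, center: float, scale: float, lo: float, hi: float, size: int):
    # inverse-CDF sampling restricted to [lo, hi]
    dist = stats.laplace(loc=center, scale=scale)
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=size)
    return dist.ppf(u)


def simulate_hopping(
    landscape: LandscapeSpec, hopping: HoppingSpec, seed: int
) -> pd.DataFrame:
    """Simulate one hopping experiment.

    Returns the locus table of cells that kept an integration inside the
    simulated region: columns ``cell_id, chrom, position, orientation,
    true_fluor``. Cells reintegrating in trans are excluded; their count is
    recorded in ``df.attrs["n_trans"]``.
    """
    rng = np.random.default_rng(seed)
    n = hopping.n_cells
    u = rng.uniform(size=n)
    unhopped = u < hopping.p_unhopped
    trans = (~unhopped) & (u < hopping.p_unhopped + (1 - hopping.p_unhopped) * hopping.p_trans)
    hopped = ~unhopped & ~trans

    positions = np.full(n, hopping.launch_position, dtype=float)
    n_hop = int(hopped.sum())
    if n_hop:
        positions[hopped] = _truncated_laplace(
            rng,
            hopping.launch_position,
            hopping.kernel_scale,
            hopping.region_start,
            hopping.region_end,
            n_hop,
        )
    positions = np.clip(np.rint(positions), hopping.region_start, hopping.region_end)
    orientation = np.where(rng.uniform(size=n) < hopping.strand_prob, "+", "-")

    keep = ~trans
    positions = positions[keep].astype(np.int64)
    fluor = landscape_value(landscape, positions)
    if landscape.noise_sd_log > 0:
        fluor = fluor * np.exp(rng.normal(0.0, landscape.noise_sd_log, size=positions.size))

    df = pd.DataFrame(
        {
            "cell_id": np.arange(n)[keep],
            "chrom": hopping.chrom,
            "position": positions,
            "orientation": orientation[keep],
            "true_fluor": fluor,
        }
    )
    df.attrs["n_trans"] = int(trans.sum())
    return df


# ---------------------------------------------------------------------------
# sorting


def simulate_sort(
    cells: pd.DataFrame,
    scheme: GateScheme,
    record_fraction: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sort cells into fluorescence gates with a finite per-gate cap.

    Returns ``(pools, accounting)``. ``pools`` is the cell table restricted
    to sorted cells with a ``gate`` column. ``accounting`` has one row per
    gate: recorded cells ``R_P`` (from the recorded subset of the stream),
    total recorded ``T`` and sorted cells ``S_P = min(cells in gate, cap)``.
    """
    if not 0 < record_fraction <= 1:
        raise InvalidSpecError("record_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    gate = scheme.assign(cells["true_fluor"].to_numpy())
    recorded = rng.uniform(size=len(cells)) < record_fraction
    total_recorded = int(recorded.sum())

    rows = []
    sorted_parts = []
    for label, _, _ in scheme.gates:
        in_gate = np.flatnonzero(gate == label)
        r_p = int((recorded & (gate == label)).sum())
        s_p = min(in_gate.size, scheme.sorted_cap)
        if s_p:
            chosen = rng.choice(in_gate, size=s_p, replace=False)
            part = cells.iloc[np.sort(chosen)].copy()
            part["gate"] = label
            sorted_parts.append(part)
        rows.append({"gate": label, "recorded": r_p, "total_recorded": total_recorded,
                     "sorted": s_p})

    accounting = pd.DataFrame(rows)
    # the identity of recorded cells is needed to estimate per-gate Fluo
    accounting.attrs["recorded_cell_ids"] = cells["cell_id"].to_numpy()[recorded]
    pools = (
        pd.concat(sorted_parts, ignore_index=True)
        if sorted_parts
        else cells.iloc[:0].assign(gate=pd.Series(dtype=object))
    )
    return pools, accounting


# ---------------------------------------------------------------------------
# junction reads


def _truncated_nb(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial counts truncated at >= 1 (Poisson when dispersion=0)."""
    counts = np.zeros(size, dtype=np.int64)
    todo = np.arange(size)
    while todo.size:
        if dispersion > 0:
            r = 1.0 / dispersion
            p = r / (r + mean)
            draw = rng.negative_binomial(r, p, size=todo.size)
        else:
            draw = rng.poisson(mean, size=todo.size)
        counts[todo] = draw
        todo = todo[draw == 0]
    return counts


def simulate_reads(
    pools: pd.DataFrame,
    spec: ReadSimSpec,
    seed: int,
    replicate: str = "rep1",
) -> pd.DataFrame:
    """Generate a junction-read table for sorted pools.

    One truncated-NB count of unique reads per sorted integration; each read
    is assigned an ITR side, a mapping quality drawn from ``mapq_dist`` and a
    fragment end offset from the junction (the deduplication key downstream).
    Contaminant positions are appended with 1-2 low-count reads spread over
    pools.
    """
    rng = np.random.default_rng(seed)
    n_int = len(pools)
    records: dict[str, list] = {k: [] for k in (
        "pool", "replicate", "chrom", "position", "orientation", "itr_side",
        "mapq", "fragment_end")}

    mapq_vals = np.array([q for q, _ in spec.mapq_dist])
    mapq_p = np.array([p for _, p in spec.mapq_dist])

    if n_int:
        counts = _truncated_nb(rng, spec.mean_reads, spec.dispersion, n_int)
        total = int(counts.sum())
        rep_pos = np.repeat(pools["position"].to_numpy(), counts)
        rep_ori = np.repeat(pools["orientation"].to_numpy(), counts)
        rep_pool = np.repeat(pools["gate"].to_numpy(), counts)
        rep_chrom = np.repeat(pools["chrom"].to_numpy(), counts)
        side = np.where(rng.uniform(size=total) < spec.p_itr5, "ITR5", "ITR3")
        mapq = rng.choice(mapq_vals, size=total, p=mapq_p)
        offset = rng.integers(30, 500, size=total)
        frag = np.where(rep_ori == "+", rep_pos + offset, rep_pos - offset)
        records["pool"] = list(rep_pool)
        records["replicate"] = [replicate] * total
        records["chrom"] = list(rep_chrom)
        records["position"] = list(rep_pos)
        records["orientation"] = list(rep_ori)
        records["itr_side"] = list(side)
        records["mapq"] = list(mapq)
        records["fragment_end"] = list(frag)

    pool_labels = pools["gate"].unique().tolist() if n_int else ["P1"]
    for cpos in spec.contaminant_positions:
        n_reads = int(rng.integers(1, 3))
        for _ in range(n_reads):
            records["pool"].append(rng.choice(pool_labels))
            records["replicate"].append(replicate)
            records["chrom"].append(spec.chrom)
            records["position"].append(cpos)
            records["orientation"].append(rng.choice(["+", "-"]))
            records["itr_side"].append(rng.choice(["ITR5", "ITR3"]))
            records["mapq"].append(int(rng.choice(mapq_vals, p=mapq_p)))
            records["fragment_end"].append(cpos + int(rng.integers(30, 500)))

    reads = pd.DataFrame(records)
    reads.insert(0, "read_id", [f"r{i:07d}" for i in range(len(reads))])
    reads["position"] = reads["position"].astype(np.int64)
    reads["mapq"] = reads["mapq"].astype(np.int64)
    reads["fragment_end"] = reads["fragment_end"].astype(np.int64)
    return reads


# ---------------------------------------------------------------------------
# flow cytometry events


CHANNELS = ("mTurq", "eGFP", "mCherry")


def simulate_flow_events(
    n_cells: int,
    channel_means: dict[str, float],
    channel_cvs: dict[str, float],
    spillover_frac: float = 0.0,
    seed: int = 0,
    autofluor: float = 0.0,
    sample: str = "sim",
) -> pd.DataFrame:
    """Per-cell log-normal channel intensities with optical spillover.

    Each channel is log-normal with the requested arithmetic mean and
    coefficient of variation (cv 0 collapses to the mean exactly). The
    observed eGFP channel is true eGFP plus ``spillover_frac`` times the true
    mTurq signal; a constant autofluorescence offset is added to every
    channel afterwards.
    """
    if n_cells <= 0:
        raise InvalidSpecError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    true: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        mean = float(channel_means.get(ch, 0.0))
        cv = float(channel_cvs.get(ch, 0.0))
        if mean < 0:
            raise InvalidSpecError(f"channel mean for {ch} must be >= 0")
        if cv < 0:
            raise InvalidSpecError(f"cv for {ch} must be >= 0")
        if mean == 0 or cv == 0:
            true[ch] = np.full(n_cells, mean)
        else:
            sigma2 = np.log1p(cv**2)
            mu = np.log(mean) - sigma2 / 2  # matches the arithmetic mean exactly
            true[ch] = rng.lognormal(mu, np.sqrt(sigma2), size=n_cells)

    observed = dict(true)
    observed["eGFP"] = true["eGFP"] + spillover_frac * true["mTurq"]
    df = pd.DataFrame({"sample": sample, **{ch: observed[ch] + autofluor for ch in CHANNELS}})
    return df


# ---------------------------------------------------------------------------
# RNA decay Ct tables


def simulate_decay_cts(
    k_true: float,
    timepoints,
    ct_noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
    ct0: float = 20.0,
    n_technical: int = 3,
    target: str = "mTurq",
    reference_targets: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Exponential-decay qPCR time course in long format.

    True abundance is ``exp(-k_true * t)``; the observed quantification cycle
    is ``Ct(t) = ct0 - log2(abundance) + Normal(0, ct_noise_sd)`` per
    technical measurement. Reference targets decay with rate 0 (stable).
    Columns: replicate, timepoint_h, target, ct.
    """
    if k_true <= 0:
        raise InvalidSpecError("k_true must be positive")
    t = np.asarray(sorted(timepoints), dtype=float)
    if 0.0 not in t:
        raise InvalidSpecError("timepoints must include t=0 (normalization anchor)")
    rng = np.random.default_rng(seed)
    rows = []
    targets = [(target, k_true)] + [(r, 0.0) for r in reference_targets]
    for rep in range(1, n_replicates + 1):
        for name, k in targets:
            base = ct0 + k * t / np.log(2)  # -log2(exp(-kt)) = kt/ln2
            for ti, ct_t in zip(t, base):
                cts = ct_t + rng.normal(0.0, ct_noise_sd, size=n_technical)
                for ct in cts:
                    rows.append((f"rep{rep}", ti, name, float(ct)))
    return pd.DataFrame(rows, columns=["replicate", "timepoint_h", "target", "ct"])


# ---------------------------------------------------------------------------
# contact matrices


def simulate_contact_matrix(
    n_bins: int,
    bin_size: int,
    decay_exponent: float = 1.0,
    tad_blocks: tuple[tuple[int, int, float], ...] = (),
    peak_pairs: tuple[tuple[int, int, float], ...] = (),
    seed: int = 0,
    chrom: str = "chr3",
    origin: int = 0,
    noise_sd_log: float = 0.0,
) -> ContactMatrix:
    """Distance-decay contact matrix with TAD blocks and focal peaks.

    Off-diagonal value is ``|i - j| ** -decay_exponent`` multiplied by a
    block factor when both bins fall inside one TAD block ``(start_bin,
    end_bin, multiplier)`` (end exclusive) and by a peak factor at listed
    ``(i, j, multiplier)`` pairs. Optional multiplicative log-normal noise is
    applied symmetrically. The diagonal is set to the per-row off-diagonal
    maximum; downstream operations exclude it anyway.
    """
    if n_bins < 4:
        raise InvalidSpecError("n_bins must be >= 4")
    for a, b, _ in tad_blocks:
        if not 0 <= a < b <= n_bins:
            raise InvalidSpecError(f"block ({a},{b}) outside [0,{n_bins}]")
    for (a1, b1, m1) in tad_blocks:
        for (a2, b2, m2) in tad_blocks:
            if (a1, b1) < (a2, b2) and a2 < b1 and a1 < b2 and m1 != m2:
                raise InvalidSpecError("overlapping blocks with conflicting multipliers")

    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        values = np.where(dist > 0, dist**-decay_exponent, 0.0)

    for a, b, mult in tad_blocks:
        inside = (idx >= a) & (idx < b)
        values[np.ix_(inside, inside)] *= mult
    for i, j, mult in peak_pairs:
        values[i, j] *= mult
        values[j, i] *= mult

    if noise_sd_log > 0:
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.normal(0.0, noise_sd_log, size=(n_bins, n_bins)))
        noise = np.sqrt(noise * noise.T)  # symmetric multiplicative jitter
        values *= noise

    np.fill_diagonal(values, 0.0)
    row_max = values.max(axis=1)
    np.fill_diagonal(values, row_max)

    bins = pd.DataFrame(
        {
            "chrom": chrom,
            "start": origin + idx * bin_size,
            "end": origin + (idx + 1) * bin_size,
        }
    )
    return ContactMatrix(bins=bins, values=values, resolution=bin_size)


# ---------------------------------------------------------------------------
# default scenario


@dataclass(frozen=True)
class Scenario:
    """A complete synthetic study: landscape, hopping, gating and read specs."""

    landscape: LandscapeSpec
    hopping: HoppingSpec
    gates: GateScheme
    reads: ReadSimSpec
    n_replicates: int = 2
    record_fraction: float = 0.9
    region: tuple[str, int, int] = ("chr3", 34_000_000, 35_600_000)
    step: int = 500
    window_bins: int = 10
    min_integrations: int = 3
    extra: dict = field(default_factory=dict)


def default_scenario() -> Scenario:
    """The default two-peak bounded-domain hopping scenario.

    Mirrors the study conditions: hopping over a ~1.6 Mb locus, a launch pad
    inside a permissive domain containing a strong distal enhancer-cluster
    peak and a weaker promoter-proximal peak, 33% non-mobilized cassettes,
    28% of hops leaving the locus, a 200 kb Laplace reintegration scale, six
    expression gates with a 2000-cell sorting cap per gate over two
    replicate experiments, and sparse overdispersed junction-read support.
    The scored region is the permissive domain itself — the densely covered
    locus of interest — while integrations land over the whole region.
    """
    chrom, region_start, region_end = "chr3", 34_000_000, 35_600_000
    landscape = LandscapeSpec(
        domain_start=34_550_000,
        domain_end=34_950_000,
        peaks=((34_757_000, 30_000.0, 8_000.0), (34_650_000, 15_000.0, 2_500.0)),
        baseline_inside=500.0,
        baseline_outside=50.0,
        noise_sd_log=0.25,
    )
    hopping = HoppingSpec(
        launch_position=34_641_000,
        n_cells=8_000,
        kernel_scale=200_000.0,
        p_unhopped=0.33,
        p_trans=0.28,
        strand_prob=0.5,
        region_start=region_start,
        region_end=region_end,
        chrom=chrom,
    )
    # log-spaced gates spanning the plausible fluorescence range
    edges = [0.0, 120.0, 400.0, 900.0, 2_000.0, 5_000.0, float("inf")]
    labels = ["P6", "P5", "P4", "P3", "P2", "P1"]  # P1 = highest expression
    gates = GateScheme(
        gates=tuple((lab, lo, hi) for lab, lo, hi in zip(labels, edges[:-1], edges[1:])),
        sorted_cap=2000,
    )
    reads = ReadSimSpec(
        mean_reads=3.0,
        dispersion=0.6,
        contaminant_positions=(34_721_183, 35_232_946),
        chrom=chrom,
    )
    return Scenario(
        landscape=landscape,
        hopping=hopping,
        gates=gates,
        reads=reads,
        n_replicates=2,
        record_fraction=0.9,
        region=(chrom, 34_550_000, 34_950_000),
        step=500,
        window_bins=10,
        min_integrations=3,
    )
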
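"""End-to-end pipeline: simulate, call, score, correlate.

Ties the simulator, integration calling and landscape scoring into one
reproducible run driven by a :class:`~hoplandscape.config.RunConfig`. Every
stage draws its randomness from a child seed derived from the single run
seed, and the run report records record counts at each filter stage, so a
config plus a seed reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

import hoplandscape
from hoplandscape import io as hio
from hoplandscape.calling import call_pool_integrations, default_blacklist, filter_reads
from hoplandscape.config import RunConfig, child_seed
from hoplandscape.contacts import correlate_score_with_contact, insulation_score, virtual_4c
from hoplandscape.errors import ConfigurationError
from hoplandscape.intervals import GenomicInterval
from hoplandscape.landscape import (
    DeletionShift,
    SortedPopulation,
    WindowSpec,
    bootstrap_track,
    estimate_gate_fluorescence,
    unshift_track,
)
from hoplandscape.synthetic import (
    Scenario,
    default_scenario,
    simulate_contact_matrix,
    simulate_hopping,
    simulate_reads,
    simulate_sort,
)


def simulate_replicate(
    scenario: Scenario, replicate: str, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, list[SortedPopulation]]:
    """One replicate experiment: cells -> sorted pools -> junction reads.

    Returns (cells, reads, populations). Per-gate Fluo is the median
    fluorescence of recorded cells in the gate, mirroring how the sorter's
    recorded events are used.
    """
    cells = simulate_hopping(scenario.landscape, scenario.hopping, seed)
    pools, accounting = simulate_sort(
        cells, scenario.gates, scenario.record_fraction, seed=seed + 1
    )
    reads = simulate_reads(pools, scenario.reads, seed=seed + 2, replicate=replicate)

    recorded_ids = accounting.attrs["recorded_cell_ids"]
    recorded = cells[cells["cell_id"].isin(recorded_ids)]
    populations = []
    for _, row in accounting.iterrows():
        if row["sorted"] == 0:
            continue
        bounds = next(
            (lo, hi) for lab, lo, hi in scenario.gates.gates if lab == row["gate"]
        )
        try:
            fluo = estimate_gate_fluorescence(recorded, bounds, channel="true_fluor")
        except Exception:
            continue  # no recorded event in the gate: Fluo unknown, drop gate
        populations.append(
            SortedPopulation(
                experiment=replicate,
                gate=row["gate"],
                fluo=fluo,
                recorded=int(row["recorded"]),
                total_recorded=int(row["total_recorded"]),
                sorted_cells=int(row["sorted"]),
            )
        )
    return cells, reads, populations


def _pool_classes(scenario: Scenario) -> dict[str, str]:
    """The highest-expression gate is filtered with the dual-ITR rule."""
    top = max(scenario.gates.gates, key=lambda g: g[1])[0]
    return {lab: ("top_gate" if lab == top else "sorted") for lab, _, _ in scenario.gates.gates}


def run_pipeline(
    config: RunConfig, scenario: Scenario | None = None
) -> tuple[pd.DataFrame, dict]:
    """Execute simulate -> call -> score (-> contacts) and write artifacts.

    Returns the bootstrap expression track and the machine-readable run
    report (also written as JSON to the output directory).
    """
    if scenario is None:
        scenario = default_scenario()
        scenario = dataclasses.replace(
            scenario,
            hopping=dataclasses.replace(scenario.hopping, n_cells=config.n_cells),
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    hop_seed = child_seed(config.seed, "hopping")
    all_reads, populations = [], []
    for i in range(1, config.n_replicates + 1):
        _, reads, pops = simulate_replicate(
            scenario, replicate=f"rep{i}", seed=(hop_seed + 10 * i) % 2**31
        )
        all_reads.append(reads)
        populations.extend(pops)
    reads = pd.concat(all_reads, ignore_index=True)

    n_reads_raw = len(reads)
    n_reads_mapq = len(filter_reads(reads))
    blacklist = default_blacklist(origin_launchpad=scenario.hopping.launch_position)
    integrations = call_pool_integrations(
        reads, _pool_classes(scenario), blacklist=blacklist
    )
    n_integrations = len(integrations)

    chrom, rstart, rend = scenario.region
    spec = WindowSpec(
        step=config.step,
        window_bins=config.window_bins,
        region=(chrom, rstart, rend),
        min_integrations=config.min_integrations,
    )

    shift = None
    if config.deletion:
        iv = GenomicInterval.from_string(config.deletion)
        c, s1, e1 = iv.to_1based()
        shift = DeletionShift(chrom=c, start=s1, end=e1)
        from hoplandscape.landscape import apply_deletion_shift

        integrations_scored = apply_deletion_shift(integrations, shift)
    else:
        integrations_scored = integrations

    track = bootstrap_track(
        integrations_scored,
        populations,
        spec,
        B=config.bootstrap,
        seed=child_seed(config.seed, "bootstrap"),
        strand=config.strand,
    )
    if shift is not None:
        track = unshift_track(track, shift)

    config_echo = dataclasses.asdict(config)
    config_echo.pop("outdir")  # paths differ between otherwise identical runs
    report: dict = {
        "package_version": hoplandscape.__version__,
        "seed": config.seed,
        "config": config_echo,
        "counts": {
            "reads_raw": n_reads_raw,
            "reads_mapq_pass": n_reads_mapq,
            "integrations_retained": n_integrations,
            "windows_total": int(len(track)),
            "windows_unmasked": int((~track["masked"]).sum()),
        },
    }

    if config.with_contacts:
        cm_seed = child_seed(config.seed, "contacts")
        n_bins = config.contact_bins
        matrix = simulate_contact_matrix(
            n_bins=n_bins,
            bin_size=config.contact_resolution,
            decay_exponent=1.0,
            tad_blocks=((0, n_bins // 2, 3.0), (n_bins // 2, n_bins, 3.0)),
            seed=cm_seed,
            chrom=chrom,
            origin=rstart,
            noise_sd_log=0.1,
        )
        ins = insulation_score(matrix, window_bins=min(20, n_bins // 4))
        center_bin = n_bins // 2
        viewpoint = GenomicInterval(
            chrom,
            rstart + center_bin * config.contact_resolution,
            rstart + (center_bin + 1) * config.contact_resolution,
        )
        profile = virtual_4c(matrix, viewpoint)
        matrix.to_files(outdir / "contact_bins.bed", outdir / "contact_triplets.tsv")
        ins.to_csv(outdir / "insulation.tsv", sep="\t", index=False)
        profile.to_csv(outdir / "virtual4c.tsv", sep="\t", index=False)
        report["contacts"] = {
            "n_bins": n_bins,
            "insulation_min_bin": int(ins["insulation"].idxmin()),
        }

    hio.write_reads(reads, outdir / "reads.tsv")
    hio.write_integrations(integrations, outdir / "integrations.tsv")
    hio.write_populations(populations, outdir / "populations.tsv")
    hio.write_track_tsv(track, outdir / "track.tsv")
    hio.write_track_bedgraph(track, outdir / "track.bedgraph")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return track, report


def bin_level_track(
    integrations: pd.DataFrame,
    populations: list[SortedPopulation],
    region: tuple[str, int, int],
    resolution: int,
    min_integrations: int = 3,
) -> pd.DataFrame:
    """Expression score per single bin (window of one bin), for correlation
    against contact profiles on the same grid."""
    from hoplandscape.landscape import bin_counts, expression_score

    spec = WindowSpec(
        step=resolution, window_bins=1, region=region, min_integrations=min_integrations
    )
    counts = bin_counts(integrations, spec)
    return expression_score(counts, populations, spec)


def correlate_pipeline_outputs(
    track: pd.DataFrame,
    profile: pd.DataFrame,
    viewpoint: GenomicInterval,
    min_integrations: int = 3,
) -> dict:
    rho_c, rho_d, n = correlate_score_with_contact(
        track, profile, viewpoint, min_integrations=min_integrations
    )
    return {"rho_contact": rho_c, "rho_distance": rho_d, "n_bins": n}
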
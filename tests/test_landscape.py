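"""Expression-score formula, windowing, deletion shift and bootstrap."""

import numpy as np
import pandas as pd
import pytest

from hoplandscape.errors import DataIntegrityError, InvalidSpecError
from hoplandscape.landscape import (
    DeletionShift,
    SortedPopulation,
    WindowSpec,
    apply_deletion_shift,
    bin_counts,
    bootstrap_track,
    combine_experiments,
    estimate_gate_fluorescence,
    expression_score,
    sort_fraction,
    unshift_track,
)


def pop(gate="P1", exp="rep1", fluo=100.0, R=999, T=10_000, S=2_000, r=1, m=1):
    return SortedPopulation(experiment=exp, gate=gate, fluo=fluo, recorded=R,
                            total_recorded=T, sorted_cells=S, n_replicates=r,
                            min_replicates=m)


def make_ints(positions, pools, exps=None, orientations=None, chrom="chr3"):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "position": positions,
            "orientation": orientations if orientations is not None else ["+"] * n,
            "unique_reads": 2,
            "reads_itr5": 1,
            "reads_itr3": 1,
            "pool": pools,
            "replicate": exps if exps is not None else ["rep1"] * n,
        }
    )


class TestGateFluorescence:
    def test_odd_count_median(self):
        ev = pd.DataFrame({"mTurq": [10.0, 20.0, 30.0]})
        assert estimate_gate_fluorescence(ev, (0, 100)) == 20.0

    def test_even_count_midpoint(self):
        ev = pd.DataFrame({"mTurq": [10.0, 30.0]})
        assert estimate_gate_fluorescence(ev, (0, 100)) == 20.0

    def test_empty_gate_raises(self):
        ev = pd.DataFrame({"mTurq": [1.0, 2.0]})
        with pytest.raises(DataIntegrityError):
            estimate_gate_fluorescence(ev, (10, 100))


class TestSortFraction:
    def test_formula_arithmetic(self):
        assert sort_fraction(pop(R=999, T=10_000, S=2_000)) == pytest.approx(5e-5)

    def test_pseudocount_active_for_unobserved_gate(self):
        assert sort_fraction(pop(R=0, T=10_000, S=100)) == pytest.approx(1e-6)

    def test_replicate_imbalance_factor(self):
        assert sort_fraction(pop(R=999, T=10_000, S=2_000, r=2, m=1)) == pytest.approx(2.5e-5)

    def test_zero_sorted_cells_rejected(self):
        with pytest.raises(InvalidSpecError):
            sort_fraction(pop(S=0))


class TestBinCounts:
    def spec(self, **kw):
        defaults = dict(step=100, window_bins=1, region=("chr3", 0, 1_000),
                        min_integrations=1)
        defaults.update(kw)
        return WindowSpec(**defaults)

    def test_boundary_position_goes_to_starting_bin(self):
        # 1-based position 101 is the first base of the second 0-based bin [100, 200)
        ints = make_ints([101], ["P1"])
        counts = bin_counts(ints, self.spec())
        assert list(counts["bin"]) == [1]

    def test_strand_filter(self):
        ints = make_ints([101, 201], ["P1", "P1"], orientations=["-", "-"])
        assert bin_counts(ints, self.spec(), strand="forward").empty
        assert bin_counts(ints, self.spec(), strand="reverse")["count"].sum() == 2

    def test_count_conservation_across_pools(self):
        ints = make_ints([10, 110, 210, 310, 410], ["P1", "P2", "P1", "P2", "P1"])
        counts = bin_counts(ints, self.spec())
        assert counts["count"].sum() == 5

    def test_out_of_region_not_counted(self):
        ints = make_ints([5_000], ["P1"])
        assert bin_counts(ints, self.spec())["count"].sum() == 0


class TestExpressionScore:
    def test_single_population_identity(self):
        spec = WindowSpec(step=100, window_bins=2, region=("chr3", 0, 1_000),
                          min_integrations=1)
        ints = make_ints([50, 150, 450, 950], ["P1"] * 4)
        track = expression_score(bin_counts(ints, spec), [pop(fluo=321.0)], spec)
        un = track[~track["masked"]]
        assert len(un) > 0
        np.testing.assert_allclose(un["score"], 321.0, rtol=1e-12)

    def test_two_population_hand_example(self):
        # Fsort (0.5, 0.25), N (2, 1), Fluo (100, 400) -> 160
        pops = [
            pop(gate="A", fluo=100.0, R=0, T=2, S=1),        # Fsort = 0.5
            pop(gate="B", fluo=400.0, R=0, T=4, S=1),        # Fsort = 0.25
        ]
        spec = WindowSpec(step=100, window_bins=1, region=("chr3", 0, 100),
                          min_integrations=1)
        ints = make_ints([10, 20, 30], ["A", "A", "B"])
        track = expression_score(bin_counts(ints, spec), pops, spec)
        assert track.loc[0, "score"] == pytest.approx(160.0)

    def test_low_count_windows_are_masked(self):
        spec = WindowSpec(step=100, window_bins=1, region=("chr3", 0, 200),
                          min_integrations=3)
        ints = make_ints([10, 20], ["P1", "P1"])
        track = expression_score(bin_counts(ints, spec), [pop()], spec)
        assert track.loc[0, "masked"] and track.loc[0, "n_integrations"] == 2

    def test_unknown_population_is_integrity_error(self):
        spec = WindowSpec(step=100, window_bins=1, region=("chr3", 0, 100),
                          min_integrations=1)
        ints = make_ints([10], ["mystery"])
        with pytest.raises(DataIntegrityError):
            expression_score(bin_counts(ints, spec), [pop(gate="P1")], spec)

    def test_score_bounded_by_contributing_fluorescences(self):
        rng = np.random.default_rng(3)
        gates = ["P1", "P2", "P3"]
        pops = [pop(gate=g, fluo=f, R=int(rng.integers(0, 5_000)))
                for g, f in zip(gates, (50.0, 400.0, 2_000.0))]
        ints = make_ints(rng.integers(1, 2_000, size=300),
                         rng.choice(gates, size=300))
        spec = WindowSpec(step=100, window_bins=5, region=("chr3", 0, 2_000),
                          min_integrations=1)
        track = expression_score(bin_counts(ints, spec), pops, spec)
        un = track[~track["masked"]]
        assert (un["score"] >= 50.0 - 1e-9).all() and (un["score"] <= 2_000.0 + 1e-9).all()

    def test_common_fsort_scaling_leaves_scores_unchanged(self):
        # doubling every S_P scales all Fsort by 1/2; scores must not move
        rng = np.random.default_rng(4)
        ints = make_ints(rng.integers(1, 1_000, size=100),
                         rng.choice(["A", "B"], size=100))
        spec = WindowSpec(step=50, window_bins=4, region=("chr3", 0, 1_000),
                          min_integrations=1)
        pops1 = [pop(gate="A", fluo=10.0, S=100), pop(gate="B", fluo=99.0, S=400)]
        pops2 = [pop(gate="A", fluo=10.0, S=200), pop(gate="B", fluo=99.0, S=800)]
        t1 = expression_score(bin_counts(ints, spec), pops1, spec)
        t2 = expression_score(bin_counts(ints, spec), pops2, spec)
        np.testing.assert_allclose(t1["score"], t2["score"], rtol=1e-12)


def brute_force_score(integrations, populations, spec):
    """Direct per-window evaluation of the weighted-mean formula from raw lists."""
    fsort = {(p.experiment, p.gate): sort_fraction(p) for p in populations}
    fluo = {(p.experiment, p.gate): p.fluo for p in populations}
    chrom, rstart, rend = spec.region
    n_bins = (rend - rstart) // spec.step
    scores, ns = [], []
    for w in range(n_bins - spec.window_bins + 1):
        lo = rstart + w * spec.step
        hi = lo + spec.window_bins * spec.step
        num = den = 0.0
        n = 0
        for _, row in integrations.iterrows():
            p0 = row["position"] - 1
            if row["chrom"] == chrom and lo <= p0 < hi:
                key = (row["replicate"], row["pool"])
                num += fsort[key] * fluo[key]
                den += fsort[key]
                n += 1
        scores.append(num / den if den > 0 else np.nan)
        ns.append(n)
    return np.array(scores), np.array(ns)


def random_instance(rng):
    n_gates = int(rng.integers(1, 6))
    n_exps = int(rng.integers(1, 4))
    gates = [f"P{g}" for g in range(n_gates)]
    exps = [f"e{e}" for e in range(n_exps)]
    pops = [
        SortedPopulation(
            experiment=e, gate=g,
            fluo=float(rng.uniform(10, 5_000)),
            recorded=int(rng.integers(0, 5_000)),
            total_recorded=10_000,
            sorted_cells=int(rng.integers(1, 3_000)),
            n_replicates=int(rng.integers(1, 4)),
            min_replicates=1,
        )
        for e in exps for g in gates
    ]
    n_ints = int(rng.integers(1, 200))
    ints = make_ints(
        rng.integers(1, 3_000, size=n_ints),
        rng.choice(gates, size=n_ints),
        exps=rng.choice(exps, size=n_ints),
    )
    spec = WindowSpec(
        step=int(rng.choice([50, 100, 250])),
        window_bins=int(rng.integers(1, 8)),
        region=("chr3", 0, 3_000),
        min_integrations=int(rng.integers(1, 4)),
    )
    return ints, pops, spec


@pytest.mark.parametrize("seed", [0, 1])
def test_windowed_score_matches_brute_force(seed):
    """Random small instances agree with direct formula evaluation to 1e-9."""
    rng = np.random.default_rng(seed)
    for _ in range(25):
        ints, pops, spec = random_instance(rng)
        track = expression_score(bin_counts(ints, spec), pops, spec)
        expected, ns = brute_force_score(ints, pops, spec)
        np.testing.assert_array_equal(track["n_integrations"], ns)
        both = np.isfinite(expected) & track["score"].notna().to_numpy()
        np.testing.assert_allclose(
            track["score"].to_numpy()[both], expected[both], rtol=1e-9
        )


class TestDeletionShift:
    def test_positions_after_deletion_move_left(self):
        shift = DeletionShift("chr3", 1_000, 1_999)
        ints = make_ints([900, 2_500], ["P1", "P1"])
        out = apply_deletion_shift(ints, shift)
        assert list(out["position"]) == [900, 1_500]

    def test_integration_inside_deletion_is_inconsistent(self):
        shift = DeletionShift("chr3", 1_000, 1_999)
        with pytest.raises(DataIntegrityError):
            apply_deletion_shift(make_ints([1_500], ["P1"]), shift)

    def test_shift_unshift_round_trip(self):
        shift = DeletionShift("chr3", 401, 600)  # width 200
        spec = WindowSpec(step=100, window_bins=2, region=("chr3", 0, 2_000),
                          min_integrations=1)
        track = pd.DataFrame(
            {
                "chrom": "chr3",
                "start": np.arange(0, 1_900, 100),
                "end": np.arange(200, 2_100, 100),
                "score": 1.0,
                "n_integrations": 5,
                "masked": False,
            }
        )
        out = unshift_track(track, shift)
        before = out[out["start"] < 400]
        after = out[out["start"] >= 400]
        assert (before["start"].to_numpy() == track["start"].to_numpy()[: len(before)]).all()
        assert (after["start"].to_numpy()
                == track["start"].to_numpy()[len(before):] + 200).all()


class TestBootstrap:
    def test_degenerate_data_gives_zero_width_interval(self):
        spec = WindowSpec(step=100, window_bins=1, region=("chr3", 0, 100),
                          min_integrations=1)
        ints = make_ints([50] * 10, ["P1"] * 10)
        track = bootstrap_track(ints, [pop(fluo=77.0)], spec, B=50, seed=0)
        row = track.iloc[0]
        assert row["ci_low"] == row["ci_high"] == row["boot_median"] == pytest.approx(77.0)

    def test_single_resample_collapses_statistics(self):
        spec = WindowSpec(step=100, window_bins=1, region=("chr3", 0, 100),
                          min_integrations=1)
        ints = make_ints([10, 20, 30], ["P1"] * 3)
        track = bootstrap_track(ints, [pop(fluo=5.0)], spec, B=1, seed=1)
        row = track.iloc[0]
        assert row["ci_low"] == row["boot_median"] == row["ci_high"]

    def test_masking_uses_observed_counts(self):
        spec = WindowSpec(step=100, window_bins=1, region=("chr3", 0, 200),
                          min_integrations=3)
        ints = make_ints([10, 20], ["P1", "P1"])
        track = bootstrap_track(ints, [pop()], spec, B=20, seed=0)
        assert track["masked"].all()
        assert track[["boot_median", "ci_low", "ci_high"]].isna().all().all()


class TestCombineExperiments:
    def spec(self):
        return WindowSpec(step=100, window_bins=2, region=("chr3", 0, 1_000),
                          min_integrations=1)

    def test_identical_experiments_reproduce_single_experiment_score(self):
        rng = np.random.default_rng(7)
        pos = rng.integers(1, 1_000, size=60)
        ints1 = make_ints(pos, ["P1"] * 60, exps=["e1"] * 60)
        ints2 = make_ints(pos, ["P1"] * 60, exps=["e2"] * 60)
        pops1 = [pop(exp="e1", fluo=150.0)]
        pops2 = [pop(exp="e2", fluo=150.0)]
        pooled_ints, pooled_pops = combine_experiments([(ints1, pops1), (ints2, pops2)])
        spec = self.spec()
        single = expression_score(bin_counts(ints1, spec), pops1, spec)
        pooled = expression_score(bin_counts(pooled_ints, spec), pooled_pops, spec)
        np.testing.assert_allclose(pooled["score"], single["score"], rtol=1e-12)

    def test_empty_experiment_is_a_no_op(self):
        ints1 = make_ints([10, 110], ["P1", "P1"], exps=["e1", "e1"])
        pops1 = [pop(exp="e1")]
        empty = ints1.iloc[:0]
        pooled_ints, pooled_pops = combine_experiments([(ints1, pops1), (empty, [])])
        spec = self.spec()
        a = expression_score(bin_counts(ints1, spec), pops1, spec)
        b = expression_score(bin_counts(pooled_ints, spec), pooled_pops, spec)
        pd.testing.assert_frame_equal(a, b)

    def test_same_gate_label_across_experiments_not_merged(self):
        # same gate label, different Fluo per experiment: both must contribute
        pops = [pop(exp="e1", gate="P1", fluo=100.0, R=0, T=2, S=1),
                pop(exp="e2", gate="P1", fluo=300.0, R=0, T=2, S=1)]
        ints = make_ints([10, 20], ["P1", "P1"], exps=["e1", "e2"])
        spec = WindowSpec(step=100, window_bins=1, region=("chr3", 0, 100),
                          min_integrations=1)
        track = expression_score(bin_counts(ints, spec), pops, spec)
        assert track.loc[0, "score"] == pytest.approx(200.0)


def test_strand_specific_tracks_agree_on_strand_balanced_data(experiment, scenario):
    """With a strand-independent landscape, forward- and reverse-only scores
    rank windows the same way."""
    from scipy.stats import spearmanr

    from hoplandscape.landscape import WindowSpec, bin_counts, expression_score

    _, pops, ints = experiment
    spec = WindowSpec(step=scenario.step, window_bins=scenario.window_bins,
                      region=scenario.region, min_integrations=scenario.min_integrations)
    fwd = expression_score(bin_counts(ints, spec, strand="forward"), pops, spec)
    rev = expression_score(bin_counts(ints, spec, strand="reverse"), pops, spec)
    both = ~fwd["masked"] & ~rev["masked"]
    assert both.sum() >= 200
    rho = spearmanr(fwd["score"][both], rev["score"][both]).statistic
    assert rho >= 0.8
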
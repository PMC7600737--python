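import numpy as np
import pytest

from poolsweep.differentiation import (
    FstRecord,
    PairStats,
    compute_di,
    compute_pair_stats,
    di_threshold,
    pairwise_window_fst,
    per_snv_fst,
    window_fst,
)
from poolsweep.simulate import (
    SimulationConfig,
    SweepSpec,
    plant_sweeps,
    sample_pooled_reads,
    simulate_population_frequencies,
)
from poolsweep.windows import GenomeWindow, assign_snvs, compute_hp_records, make_windows

from _oracles import di_oracle, fst_anova_oracle, window_fst_oracle
from util import pv, random_counts


class TestPerSnvFst:
    def test_identical_pools_clamp_to_zero(self):
        comp = per_snv_fst((6, 6), (6, 6))
        assert comp.fst == 0.0
        # the raw estimate is negative: no between-pool variance
        assert comp.msp < comp.msg

    def test_fixed_difference_is_one(self):
        comp = per_snv_fst((0, 12), (12, 0))
        assert comp.fst == 1.0
        assert comp.msg == 0.0

    def test_hand_picked_case_matches_anova_oracle(self):
        comp = per_snv_fst((4, 8), (10, 2))
        oracle = fst_anova_oracle((4, 8), (10, 2))
        assert comp.msp == pytest.approx(oracle[0], rel=1e-12)
        assert comp.msg == pytest.approx(oracle[1], rel=1e-12)
        assert comp.n == pytest.approx(oracle[2], rel=1e-12)
        assert comp.fst == pytest.approx(oracle[3], rel=1e-12)

    def test_zero_depth_undefined(self):
        assert per_snv_fst((0, 0), (6, 6)) is None
        assert per_snv_fst((6, 6), (0, 0)) is None

    def test_monomorphic_site_undefined(self):
        assert per_snv_fst((12, 0), (10, 0)) is None

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 150:
            c_i = (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
            c_j = (int(rng.integers(0, 20)), int(rng.integers(0, 20)))
            comp = per_snv_fst(c_i, c_j)
            oracle = fst_anova_oracle(c_i, c_j)
            if oracle is None:
                assert comp is None
                continue
            assert comp.fst == pytest.approx(oracle[3], rel=1e-12, abs=1e-12)
            checked += 1

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            c_i = (int(rng.integers(1, 20)), int(rng.integers(0, 20)))
            c_j = (int(rng.integers(1, 20)), int(rng.integers(0, 20)))
            a, b = per_snv_fst(c_i, c_j), per_snv_fst(c_j, c_i)
            if a is None:
                assert b is None
            else:
                assert a.fst == b.fst


class TestWindowFst:
    def test_single_snv_window_equals_per_snv(self):
        comp = per_snv_fst((4, 8), (10, 2))
        assert window_fst([comp]) == comp.fst

    def test_identical_pool_counts_give_zero(self):
        comps = [per_snv_fst((6, 6), (6, 6)), per_snv_fst((3, 9), (3, 9))]
        assert window_fst(comps) == 0.0

    def test_no_usable_snv_missing(self):
        assert window_fst([None, None]) is None

    def test_random_windows_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(1, 200))
            pairs = [
                (
                    (int(rng.integers(0, 20)), int(rng.integers(0, 20))),
                    (int(rng.integers(0, 20)), int(rng.integers(0, 20))),
                )
                for _ in range(n)
            ]
            comps = [per_snv_fst(ci, cj) for ci, cj in pairs]
            expected = window_fst_oracle(pairs)
            got = window_fst(comps)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_vectorised_matches_scalar_path(self):
        rng = np.random.default_rng(9)
        variants = [
            pv(int(p), random_counts(rng, 3))
            for p in sorted(rng.choice(200_000, size=800, replace=False) + 1)
        ]
        windows = make_windows({"c1": 200_000}, 50_000, 25_000)
        assign_snvs(windows, variants)
        for pair in [(0, 1), (0, 2), (1, 2)]:
            records = pairwise_window_fst(variants, windows, pair)
            for w, rec in zip(windows, records):
                comps = [
                    per_snv_fst(variants[i].counts[pair[0]], variants[i].counts[pair[1]])
                    for i in w.snv_indices
                ]
                expected = window_fst(comps)
                if expected is None:
                    assert rec.fst is None
                else:
                    assert rec.fst == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_clamped_to_unit_interval(self):
        rng = np.random.default_rng(10)
        variants = [pv(i + 1, random_counts(rng, 2, depth=6)) for i in range(500)]
        windows = make_windows({"c1": 600}, 100, 50)
        assign_snvs(windows, variants)
        for rec in pairwise_window_fst(variants, windows, (0, 1)):
            if rec.fst is not None:
                assert 0.0 <= rec.fst <= 1.0


def _records(pair, fsts):
    return [
        FstRecord(GenomeWindow("c1", k * 100, (k + 1) * 100), pair, 0, 0, f)
        for k, f in enumerate(fsts)
    ]


class TestPairStats:
    def test_identical_windows_degenerate(self):
        with pytest.raises(ValueError, match="zero"):
            compute_pair_stats(_records((0, 1), [0.1, 0.1, 0.1]))

    def test_two_window_mean(self):
        stats = compute_pair_stats(_records((0, 1), [0.0, 0.2]))
        assert stats.mean_fst == pytest.approx(0.1)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(1)
        fsts = rng.uniform(0, 0.3, size=200).tolist()
        stats = compute_pair_stats(_records((0, 1), fsts))
        assert stats.mean_fst == pytest.approx(np.mean(fsts), rel=1e-12)
        assert stats.sd_fst == pytest.approx(np.std(fsts), rel=1e-12)

    def test_missing_windows_excluded(self):
        stats = compute_pair_stats(_records((0, 1), [0.0, None, 0.2]))
        assert stats.mean_fst == pytest.approx(0.1)


class TestComputeDi:
    def test_window_at_pair_means_gives_zero(self):
        fst_by_pair = {
            (0, 1): _records((0, 1), [0.1, 0.3]),
            (0, 2): _records((0, 2), [0.2, 0.4]),
            (1, 2): _records((1, 2), [0.3, 0.5]),
        }
        stats = {p: compute_pair_stats(r) for p, r in fst_by_pair.items()}
        # every pair mean lies halfway between its two windows, so a
        # synthetic window exactly at the means scores di = 0; here the
        # two real windows are symmetric: di values are -k and +k
        track = compute_di(fst_by_pair, stats, 0)
        vals = track.values()
        assert vals[0] == pytest.approx(-vals[1])
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_population_toy(self):
        # window fst: (0,1)=0.25, (0,2)=0.15; pair means 0.10/0.10, sds 0.10/0.10
        # di_0 = (0.25-0.10)/0.10 + (0.15-0.10)/0.10 = 1.5 + 0.5 = 2.0
        fst_by_pair = {
            (0, 1): _records((0, 1), [0.25]),
            (0, 2): _records((0, 2), [0.15]),
            (1, 2): _records((1, 2), [0.05]),
        }
        stats = {
            (0, 1): PairStats((0, 1), 0.10, 0.10),
            (0, 2): PairStats((0, 2), 0.10, 0.10),
            (1, 2): PairStats((1, 2), 0.10, 0.10),
        }
        track = compute_di(fst_by_pair, stats, 0)
        assert track.values()[0] == pytest.approx(2.0)
        expected = di_oracle(
            {(0, 1): 0.25, (0, 2): 0.15, (1, 2): 0.05},
            {p: s.mean_fst for p, s in stats.items()},
            {p: s.sd_fst for p, s in stats.items()},
            0,
        )
        assert track.values()[0] == pytest.approx(expected)

    def test_mean_di_zero_without_missing(self):
        rng = np.random.default_rng(6)
        pairs = [(0, 1), (0, 2), (1, 2)]
        fst_by_pair = {
            p: _records(p, rng.uniform(0, 0.3, size=300).tolist()) for p in pairs
        }
        stats = {p: compute_pair_stats(r) for p, r in fst_by_pair.items()}
        for pop in range(3):
            track = compute_di(fst_by_pair, stats, pop)
            assert abs(np.nanmean(track.values())) < 1e-6

    def test_missing_pair_fst_gives_missing_di(self):
        fst_by_pair = {
            (0, 1): _records((0, 1), [0.1, None, 0.3]),
            (0, 2): _records((0, 2), [0.1, 0.2, 0.3]),
        }
        stats = {
            (0, 1): PairStats((0, 1), 0.2, 0.1),
            (0, 2): PairStats((0, 2), 0.2, 0.1),
        }
        track = compute_di(fst_by_pair, stats, 0)
        assert track.records[1][1] is None


class TestDiThreshold:
    def test_hundred_values_interpolated_99th(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=100)
        cutoff = di_threshold(vals.tolist())
        s = np.sort(vals)
        h = 0.99 * 99
        lo = int(np.floor(h))
        expected = s[lo] + (h - lo) * (s[lo + 1] - s[lo])
        assert cutoff == pytest.approx(expected, rel=1e-12)

    def test_all_equal_nothing_passes_strictly(self):
        with pytest.warns(UserWarning):
            cutoff = di_threshold([1.5] * 50)
        assert cutoff == 1.5
        assert sum(v > cutoff for v in [1.5] * 50) == 0

    def test_normal_quantile_monte_carlo(self):
        rng = np.random.default_rng(8)
        cutoff = di_threshold(rng.normal(size=100_000).tolist())
        assert abs(cutoff - 2.326) < 0.05


class TestCalibrationAndRecovery:
    def test_sweep_windows_exceed_top_percentile_di(self):
        # planted-signal recovery: the fully swept window scores di above
        # the genome-wide top-1% cutoff in the target population
        sweep = SweepSpec("c1", 1_000_000, 1_050_000, (0,), 1.0)
        hits = trials = 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_populations=4,
                contig_lengths={"c1": 4_000_000},
                snv_density=0.002,
                mean_depth=20.0,
                sweep_specs=(sweep,),
                seed=seed,
            )
            table = plant_sweeps(simulate_population_frequencies(cfg), cfg.sweep_specs)
            variants = sample_pooled_reads(table, cfg.mean_depth, seed=seed + 500)
            windows = make_windows(cfg.contig_lengths, 50_000, 25_000)
            assign_snvs(windows, variants)
            retained = [w for w in windows if len(w.snv_indices) > 10]
            pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
            fst_by_pair = {
                p: pairwise_window_fst(variants, retained, p) for p in pairs
            }
            stats = {p: compute_pair_stats(fst_by_pair[p]) for p in pairs}
            track = compute_di(fst_by_pair, stats, 0)
            cutoff = di_threshold(track.values().tolist())
            for w, d in track.records:
                if sweep.start <= w.start and w.end <= sweep.end:
                    trials += 1
                    hits += d is not None and d > cutoff
        assert trials >= 5
        assert hits / trials >= 0.8
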
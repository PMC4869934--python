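"""Statistics against independent oracles; spectroscopy quantification."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from nfkbe2f import stats_quant as sq
from nfkbe2f.synthetic_data import FccsTriplet, FcsInput


def brute_force_kruskal_dunn(groups):
    """Independent oracle: explicit rank table and Dunn z statistics."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_r = [ranks[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
    h = 12.0 / (n * (n + 1)) * sum(
        s * r ** 2 for s, r in zip(sizes, mean_r)) - 3 * (n + 1)
    _, t = np.unique(pooled, return_counts=True)
    h /= 1.0 - np.sum(t ** 3 - t) / (n ** 3 - n)
    var = n * (n + 1) / 12.0 - np.sum(t ** 3 - t) / (12.0 * (n - 1))
    zs = {}
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var * (1 / sizes[i] + 1 / sizes[j]))
        zs[(i, j)] = (mean_r[i] - mean_r[j]) / se
    return h, zs


def brute_force_theil_sen(x, y):
    slopes = [(y[j] - y[i]) / (x[j] - x[i])
              for i, j in combinations(range(len(x)), 2) if x[j] != x[i]]
    return float(np.median(slopes))


class TestKruskalDunn:
    def test_hand_computed_h(self):
        res = sq.kruskal_dunn([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic == pytest.approx(7.2)

    def test_identical_groups_null(self):
        res = sq.kruskal_dunn([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0
        assert not res.pairwise["significant"].any()

    def test_permutation_invariance(self):
        a = sq.kruskal_dunn([[3, 1, 2], [6, 4, 5]])
        b = sq.kruskal_dunn([[1, 2, 3], [4, 5, 6]])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.pairwise["z"].tolist() == pytest.approx(
            b.pairwise["z"].tolist())

    def test_adjusted_p_at_least_raw(self):
        res = sq.kruskal_dunn([[1, 2, 9], [4, 5, 6], [7, 8, 3]])
        assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-15).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            sq.kruskal_dunn([[1.0], [2.0, 3.0]])

    @given(st.lists(st.lists(st.integers(0, 50), min_size=2, max_size=4),
                    min_size=2, max_size=3))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, groups):
        """H and every Dunn z match explicit rank-table enumeration on all
        small inputs (ties included)."""
        from hypothesis import assume
        pooled = np.concatenate(groups)
        assume(not np.all(pooled == pooled[0]))   # degenerate: no ranking
        res = sq.kruskal_dunn(groups)
        h, zs = brute_force_kruskal_dunn([np.array(g, float) for g in groups])
        assert res.statistic == pytest.approx(h, abs=1e-9)
        for k, (i, j) in enumerate(combinations(range(len(groups)), 2)):
            assert res.pairwise["z"].iloc[k] == pytest.approx(zs[(i, j)],
                                                              abs=1e-9)


class TestLevene:
    def test_identical_spread_gives_zero(self):
        res = sq.levene_test([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 2, 30)
        r1 = sq.levene_test([a, b])
        r2 = sq.levene_test([a + 100.0, b - 50.0])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_power_against_scaled_group(self):
        """3x SD inflation at n=100 is detected in >= 95/100 replicates."""
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 100)
            b = rng.normal(0, 3, 100)
            hits += sq.levene_test([a, b]).p_value < 0.01
        assert hits >= 95


class TestTheilSen:
    @pytest.mark.parametrize("x, y, expected", [
        ([0, 1, 2], [0, 2, 4], 2.0),
        ([0, 1, 2, 3, 4], [0, 2, 4, 6, 100], 2.0),   # outlier-immune
        ([0, 2], [0, 6], 3.0),
    ])
    def test_known_slopes(self, x, y, expected):
        slope, lo, hi = sq.theil_sen_slope(x, y)
        assert slope == pytest.approx(expected)
        assert lo <= slope <= hi

    def test_all_equal_x_rejected(self):
        with pytest.raises(ValueError):
            sq.theil_sen_slope([1, 1, 1], [1, 2, 3])

    @given(st.lists(st.tuples(st.integers(-20, 20), st.integers(-20, 20)),
                    min_size=2, max_size=12, unique_by=lambda p: p[0]))
    @settings(max_examples=80, deadline=None)
    def test_matches_pairwise_enumeration(self, pts):
        x = np.array([p[0] for p in pts], float)
        y = np.array([p[1] for p in pts], float)
        slope, _, _ = sq.theil_sen_slope(x, y)
        assert slope == pytest.approx(brute_force_theil_sen(x, y))

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 25)
        y = 2.5 * x + rng.normal(0, 1, 25)
        slope, _, _ = sq.theil_sen_slope(x, y)
        assert slope == pytest.approx(sps.theilslopes(y, x).slope)


class TestEstimateKd:
    def _triplets(self, kd, pairs):
        return [FccsTriplet(a, b, a * b / kd) for a, b in pairs]

    def test_noiseless_recovery_exact(self):
        trips = self._triplets(12.0, [(10, 20), (30, 40), (50, 15), (5, 80)])
        assert sq.estimate_kd(trips).kd_nM == pytest.approx(12.0)

    def test_outlier_robustness(self):
        trips = self._triplets(8.0, [(10 * i, 5 + 3 * i) for i in range(1, 11)])
        trips.append(FccsTriplet(50.0, 50.0, 1.0))   # wild outlier
        assert sq.estimate_kd(trips).kd_nM == pytest.approx(8.0)

    def test_scale_equivariance(self):
        pairs = [(10, 20), (30, 40), (50, 15), (5, 80), (22, 9)]
        kd1 = sq.estimate_kd(self._triplets(12.0, pairs)).kd_nM
        c = 3.0
        scaled = [FccsTriplet(c * t.free_a_nM, c * t.free_b_nM,
                              c * t.complex_nM)
                  for t in self._triplets(12.0, pairs)]
        assert sq.estimate_kd(scaled).kd_nM == pytest.approx(c * kd1)


class TestMoleculesPerCell:
    def test_zero_particles(self):
        assert sq.molecules_per_cell(FcsInput(0.0, 0.0)) == 0.0

    def test_identity_volume(self):
        inp = FcsInput(1.0, 0.0, v_conf_fL=1.0, v_nuc_fL=1.0, v_cyt_fL=1.0)
        assert sq.molecules_per_cell(inp) == pytest.approx(1.0)

    def test_printed_volume_arithmetic(self):
        inp = FcsInput(10.0, 0.0, v_conf_fL=0.59, v_nuc_fL=1420.0,
                       v_cyt_fL=6110.0)
        assert sq.molecules_per_cell(inp) == pytest.approx(24068, rel=1e-4)

    def test_negative_particles_rejected(self):
        with pytest.raises(ValueError):
            sq.molecules_per_cell(FcsInput(-1.0, 0.0))


class TestCycleEffectSummary:
    def test_identical_samples_null_effect(self):
        u = [18.0, 20.0, 22.0, 19.0]
        out = sq.cycle_effect_summary(u, u, seed=0, n_boot=200)
        assert out["mean_difference_h"] == 0.0
        assert out["sd_ratio"] == pytest.approx(1.0)

    def test_shift_arithmetic(self):
        out = sq.cycle_effect_summary([18.0, 20.0, 22.0],
                                      [20.0, 22.0, 24.0],
                                      seed=0, n_boot=200)
        assert out["mean_difference_h"] == pytest.approx(2.0)

    def test_phase_subsets(self):
        out = sq.cycle_effect_summary(
            [20.0, 20.0, 20.0, 20.0], [26.0, 27.0, 20.0, 21.0],
            treated_phases=["G1/S", "G1/S", "S", "S"], seed=0, n_boot=200)
        assert out["g1s_mean_difference_h"] == pytest.approx(6.5)
        assert out["s_mean_h"] == pytest.approx(20.5)

    def test_bootstrap_ci_seeded_and_contains_effect(self):
        rng = np.random.default_rng(1)
        u = rng.normal(20, 2, 150)
        t = rng.normal(22, 2, 150)
        a = sq.cycle_effect_summary(u, t, seed=5, n_boot=500)
        b = sq.cycle_effect_summary(u, t, seed=5, n_boot=500)
        assert a["mean_difference_ci_h"] == b["mean_difference_ci_h"]
        lo, hi = a["mean_difference_ci_h"]
        assert lo < 2.0 < hi


class TestBootstrapCoverage:
    def test_ci_covers_programmed_effect(self):
        """Over 100 scaled-down generator replicates (60 cells/arm), the
        bootstrap CI for the mean cycle lengthening covers the programmed
        population effect at >= 90% empirical coverage."""
        from scipy.stats import norm
        from nfkbe2f import synthetic_data as sd
        from nfkbe2f.trace_features import cycle_durations

        eff = sd.CycleEffect()
        # expected per-cell delay: truncated-normal mean times the
        # susceptible-window probability (closed form, independent oracle)
        mu, s = eff.lengthening_mean_h, eff.lengthening_sd_h
        a = mu / s
        trunc_mean = mu * norm.cdf(a) + s * norm.pdf(a)
        p_window = eff.susceptible_hi - eff.susceptible_lo
        programmed = p_window * trunc_mean

        hits = 0
        n_rep = 100
        for r in range(n_rep):
            dur = {}
            for dose, seed in ((0.0, 2 * r), (1.0, 2 * r + 1)):
                cfg = sd.PopulationConfig(n_cells=60, seed=10_000 + seed,
                                          dose_scale=dose, record_h=60.0,
                                          simulate=False)
                traces = sd.generate_population(cfg)
                t_h = cfg.treatment_time_h
                vals = []
                for tr in traces:
                    before = [m for m in tr.mitosis_times_h if m <= t_h]
                    after = [m for m in tr.mitosis_times_h if m > t_h]
                    if before and after:
                        vals.append(min(after) - max(before))
                dur[dose] = vals
            out = sq.cycle_effect_summary(dur[0.0], dur[1.0], seed=r,
                                          n_boot=300)
            lo, hi = out["mean_difference_ci_h"]
            hits += lo <= programmed <= hi
        assert hits / n_rep >= 0.90
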
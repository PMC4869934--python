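"""Model-construction, conservation, reduction and behaviour tests."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from nfkbe2f import kinetics as kin


GRID = np.arange(0.0, 601.0, 2.0)
TNF = kin.StimulusProtocol(0.0, np.inf, 1.0)


class TestBuildModel:
    def test_variant_species_nesting(self):
        base = kin.build_model("base")
        e2f1 = kin.build_model("e2f1")
        revised = kin.build_model("revised")
        assert not any("E2F" in s for s in base.species)
        assert set(base.species) < set(e2f1.species) < set(revised.species)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            kin.build_model("extended")

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            kin.build_model("base", {"k_nonexistent": 1.0})

    def test_negative_override_rejected(self):
        with pytest.raises(ValueError):
            kin.build_model("base", {"k_ikk_act": -0.1})

    def test_hill_coefficient_below_one_rejected(self):
        with pytest.raises(ValueError):
            kin.build_model("base", {"h_tikba": 0.5})


class TestEquilibrate:
    def test_fixed_point(self, base_model, base_equilibrium):
        again = kin.equilibrate(base_model, init=base_equilibrium,
                                horizon=100.0)
        assert np.allclose(again, base_equilibrium, rtol=1e-6, atol=1e-8)

    def test_resting_state_is_cytoplasmic(self, base_model, base_equilibrium):
        assert kin.nc_ratio(base_model, base_equilibrium) < 1.0

    def test_high_e2f1_gives_nuclear_rela(self):
        m = kin.build_model("e2f1", {"k_e2f1_syn": 2.0})
        eq = kin.equilibrate(m, horizon=30000.0, tol=1e-6)
        assert kin.nc_ratio(m, eq) > 1.0

    def test_extra_ikba_restores_cytoplasmic_rela(self):
        # IkBa co-expression rescues the localization despite high E2F-1
        m = kin.build_model("e2f1", {"k_e2f1_syn": 2.0, "k_tikba_basal": 2.0})
        eq = kin.equilibrate(m, horizon=30000.0, tol=1e-6)
        assert kin.nc_ratio(m, eq) < 1.0

    def test_unreachable_tolerance_reports_residual(self, base_model):
        with pytest.raises(kin.EquilibrationError) as err:
            kin.equilibrate(base_model, horizon=1.0, tol=1e-14)
        assert err.value.residual > 0


class TestSimulateCell:
    def test_zero_dose_stays_flat(self, base_model, base_equilibrium):
        traj = kin.simulate_cell(base_model, base_equilibrium,
                                 kin.StimulusProtocol(0, np.inf, 0.0), GRID)
        nc = traj.nc
        assert np.max(np.abs(nc - nc[0])) < 1e-6 * nc[0]

    def test_sustained_tnf_oscillates(self, base_trajectory):
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(base_trajectory.nc, prominence=0.05)
        assert len(peaks) >= 3

    def test_rela_conserved(self, base_model, base_equilibrium):
        grid = np.arange(0.0, 1001.0, 2.0)
        traj = kin.simulate_cell(base_model, base_equilibrium, TNF, grid)
        total = kin.total_rela(base_model, traj.y.T)
        drift = np.abs(total / total[0] - 1.0)
        assert drift.max() < 1e-6

    def test_tolerance_halving_stability(self, base_model, base_equilibrium):
        a = kin.simulate_cell(base_model, base_equilibrium, TNF, GRID,
                              rtol=1e-8, atol=1e-10)
        b = kin.simulate_cell(base_model, base_equilibrium, TNF, GRID,
                              rtol=5e-9, atol=5e-11)
        rel = np.max(np.abs(a.nc - b.nc)) / np.max(np.abs(a.nc))
        assert rel < 1e-3

    def test_pure_decay_matches_closed_form(self):
        # all couplings off: free nuclear IkBa decays as exp(-k t)
        m = kin.build_model("base", {
            "kf_nfkb_ikba": 0.0, "kr_nfkb_ikba": 0.0, "k_ikba_import": 0.0,
            "k_ikba_export": 0.0, "k_tikba_basal": 0.0, "k_tikba_max": 0.0,
            "k_ikba_tl": 0.0, "k_ikba_deg": 0.01,
        })
        y0 = np.zeros(len(m.species))
        y0[m.index["IkBa_n"]] = 50.0
        traj = kin.simulate_cell(m, y0, kin.NO_STIMULUS, GRID)
        expected = 50.0 * np.exp(-0.01 * GRID)
        rel = np.abs(traj.series("IkBa_n") - expected) / expected
        assert rel.max() < 1e-6

    def test_non_monotone_grid_rejected(self, base_model, base_equilibrium):
        with pytest.raises(ValueError):
            kin.simulate_cell(base_model, base_equilibrium, TNF,
                              np.array([0.0, 10.0, 5.0]))


class TestReductionLimits:
    def test_e2f1_reduces_to_base(self, base_model, base_equilibrium):
        me = kin.build_model("e2f1", {"k_e2f1_syn": 0.0})
        y0 = np.zeros(len(me.species))
        y0[: len(base_model.species)] = base_equilibrium
        tb = kin.simulate_cell(base_model, base_equilibrium, TNF, GRID)
        te = kin.simulate_cell(me, y0, TNF, GRID)
        shared = te.y[: len(base_model.species)]
        assert np.max(np.abs(tb.y - shared)) < 1e-8

    def test_revised_reduces_to_e2f1(self):
        me = kin.build_model("e2f1")
        mr = kin.build_model("revised", {"kf_e2f4": 0.0})
        eq = kin.equilibrate(me, horizon=30000.0, tol=1e-6)
        y0 = np.zeros(len(mr.species))
        y0[: len(me.species)] = eq
        te = kin.simulate_cell(me, eq, TNF, GRID)
        tr = kin.simulate_cell(mr, y0, TNF, GRID)
        shared = tr.y[: len(me.species)]
        assert np.max(np.abs(te.y - shared)) < 1e-8


class TestRevisedBehaviour:
    def test_e2f4_monotonically_damps_first_peak(self):
        """More E2F-4 delays and damps the first post-TNF translocation."""
        peaks = []
        for e2f4_0 in (0.0, 30.0, 90.0):
            m = kin.build_model("revised", {"k_e2f4_syn": 0.0})
            eq_base = kin.equilibrate(kin.build_model("base"))
            y0 = np.zeros(len(m.species))
            y0[: len(eq_base)] = eq_base
            y0[m.index["E2F4_c"]] = e2f4_0
            traj = kin.simulate_cell(m, y0, TNF, np.arange(0.0, 241.0, 2.0))
            peaks.append(traj.nc.max())
        assert peaks[0] > peaks[1] > peaks[2]

    def test_variant_split_immediate_vs_delayed(self):
        """With co-expressed E2F-1, the e2f1 variant responds within one
        base oscillation period while the revised variant's second peak is
        delayed by more than twice the base inter-peak interval."""
        from nfkbe2f.trace_features import detect_peaks

        base = kin.build_model("base")
        eqb = kin.equilibrate(base)
        tb = kin.simulate_cell(base, eqb, TNF, GRID)
        pt_b, _ = detect_peaks(tb.t, tb.nc)
        period = pt_b[1] - pt_b[0]

        grid = np.arange(0.0, 1501.0, 2.0)
        def coexpression_run(variant):
            m = kin.build_model(variant)
            y0 = np.zeros(len(m.species))
            ix = m.index
            y0[ix["NFkB_E2F1_n"]] = 0.95 * m.params["NFkB_total"]
            y0[ix["NFkB_IkBa_c"]] = 0.05 * m.params["NFkB_total"]
            y0[ix["E2F1_n"]] = 150.0
            y0[ix["IKKn"]] = m.params["IKK_total"]
            return kin.simulate_cell(m, y0, TNF, grid, rtol=1e-6, atol=1e-8)

        te = coexpression_run("e2f1")
        pt_e, _ = detect_peaks(te.t, te.nc)
        assert pt_e[0] <= period          # immediate first response

        tr = coexpression_run("revised")
        pt_r, _ = detect_peaks(tr.t, tr.nc)
        assert len(pt_r) >= 2
        assert pt_r[1] > 2.0 * period     # delayed oscillation onset


class TestCoexpressionDelay:
    def test_monotone_in_half_life(self):
        m = kin.build_model("e2f1")
        t1 = kin.simulate_coexpression_delay(m, 60.0)
        t2 = kin.simulate_coexpression_delay(m, 300.0)
        t3 = kin.simulate_coexpression_delay(m, 900.0, t_end=6000.0)
        assert t1 <= t2 <= t3

    def test_half_life_sweep_rank_correlation(self):
        """30-cell half-life sweep: strong positive rank correlation between
        E2F-1 decay time and RelA nuclear-occupancy time."""
        m = kin.build_model("e2f1")
        hls = np.linspace(60.0, 1200.0, 30)
        ts = [kin.simulate_coexpression_delay(m, h, t_end=8000.0, dt=4.0)
              for h in hls]
        rho = spearmanr(hls, ts).statistic
        assert rho > 0.9

    def test_requires_e2f1_variant(self, base_model):
        with pytest.raises(ValueError):
            kin.simulate_coexpression_delay(base_model, 100.0)


class TestStimulusProtocol:
    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            kin.StimulusProtocol(10.0, 5.0, 1.0)

    def test_dose_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            kin.StimulusProtocol(0.0, np.inf, 1.5)
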
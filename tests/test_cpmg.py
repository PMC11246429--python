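"""Two-state CPMG dispersion: forward models, statistics, global fit."""

import numpy as np
import pandas as pd
import pytest

from nmrbind.core import DispersionTable
from nmrbind.cpmg import (
    DEFAULT_CYCLES,
    DEFAULT_T_RELAX,
    carver_richards_rate,
    cycle_count,
    delta_r2,
    detect_dispersion,
    fast_exchange_rex,
    global_fit,
    nitrogen_omega,
    r2eff_from_intensities,
    simulate_bm,
    simulate_cr,
)
from nmrbind.synth import gen_dispersion

T = DEFAULT_T_RELAX
NUS = np.array(DEFAULT_CYCLES) / T


class TestR2eff:
    def test_no_decay(self):
        assert r2eff_from_intensities(50.0, 50.0, T) == 0.0

    def test_hand_evaluation(self):
        assert r2eff_from_intensities(0.8, 1.0, T) == pytest.approx(6.973, abs=5e-4)

    def test_unit_case(self):
        assert r2eff_from_intensities(np.e**-1, 1.0, 1.0) == pytest.approx(1.0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            r2eff_from_intensities(0.0, 1.0, T)


class TestCycleRule:
    def test_study_grid_endpoints(self):
        # 31.35 Hz -> 1 cycle, 1000 Hz -> 32 cycles at 32 ms
        assert cycle_count(31.35, T) == 1
        assert cycle_count(1000.0, T) == 32

    def test_sub_cycle_rejected(self):
        with pytest.raises(ValueError):
            cycle_count(10.0, T)


class TestForwardModels:
    def test_no_shift_difference_gives_baseline(self):
        for sim in (simulate_bm, simulate_cr):
            out = sim(NUS, T, 600.0, 0.0, 662.0, 0.089, 5.0)
            assert np.allclose(out, 5.0, atol=1e-9)

    def test_no_minor_state_gives_free_baseline(self):
        for sim in (simulate_bm, simulate_cr):
            out = sim(NUS, T, 600.0, 3.0, 662.0, 0.0, 5.0)
            assert np.allclose(out, 5.0, atol=1e-9)

    def test_fast_exchange_closed_form(self):
        # k_ex = 1e5 s-1, p_b = 0.1, dw = 1000 rad/s, r2_0 = 5 -> ~5.90, flat
        dw_ppm = 1000.0 / (2 * np.pi * 600.0 * 0.101329)
        out = simulate_bm(NUS, T, 600.0, dw_ppm, 1e5, 0.1, 5.0)
        expected = 5.0 + fast_exchange_rex(1000.0, 1e5, 0.1)
        assert out[0] == pytest.approx(expected, abs=0.01)
        assert np.ptp(out) < 0.05 * 0.9  # essentially flat in nu

    def test_oracle_equivalence_spot_grid(self):
        kex, pb, dw = np.meshgrid(
            [150.0, 662.0, 2500.0], [0.02, 0.089, 0.2], [0.5, 2.0, 4.0],
            indexing="ij",
        )
        for fm in (600.0, 850.0):
            for nu in NUS[::4]:
                bm = simulate_bm(nu, T, fm, dw, kex, pb, 8.0)
                cr = simulate_cr(nu, T, fm, dw, kex, pb, 8.0)
                assert np.abs(bm - cr).max() < 0.1

    def test_high_frequency_limit_refocuses(self):
        # at nu -> inf the shift difference is fully refocused
        out = simulate_cr(1000.0, T, 600.0, 2.0, 662.0, 0.089, 5.0)
        lo = simulate_cr(31.35, T, 600.0, 2.0, 662.0, 0.089, 5.0)
        assert lo > out
        fine = simulate_bm(np.array([4000.0]), 0.032, 600.0, 2.0, 662.0, 0.089, 5.0)
        assert fine[0] < out

    def test_monotone_non_increasing_in_nu(self):
        # representative (fast-to-intermediate) exchange; deep in slow
        # exchange dispersion profiles are legitimately non-monotone
        for kex, dw in ((300.0, 2.0), (662.0, 3.0), (1500.0, 3.0)):
            prof = simulate_cr(NUS, T, 600.0, dw, kex, 0.089, 7.0)
            assert np.all(np.diff(prof) <= 1e-9)

    def test_rate_only_expression_in_fast_regime(self):
        """The classic rate-only expression agrees with the exact closed form
        when exchange is fast compared to the shift difference."""
        dw = 1.0
        for fm in (600.0, 850.0):
            kex = 10.0 * nitrogen_omega(dw, fm)
            rate = carver_richards_rate(NUS, T, fm, dw, kex, 0.089, 5.0)
            exact = simulate_cr(NUS, T, fm, dw, kex, 0.089, 5.0)
            assert np.abs(rate - exact).max() < 0.05

    def test_different_state_baselines_supported(self):
        out = simulate_bm(NUS, T, 600.0, 0.0, 5000.0, 0.1, 5.0, r2_0b=25.0)
        # fast exchange with dw = 0: population-weighted average baseline
        assert out[-1] == pytest.approx(0.9 * 5.0 + 0.1 * 25.0, abs=0.05)


class TestDispersionStatistics:
    def profile(self, values, err=0.5):
        return pd.DataFrame(
            {"nu_cpmg_hz": NUS, "r2eff": values, "error": err}
        )

    def test_flat_profile_delta(self):
        dr2, err = delta_r2(self.profile(np.full(len(NUS), 8.0)))
        assert dr2 == pytest.approx(0.0)
        assert err == pytest.approx(1.0)

    def test_exchange_gives_positive_delta(self):
        vals = simulate_bm(NUS, T, 600.0, 3.0, 662.0, 0.089, 8.0)
        dr2, _ = delta_r2(self.profile(vals))
        assert dr2 > 0

    def test_missing_endpoint_is_error(self):
        prof = self.profile(np.full(len(NUS), 8.0))
        prof = prof[prof["nu_cpmg_hz"] > 100]
        with pytest.raises(ValueError, match="31.35"):
            delta_r2(prof)

    def test_detection_rules(self):
        flat = self.profile(np.full(len(NUS), 8.0))
        assert detect_dispersion(flat)[0] == "flat"
        strong = self.profile(
            np.linspace(13.0, 8.0, len(NUS))  # dR2 = 5 with 0.5 errors
        )
        flag, score = detect_dispersion(strong)
        assert flag == "dispersing" and score == pytest.approx(5.0)
        borderline = self.profile(np.linspace(9.4, 8.0, len(NUS)), err=0.25)
        assert detect_dispersion(borderline)[0] == "flat"  # 1.4 < 3 * 0.5

    def test_too_few_points_undetermined(self):
        prof = self.profile(np.full(len(NUS), 8.0)).iloc[:4]
        assert detect_dispersion(prof)[0] == "undetermined"


class TestGlobalFit:
    def test_noiseless_exact_recovery(self):
        table, truth = gen_dispersion(
            [1, 2, 3], {1: 1.5, 2: 2.5, 3: 3.5}, 662.0, 0.089,
            noise_sd=0.0, seed=0,
        )
        fit = global_fit(table, seed=0)
        assert fit.chi2 < 1e-6
        assert fit.k_ex == pytest.approx(662.0, rel=1e-3)
        assert fit.p_b == pytest.approx(0.089, rel=1e-3)
        for res, dw in {1: 1.5, 2: 2.5, 3: 3.5}.items():
            assert fit.dw_ppm[res] == pytest.approx(dw, abs=1e-3)

    def test_derived_binding_consistency(self):
        table, _ = gen_dispersion([1, 2], {1: 2.0, 2: 3.0}, 662.0, 0.089,
                                  noise_sd=0.0, seed=1)
        fit = global_fit(table, seed=1)
        derived = fit.derive_binding(100.0, 10.0)
        from nmrbind.binding import kd_from_bound_fraction
        assert derived.kd == kd_from_bound_fraction(fit.p_b, 100.0, 10.0)

    def test_single_residue_single_field_flagged_degenerate(self):
        table, _ = gen_dispersion([1], {1: 2.0}, 662.0, 0.089,
                                  fields_mhz=(600.0,), noise_sd=0.0, seed=2)
        fit = global_fit(table, seed=2)
        assert fit.diagnostics["degenerate"]

    def test_noisy_recovery_single_seed(self):
        rng = np.random.default_rng(3)
        dw_map = {r: float(rng.uniform(1, 4)) for r in range(1, 9)}
        table, _ = gen_dispersion(list(dw_map), dw_map, 662.0, 0.089,
                                  noise_sd=0.5, seed=3)
        fit = global_fit(table, seed=3)
        assert abs(fit.k_ex - 662.0) / 662.0 < 0.15
        assert abs(fit.p_b - 0.089) < 0.02
        assert fit.k_ex_error > 0 and fit.p_b_error > 0

    def test_empty_table_is_error(self):
        table = DispersionTable(pd.DataFrame(columns=DispersionTable.COLUMNS))
        with pytest.raises(ValueError):
            global_fit(table)
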
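"""Decay fitting and residue-wise K_D estimation from R1rho titrations."""

import numpy as np
import pandas as pd
import pytest

from nmrbind.binding import bound_fraction_exact
from nmrbind.core import DecayTable, SequenceRecord, TitrationDesign
from nmrbind.relaxation import (
    fit_all_site_kds,
    fit_decay,
    fit_site_kd,
    predict_r1rho,
)
from nmrbind.synth import R1RHO_DELAYS, gen_titration_rates


class TestFitDecay:
    def test_noiseless_exact_recovery(self, decay_table):
        prof = fit_decay(decay_table, n_mc=50, seed=0)
        assert prof["r1rho"].iloc[0] == pytest.approx(5.0, abs=1e-6)
        assert prof["flag"].iloc[0] == "ok"

    def test_noisy_recovery_within_mc_band(self):
        rng = np.random.default_rng(42)
        clean = 100.0 * np.exp(-5.0 * R1RHO_DELAYS)
        noisy = clean * (1 + rng.normal(0, 0.02, len(clean)))
        rows = [(1, t, y, 0.02 * 100.0) for t, y in zip(R1RHO_DELAYS, noisy)]
        table = DecayTable(pd.DataFrame(rows, columns=DecayTable.COLUMNS))
        prof = fit_decay(table, n_mc=200, seed=7)
        sigma = prof["r1rho_error"].iloc[0]
        assert sigma > 0
        assert abs(prof["r1rho"].iloc[0] - 5.0) < 3 * sigma

    def test_flat_intensities_flagged_baseline(self):
        rows = [(1, t, 100.0, 1.0) for t in R1RHO_DELAYS]
        table = DecayTable(pd.DataFrame(rows, columns=DecayTable.COLUMNS))
        prof = fit_decay(table, n_mc=20, seed=0)
        assert prof["flag"].iloc[0] == "baseline"
        assert abs(prof["r1rho"].iloc[0]) < 0.1


class TestPredictR1rho:
    def test_no_partner_returns_free_rate(self):
        assert predict_r1rho(100.0, 0.0, 177.0, 3.0, 30.0) == 3.0

    def test_hand_evaluation(self):
        # 50/(100+100) * (23-3) + 3 = 8
        assert predict_r1rho(100.0, 50.0, 100.0, 3.0, 23.0) == pytest.approx(8.0)

    def test_degenerate_equal_rates(self):
        assert predict_r1rho(100.0, 80.0, 5.0, 7.0, 7.0) == pytest.approx(7.0)


def rates_from_curve(design, values, err=0.05):
    rows = [
        (900, lab, v, err) for (lab, _), v in zip(design.points, values)
    ]
    return pd.DataFrame(
        rows, columns=["residue_number", "point_label", "r1rho", "r1rho_error"]
    )


class TestFitSiteKd:
    def test_closed_form_inversion(self, study_design):
        rates = rates_from_curve(
            study_design,
            [predict_r1rho(100.0, b, 177.0, 3.0, 30.0)
             for b in study_design.b_totals],
        )
        fit = fit_site_kd(rates, study_design, 30.0, 900, n_mc=100, seed=0)
        assert fit.flag == "ok"
        assert fit.slope == pytest.approx(27.0 / 277.0, rel=1e-9)
        assert fit.kd == pytest.approx(177.0, rel=1e-9)
        assert fit.kd_lo < 177.0 < fit.kd_hi

    def test_flat_rates_flag_no_binding(self, study_design):
        fit = fit_site_kd(
            rates_from_curve(study_design, [3.0] * 4), study_design, 30.0, 900,
            n_mc=10, seed=0,
        )
        assert fit.flag == "no_binding"
        assert fit.kd is None

    def test_descending_rates_invalid(self, study_design):
        fit = fit_site_kd(
            rates_from_curve(study_design, [9.0, 7.0, 5.0, 3.0]),
            study_design, 30.0, 900, n_mc=10, seed=0,
        )
        assert fit.flag == "invalid"

    def test_too_few_points_is_error(self, study_design):
        rates = rates_from_curve(study_design, [3.0, 4.0, 5.0, 6.0]).iloc[:2]
        with pytest.raises(ValueError, match="3 valid"):
            fit_site_kd(rates, study_design, 30.0, 900)


class TestWeakBindingApproximation:
    """The linear relation approximates the exact bound fraction by
    p_b ~ b / (kd + a); its relative error is (b - complex) / (kd + a),
    so it is bounded by b / (kd + a) and shrinks as the partner admixture
    becomes small against kd + a_total."""

    def test_relative_error_obeys_algebraic_bound(self):
        a = 100.0
        for kd in (50.0, 177.0, 549.0, 2000.0):
            for b_frac in (0.02, 0.05, 0.1):
                b = b_frac * (kd + a)
                approx = b / (kd + a)
                exact = bound_fraction_exact(a, b, kd)
                err = abs(approx - exact) / exact
                assert err <= b / (kd + a) + 1e-12

    def test_error_within_five_percent_at_small_admixture(self):
        a = 100.0
        for kd in (50.0, 177.0, 549.0, 2000.0):
            for b_frac in (0.01, 0.02, 0.04):
                b = b_frac * (kd + a)
                approx = b / (kd + a)
                exact = bound_fraction_exact(a, b, kd)
                assert abs(approx - exact) / exact < 0.05

    def test_error_grows_with_partner_admixture(self):
        a, kd = 100.0, 177.0
        errs = []
        for b in (5.0, 15.0, 30.0, 60.0):
            approx = b / (kd + a)
            exact = bound_fraction_exact(a, b, kd)
            errs.append(abs(approx - exact) / exact)
        assert errs == sorted(errs)

    def test_exact_generator_reveals_linearisation_bias_at_tight_binding(self, study_design):
        """With kd far below a_total, rates from the exact model are no longer
        linear in b and the linear-fit K_D is biased."""
        seq = SequenceRecord("x", "L", 500)
        rates, _, _ = gen_titration_rates(
            seq, {500: 5.0}, study_design, 3.0, 30.0, noise_sd=0.0, seed=0,
            model="exact",
        )
        rates["r1rho_error"] = 0.05
        fit = fit_site_kd(rates, study_design, 30.0, 500, n_mc=10, seed=0)
        assert fit.flag == "ok"
        assert abs(fit.kd - 5.0) / 5.0 > 0.5


class TestSeededRecovery:
    def test_median_kd_recovery_small(self, study_design):
        """Small-scale version of the K_D recovery experiment (2 % noise)."""
        seq = SequenceRecord("x", "L", 700)
        recovered = []
        for seed in range(10):
            rates, _, _ = gen_titration_rates(
                seq, {700: 294.0}, study_design, 3.0, 30.0,
                noise_sd=0.02, seed=seed,
            )
            fits = fit_all_site_kds(rates, study_design, 30.0, n_mc=50, seed=seed)
            if fits["flag"].iloc[0] == "ok":
                recovered.append(fits["kd_uM"].iloc[0])
        assert abs(np.median(recovered) - 294.0) / 294.0 < 0.15
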
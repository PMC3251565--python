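"""Model-free fitting, model selection, and tau_m estimation."""

import numpy as np
import pytest

from spindyn import (
    DiffusionModel,
    DynamicsParams,
    SelectionConfig,
    SpectrometerContext,
    chi_square,
    estimate_tm_r2r1,
    fit_model,
    make_profile,
    monte_carlo_errors,
    optimize_tm,
    predict_rates,
    select_model,
    simulate_rates,
)
from spindyn.modelfree import ResidueRelaxationRecord, _rigid_r2_over_r1

from conftest import TM_S, record_for


def synthetic_record(params, diffusion, context, sigma_frac=0.02, residue_id=1):
    r1, r2, noe = predict_rates(params, diffusion, context)
    return ResidueRelaxationRecord(
        residue_id=residue_id,
        r1=r1, r1_err=sigma_frac * r1,
        r2=r2, r2_err=sigma_frac * r2,
        noe=noe, noe_err=sigma_frac * max(abs(noe), 1.0),
        context=context,
    )


class TestChiSquare:
    def test_perfect_fit_is_zero(self, diffusion, context600):
        params = DynamicsParams(model_id=2, s2=0.7, te_s=0.2e-9)
        record = synthetic_record(params, diffusion, context600)
        assert chi_square(record, params, diffusion) == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_sigma_scaling(self, diffusion, context600):
        params = DynamicsParams(model_id=2, s2=0.7, te_s=0.2e-9)
        truth = DynamicsParams(model_id=2, s2=0.6, te_s=0.2e-9)
        base = synthetic_record(truth, diffusion, context600, sigma_frac=0.02)
        double = synthetic_record(truth, diffusion, context600, sigma_frac=0.04)
        assert chi_square(base, params, diffusion) == pytest.approx(
            4.0 * chi_square(double, params, diffusion), rel=1e-9
        )

    def test_printed_record_against_hand_evaluation(self, diffusion, table4_records):
        # independently derived (50-digit mpmath) residuals of the
        # published R49 mutant triplet vs its published parameters;
        # sigma floor disabled so the printed errors weight directly
        params = DynamicsParams(model_id=2, s2=0.53, te_s=1.04e-9)
        chi2 = chi_square(table4_records["R49_P48A"], params, diffusion, sigma_floor=0.0)
        assert chi2 == pytest.approx(973.1766096566779, rel=1e-9)

    def test_nonpositive_sigma_rejected(self, diffusion, context600):
        record = ResidueRelaxationRecord(
            residue_id=1, r1=1.6, r1_err=0.0, r2=6.0, r2_err=0.0,
            noe=0.5, noe_err=0.0, context=context600,
        )
        params = DynamicsParams(model_id=1, s2=0.8)
        with pytest.raises(ValueError):
            chi_square(record, params, diffusion, sigma_floor=0.0)


class TestFitModel:
    def test_noiseless_roundtrip_model4(self, diffusion, context600):
        truth = DynamicsParams(model_id=4, s2=0.75, te_s=0.11e-9, rex=0.91)
        record = synthetic_record(truth, diffusion, context600, sigma_frac=0.005)
        fit = fit_model(record, 4, diffusion)
        assert fit.params.s2 == pytest.approx(0.75, abs=1e-4)
        assert fit.params.te_s == pytest.approx(0.11e-9, rel=1e-3)
        assert fit.params.rex == pytest.approx(0.91, abs=1e-4)

    @pytest.mark.parametrize(
        "key,expected_s2", [("R49_P48A", 0.53), ("D51_P48A", 0.61)]
    )
    def test_published_mutant_order_parameters(self, diffusion, table4_records, key, expected_s2):
        fit = fit_model(table4_records[key], 2, diffusion)
        assert fit.params.s2 == pytest.approx(expected_s2, abs=0.05)

    def test_nested_chi2_dominance(self, diffusion, table4_records, context600):
        records = list(table4_records.values()) + [
            synthetic_record(
                DynamicsParams(model_id=4, s2=0.6, te_s=0.5e-9, rex=1.0),
                diffusion, context600,
            )
        ]
        for record in records:
            chi = {m: fit_model(record, m, diffusion).chi2 for m in (1, 2, 3, 4)}
            slack = 1e-6 * (1.0 + chi[1])
            assert chi[2] <= chi[1] + slack
            assert chi[3] <= chi[1] + slack
            assert chi[4] <= chi[2] + slack
            assert chi[4] <= chi[3] + slack

    def test_grid_search_oracle_agreement(self, diffusion, table4_records):
        # exhaustive 2-D scan: S2 step 0.005, te log-spaced 1 ps - 10 ns
        record = table4_records["R49_P48A"]
        s2_grid = np.arange(0.0, 1.0 + 1e-9, 0.005)
        te_grid = np.concatenate([[0.0], np.geomspace(1e-12, 1e-8, 240)])
        te_grid = te_grid[te_grid <= TM_S]
        best = (np.inf, None, None)
        for s2 in s2_grid:
            for te in te_grid:
                c = chi_square(
                    record, DynamicsParams(model_id=2, s2=s2, te_s=te), diffusion
                )
                if c < best[0]:
                    best = (c, s2, te)
        fit = fit_model(record, 2, diffusion)
        assert fit.params.s2 == pytest.approx(best[1], abs=0.005)
        # within one log-spaced grid cell of the oracle's te
        ratio = fit.params.te_s / best[2]
        assert 1 / 1.05 < ratio < 1.05
        assert fit.chi2 <= best[0] + 1e-9


class TestSelectModel:
    def test_rigid_residue_selects_simplest_model(self, diffusion, context600):
        truth = DynamicsParams(model_id=1, s2=0.85)
        rng = np.random.default_rng(11)
        hits = 0
        n_trials = 25
        for trial in range(n_trials):
            r1, r2, noe = predict_rates(truth, diffusion, context600)
            noisy = np.array([r1, r2, noe]) * (1 + rng.normal(0, 0.02, 3))
            record = ResidueRelaxationRecord(
                residue_id=trial, r1=noisy[0], r1_err=0.02 * r1,
                r2=noisy[1], r2_err=0.02 * r2, noe=noisy[2], noe_err=0.02,
                context=context600,
            )
            fit = select_model(record, diffusion, config=SelectionConfig(n_sims=200, seed=5))
            hits += fit.params.model_id == 1
        assert hits >= 0.9 * n_trials

    def test_exchange_residue_selects_rex_model(self, diffusion, context600):
        truth = DynamicsParams(model_id=3, s2=0.8, rex=1.4)
        rng = np.random.default_rng(13)
        hits = 0
        n_trials = 15
        for trial in range(n_trials):
            r1, r2, noe = predict_rates(truth, diffusion, context600)
            noisy = np.array([r1, r2, noe]) * (1 + rng.normal(0, 0.01, 3))
            record = ResidueRelaxationRecord(
                residue_id=trial, r1=noisy[0], r1_err=0.01 * r1,
                r2=noisy[1], r2_err=0.01 * r2, noe=noisy[2], noe_err=0.01,
                context=context600,
            )
            fit = select_model(record, diffusion, config=SelectionConfig(n_sims=200, seed=5))
            hits += fit.params.model_id in (3, 4) and fit.params.rex > 0
        assert hits > n_trials / 2

    @pytest.mark.parametrize("key", ["A48_P48A", "R49_P48A", "G50_P48A", "D51_P48A"])
    def test_published_mutant_rows_select_te_without_exchange(
        self, diffusion, table4_records, key
    ):
        # the published table shows internal correlation times but empty
        # exchange cells for every mutant RGD-loop residue
        fit = select_model(table4_records[key], diffusion)
        assert fit.params.rex == 0.0
        assert fit.params.te_s > 0.0

    @pytest.mark.parametrize("key", ["R49_WT", "D51_WT"])
    def test_wildtype_loop_rows_select_exchange(self, diffusion, table4_records, key):
        # conditional on the mutant tumbling time applying to the wild
        # type, the published wild-type R49/D51 rows demand exchange
        fit = select_model(table4_records[key], diffusion)
        assert fit.params.model_id in (3, 4)
        assert fit.params.rex > 0.0


class TestMonteCarloErrors:
    def test_determinism(self, diffusion, table4_records):
        record = table4_records["R49_P48A"]
        fit = fit_model(record, 2, diffusion)
        a = monte_carlo_errors(fit, record, diffusion, n_draws=50, seed=3)
        b = monte_carlo_errors(fit, record, diffusion, n_draws=50, seed=3)
        assert a.mc_sigmas == b.mc_sigmas

    def test_sigmas_shrink_with_noise(self, diffusion, context600):
        truth = DynamicsParams(model_id=2, s2=0.7, te_s=0.3e-9)
        tight = synthetic_record(truth, diffusion, context600, sigma_frac=0.002)
        loose = synthetic_record(truth, diffusion, context600, sigma_frac=0.02)
        fit_t = fit_model(tight, 2, diffusion, sigma_floor=0.0)
        fit_l = fit_model(loose, 2, diffusion, sigma_floor=0.0)
        sig_t = monte_carlo_errors(fit_t, tight, diffusion, n_draws=100, seed=1, sigma_floor=0.0)
        sig_l = monte_carlo_errors(fit_l, loose, diffusion, n_draws=100, seed=1, sigma_floor=0.0)
        assert sig_t.mc_sigmas["s2"] < sig_l.mc_sigmas["s2"]

    def test_order_parameter_uncertainty_magnitude(self, diffusion, table4_records):
        # published S2 uncertainty for the mutant R49 row is 0.02;
        # resampled uncertainty should be the same order of magnitude
        record = table4_records["R49_P48A"]
        fit = fit_model(record, 2, diffusion)
        out = monte_carlo_errors(fit, record, diffusion, n_draws=500, seed=0)
        assert 0.002 < out.mc_sigmas["s2"] < 0.2

    def test_failed_fit_rejected(self, diffusion, table4_records):
        from spindyn.modelfree import ModelFit

        bad = ModelFit(
            residue_id=1, params=DynamicsParams(model_id=1, s2=0.5),
            chi2=np.inf, dof=2, status="failed",
        )
        with pytest.raises(ValueError):
            monte_carlo_errors(bad, table4_records["R49_P48A"], diffusion)


class TestTauM:
    def test_r2r1_inversion_single_rigid_record(self, context600):
        diffusion = DiffusionModel(kind="isotropic", tm_s=TM_S)
        record = synthetic_record(
            DynamicsParams(model_id=1, s2=1.0), diffusion, context600, sigma_frac=0.005
        )
        assert estimate_tm_r2r1([record]) == pytest.approx(TM_S, rel=1e-6)

    def test_r2r1_on_rigid_ensemble(self, context600):
        profile = make_profile("rigid", n_residues=20, seed=3)
        records = simulate_rates(profile, context600)
        assert estimate_tm_r2r1(records) == pytest.approx(TM_S, abs=0.1e-9)

    def test_r2r1_robust_to_exchange_outlier(self, diffusion, context600):
        profile = make_profile("rigid", n_residues=20, seed=3)
        records = simulate_rates(profile, context600)
        outlier = synthetic_record(
            DynamicsParams(model_id=3, s2=0.85, rex=8.0),
            diffusion, context600, residue_id=99,
        )
        with_outlier = estimate_tm_r2r1(records + [outlier])
        without = estimate_tm_r2r1(records)
        assert abs(with_outlier - without) / without < 0.05

    def test_low_noe_fallback_warns(self, diffusion, context600):
        record = synthetic_record(
            DynamicsParams(model_id=2, s2=0.35, te_s=1.5e-9), diffusion, context600
        )
        assert record.noe < 0.65
        with pytest.warns(UserWarning, match="falling back"):
            estimate_tm_r2r1([record])

    def test_optimize_recovers_rigid_ensemble_tm(self, context600):
        profile = make_profile("rigid", n_residues=12, seed=5)
        records = simulate_rates(profile, context600)
        diffusion = optimize_tm(records)
        assert diffusion.tm_s == pytest.approx(TM_S, rel=0.01)

    def test_joint_fit_across_fields(self):
        # tau_m is a molecular property: 600- and 700-MHz records are
        # fitted jointly to one shared value
        profile = make_profile("rigid", n_residues=8, seed=5)
        recs600 = simulate_rates(profile, SpectrometerContext(proton_frequency_mhz=600.13))
        recs700 = simulate_rates(profile, SpectrometerContext(proton_frequency_mhz=700.13))
        diffusion = optimize_tm(recs600 + recs700)
        assert diffusion.tm_s == pytest.approx(TM_S, rel=0.01)

    def test_too_few_records_rejected(self, context600):
        profile = make_profile("rigid", n_residues=4, seed=5)
        records = simulate_rates(profile, context600)
        with pytest.raises(ValueError, match="underdetermined|>= 5"):
            optimize_tm(records)

    def test_rigid_ratio_monotone_in_tm(self, context600):
        ratios = [
            _rigid_r2_over_r1(tm * 1e-9, context600) for tm in (2.0, 4.0, 8.0, 16.0)
        ]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))
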
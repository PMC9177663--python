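"""Parameter estimation: round trips, noise robustness, error contracts."""

import dataclasses

import numpy as np
import pytest

import modkin as mk
from modkin.fitting import FitError, FlatResponseError, VelocityGrid


class TestMichaelisMenten:
    def test_noise_free_round_trip(self):
        truth = mk.KineticParameters(kcat=1.74, km=1.60, kx=1.0, alpha=1.0, beta=1.0)
        s = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        fit = mk.fit_michaelis_menten(s, mk.mm_velocity(s, truth))
        assert fit.kcat_hat == pytest.approx(1.74, rel=1e-6)
        assert fit.km_hat == pytest.approx(1.60, rel=1e-6)

    def test_noisy_estimates_within_ten_percent(self):
        truth = mk.KineticParameters(kcat=1.74, km=1.60, kx=1.0, alpha=1.0, beta=1.0)
        s = np.repeat([0.5, 1.0, 2.0, 4.0, 8.0], 6)
        rng = np.random.default_rng(21)
        v = mk.mm_velocity(s, truth) * (1 + rng.normal(0, 0.05, s.size))
        fit = mk.fit_michaelis_menten(s, v)
        assert fit.kcat_hat == pytest.approx(1.74, rel=0.10)
        assert fit.km_hat == pytest.approx(1.60, rel=0.10)
        assert fit.kcat_se > 0 and fit.km_se > 0

    def test_degenerate_inputs_rejected(self):
        s = np.array([0.5, 1.0, 2.0, 4.0])
        with pytest.raises(FitError, match="substrate dependence"):
            mk.fit_michaelis_menten(s, np.full(4, 0.7))
        with pytest.raises(FitError, match="distinct"):
            mk.fit_michaelis_menten(np.array([1, 1, 2, 2.0]), np.array([.1, .1, .2, .2]))


class TestMMFamily:
    def test_coupled_truth_gives_constant_efficiency(self, noise_free_grids):
        fits, errors = mk.fit_michaelis_menten_family(noise_free_grids["pro-pna"])
        assert not errors
        eff = np.array([f.efficiency for f in fits])
        assert np.std(eff) / np.mean(eff) <= 0.01

    def test_km_app_increases_with_x_under_specific_inhibition(self, noise_free_grids):
        fits, _ = mk.fit_michaelis_menten_family(noise_free_grids["arg-pna"])
        km = [f.km_hat for f in sorted(fits, key=lambda f: f.x)]
        assert all(a < b for a, b in zip(km, km[1:]))

    def test_failed_level_reported_others_proceed(self, noise_free_grids):
        g = noise_free_grids["ala-pna"]
        # corrupt one X level to constant velocities
        v = g.v.copy()
        v[g.x == 5.0] = 0.123
        bad = VelocityGrid(s=g.s, x=g.x, v=v, replicate=g.replicate,
                           s_unit=g.s_unit, x_unit=g.x_unit)
        fits, errors = mk.fit_michaelis_menten_family(bad)
        assert 5.0 in errors
        assert {f.x for f in fits} == set(bad.x_levels) - {5.0}


class TestGlobalModifierFit:
    @pytest.mark.parametrize("name,tol", [("arg-pna", 1e-3), ("ala-pna", 1e-3),
                                          ("pro-pna", 1e-3)])
    def test_noise_free_recovery(self, noise_free_grids, truths, name, tol):
        truth = truths[name]
        fit = mk.fit_general_modifier_global(noise_free_grids[name])
        assert fit.params.kcat == pytest.approx(truth.kcat, rel=tol)
        assert fit.params.km == pytest.approx(truth.km, rel=tol)
        assert fit.params.kx == pytest.approx(truth.kx, rel=tol)
        assert fit.params.alpha == pytest.approx(truth.alpha, rel=tol)
        assert fit.params.beta == pytest.approx(truth.beta, rel=tol)

    def test_coupled_truth_classified_catalytic(self, noise_free_grids):
        fit = mk.fit_general_modifier_global(noise_free_grids["pro-pna"])
        assert fit.params.alpha / fit.params.beta == pytest.approx(1.0, rel=1e-3)
        assert fit.mechanism.label == "hyperbolic catalytic activation"

    def test_single_modifier_level_unidentifiable(self, truths):
        d = mk.reference_designs()["arg-pna"]
        d = dataclasses.replace(d, modifier_levels=(0.0,), noise_cv=0.0)
        grid = mk.generate_velocity_grid(d, truths["arg-pna"], seed=0)
        with pytest.raises(FitError, match="modifier levels"):
            mk.fit_general_modifier_global(grid)

    def test_monte_carlo_median_error_and_stable_labels(self, truths):
        """5% CV, n=6, full-coverage grids: median relative error of alpha
        and beta stays small and the mechanism call never flips (20 seeded
        repeats per parameter set)."""
        from modkin.simulate import recovery_designs
        designs = recovery_designs()
        for name in ("arg-pna", "ala-pna"):
            truth = truths[name]
            labels, err_a, err_b = set(), [], []
            for rep in range(20):
                grid = mk.generate_velocity_grid(designs[name], truth, seed=1000 + rep)
                fit = mk.fit_general_modifier_global(grid)
                labels.add(fit.mechanism.label)
                err_a.append(abs(fit.params.alpha - truth.alpha) / truth.alpha)
                err_b.append(abs(fit.params.beta - truth.beta) / truth.beta)
            assert len(labels) == 1
            assert np.median(err_a) <= 0.15
            assert np.median(err_b) <= 0.15

    def test_print_selection_grid_flags_nonidentifiability(self, designs, truths):
        """The efficiency-table modifier selection for the strong
        specific-inhibition substrate stops far below alpha*KX, so the
        ternary branch is invisible there and the fit must say so."""
        grid = mk.generate_velocity_grid(designs["arg-pna"], truths["arg-pna"], seed=1001)
        fit = mk.fit_general_modifier_global(grid)
        assert any(f.startswith("se_blowup") for f in fit.flags)


class TestDoseResponse:
    truth = mk.KineticParameters(kcat=1.74, km=1.60, kx=5.0, alpha=0.82, beta=25.4)

    def _titration(self, s_fixed=1.0):
        x = np.concatenate([[0.0], np.logspace(-2, 3, 21)])
        v = mk.general_modifier_velocity(s_fixed, x, self.truth)
        return x, v

    def test_x50_matches_analytic_midpoint(self):
        x, v = self._titration()
        fit = mk.fit_dose_response(x, v, s_fixed=1.0)
        expected = mk.analytic_half_effect(1.0, self.truth)
        assert fit.x50_hat == pytest.approx(expected, rel=1e-4)
        assert fit.direction == "activation"
        assert fit.half_effect_kind == "AC50"

    def test_inhibition_direction(self):
        p = mk.KineticParameters(kcat=24.35, km=18.79, kx=50.0, alpha=30.39, beta=0.09)
        x = np.concatenate([[0.0], np.logspace(-1, 4, 21)])
        v = mk.general_modifier_velocity(2.0, x, p)
        fit = mk.fit_dose_response(x, v, s_fixed=2.0)
        assert fit.direction == "inhibition"
        assert fit.half_effect_kind == "IC50"

    def test_flat_response_detected(self):
        x = np.concatenate([[0.0], np.logspace(-2, 3, 11)])
        with pytest.raises(FlatResponseError, match="no modification"):
            mk.fit_dose_response(x, np.full_like(x, 0.8), s_fixed=1.0)

    def test_design_preconditions(self):
        with pytest.raises(FitError, match="levels"):
            mk.fit_dose_response([0, 1, 2, 3], [1, 2, 3, 4], s_fixed=1.0)
        with pytest.raises(FitError, match="decades"):
            mk.fit_dose_response([0, 1, 2, 3, 4], [1, 2, 3, 4, 5], s_fixed=1.0)


class TestSESFit:
    def test_noise_free_round_trip(self):
        q = mk.SESParameters(vmax_over_etot=0.5, km=300.0, ksi=400.0)
        s = np.linspace(100, 1000, 10)
        fit = mk.fit_ses(s, mk.ses_velocity(s, q))
        assert fit.params.vmax_over_etot == pytest.approx(0.5, rel=1e-3)
        assert fit.params.km == pytest.approx(300.0, rel=1e-3)
        assert fit.params.ksi == pytest.approx(400.0, rel=1e-3)
        assert not fit.flags

    def test_no_downturn_flags_ksi(self):
        q = mk.SESParameters(vmax_over_etot=0.5, km=300.0, ksi=1e6)
        s = np.linspace(100, 1000, 10)
        fit = mk.fit_ses(s, mk.ses_velocity(s, q))
        assert "ksi_unidentifiable" in fit.flags

    def test_modifier_coupling_recovered(self):
        q = mk.SESParameters(vmax_over_etot=0.5, km=300.0, ksi=400.0, kx_ses=0.1)
        s_levels = np.linspace(100, 1000, 10)
        s, x = np.meshgrid(s_levels, [0.0, 0.16])
        s, x = s.ravel(), x.ravel()
        v = mk.ses_velocity_with_modifier(s, x, q)
        fit = mk.fit_ses(s, v, x)
        assert fit.params.kx_ses == pytest.approx(0.1, rel=0.05)
        assert fit.params.ksi == pytest.approx(400.0, rel=0.05)

    def test_dose_dependent_accentuation_on_pgp_design(self, designs, truths):
        d = dataclasses.replace(designs["pgp"], noise_cv=0.0)
        grid = mk.generate_velocity_grid(d, truths["pgp"], seed=0)
        # at fixed S in the inhibited regime, v strictly decreases with X
        m = grid.s == 600.0
        order = np.argsort(grid.x[m])
        by_x = grid.v[m][order]
        levels = grid.x[m][order]
        means = [by_x[levels == lv].mean() for lv in np.unique(levels)]
        assert all(a > b for a, b in zip(means, means[1:]))
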
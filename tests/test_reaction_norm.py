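"""Tests of dispersion estimation, NB-GLM fitting and model selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import thermonorm as tn
from thermonorm import _nbglm
from thermonorm.reaction_norm import (
    ReactionNormFit,
    adjust_fdr,
    call_differential,
    estimate_dispersion,
    fit_reaction_norm,
    fit_reaction_norms,
)

TEMPS = np.repeat([13.0, 18.0, 23.0, 29.0], 6)
EFF = np.full(24, 1e6)


def _nb_counts(rng, mu, phi, size):
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestDispersion:
    def test_poisson_limit(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1000.0, size=24)
        est = estimate_dispersion(counts, TEMPS, EFF)
        assert est.phi < 0.01

    def test_monte_carlo_recovery(self):
        """φ = 0.2 recovered on average over 500 genes (means ≈ 1,000)."""
        rng = np.random.default_rng(1)
        phis = []
        Y = _nb_counts(rng, 1000.0, 0.2, size=(500, 24))
        for y in Y:
            phis.append(estimate_dispersion(y, TEMPS, EFF).phi)
        assert abs(np.mean(phis) - 0.2) < 0.05

    def test_constant_counts_near_floor(self):
        """Underdispersed (constant) counts collapse to the floor region."""
        est = estimate_dispersion(np.full(24, 500), TEMPS, EFF)
        assert est.phi < 1e-6

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            estimate_dispersion([5, 6, 7, 8], [13.0, 18.0, 23.0, 29.0], np.full(4, 1e6))


class TestFitReactionNorm:
    def test_flat_gene_selects_null(self):
        counts = np.full(24, 800)
        fit = fit_reaction_norm(counts, TEMPS, EFF)
        assert fit.model == "null"
        assert fit.fold_change == pytest.approx(1.0, abs=1e-6)

    def test_vertex_arithmetic(self):
        """T_m = −b1/(2 b2): a noiseless parabola with vertex at 21 °C."""
        log2_mu = 8.0 + 0.02 * (np.asarray(TEMPS) - 21.0) ** 2  # b1 = −0.84, b2 = 0.02
        counts = np.round(2.0**log2_mu).astype(int)
        fit = fit_reaction_norm(counts, TEMPS, EFF)
        assert fit.model == "quadratic"
        b0, b1, b2 = fit.poly_coefficients
        assert -b1 / (2 * b2) == pytest.approx(21.0, abs=0.05)
        assert fit.derived_params["Tm"] == pytest.approx(21.0, abs=0.05)

    def test_slope_recovery_monte_carlo(self):
        """Mean estimated slope over 500 linear genes within ±0.01 of 0.15."""
        cfg = tn.SimulationConfig(
            n_genes=500,
            class_proportions={"increasing-linear": 1.0},
            effect_size_g1=0.15,
            dispersion=0.05,
            seed=2,
        )
        matrix, truth = tn.simulate_counts(cfg)
        L = matrix.samples["library_size_nominal"].to_numpy()
        # fix the slope exactly at 0.15 by regenerating with known coefficients
        fits = fit_reaction_norms(matrix.counts, matrix.temperatures, L)
        assert abs(fits["b1"].mean() - truth["b1"].mean()) < 0.01

    def test_needs_three_temperatures(self):
        with pytest.raises(ValueError, match="3 distinct temperatures"):
            fit_reaction_norm(np.arange(8), np.repeat([13.0, 29.0], 4), np.full(8, 1e6))

    def test_matches_statsmodels_oracle(self):
        """Batch IRLS vs statsmodels NB GLM at the same fixed dispersion."""
        rng = np.random.default_rng(3)
        phi = 0.1
        temps = np.asarray(TEMPS)
        x = temps - temps.mean()
        X = np.column_stack([np.ones(24), x, x**2])
        mu_true = np.exp(5.0 + 0.05 * x)
        Y = _nb_counts(rng, mu_true, phi, size=(30, 24))
        offset = np.log(EFF)
        beta, mu, ll, conv = _nbglm.irls_fit(Y, X, offset, phi)
        assert conv.all()
        for i in range(30):
            ref = sm.GLM(
                Y[i],
                X,
                family=sm.families.NegativeBinomial(alpha=phi),
                offset=offset,
            ).fit()
            np.testing.assert_allclose(beta[i], ref.params, rtol=1e-5, atol=1e-7)
            np.testing.assert_allclose(ll[i], ref.llf, rtol=1e-8)

    def test_nesting_likelihood_monotone(self):
        """Log-likelihood never decreases as the design grows (same φ)."""
        rng = np.random.default_rng(4)
        temps = np.asarray(TEMPS)
        x = temps - temps.mean()
        Y = _nb_counts(rng, 500.0, 0.05, size=(200, 24))
        offset = np.log(EFF)
        lls = []
        for cols in ([np.ones(24)], [np.ones(24), x], [np.ones(24), x, x**2]):
            _, _, ll, _ = _nbglm.irls_fit(Y, np.column_stack(cols), offset, 0.05)
            lls.append(ll)
        assert (lls[1] >= lls[0] - 1e-6).all()
        assert (lls[2] >= lls[1] - 1e-6).all()

    def test_reparameterization_consistency(self, mixed_run):
        """Fitted means from (b0,b1,b2) equal those from the derived
        slope/vertex parameterizations to 1e-9."""
        fits = mixed_run["fits"]
        temps = np.array([13.0, 18.0, 23.0, 29.0])
        fitted = fits[[f"fitted_T{t:g}" for t in temps]].to_numpy()
        lin = fits["model"] == "linear"
        ea, g1, ta = (fits.loc[lin, c].to_numpy() for c in ("Ea", "g1", "Ta"))
        from_derived = 2.0 ** (ea[:, None] + g1[:, None] * (temps[None, :] - ta[:, None]))
        np.testing.assert_allclose(fitted[lin.to_numpy()], from_derived, rtol=1e-9)
        quad = fits["model"] == "quadratic"
        em, g2, tm = (fits.loc[quad, c].to_numpy() for c in ("Em", "g2", "Tm"))
        from_derived = 2.0 ** (em[:, None] + g2[:, None] * (temps[None, :] - tm[:, None]) ** 2)
        np.testing.assert_allclose(fitted[quad.to_numpy()], from_derived, rtol=1e-9)

    def test_power_increases_with_slope(self):
        """Detection rate of plastic genes grows with the simulated |g1|."""
        rates = []
        for g1 in (0.02, 0.05, 0.1):
            cfg = tn.SimulationConfig(
                n_genes=300,
                class_proportions={"increasing-linear": 1.0},
                effect_size_g1=g1,
                seed=5,
            )
            matrix, _ = tn.simulate_counts(cfg)
            L = matrix.samples["library_size_nominal"].to_numpy()
            fits = fit_reaction_norms(matrix.counts, matrix.temperatures, L)
            rates.append((fits["q_linear_vs_null"] <= 0.05).mean())
        assert rates[0] < rates[1] < rates[2]


class TestAdjustFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(adjust_fdr([0.3]), [0.3])

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=50)
        q = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestCallDifferential:
    def _fit(self, q, fold, model="linear"):
        return ReactionNormFit(
            gene_id="g",
            model=model,
            poly_coefficients=(1.0, 0.1, 0.0),
            derived_params={},
            p_linear_vs_null=q,
            p_quad_vs_linear=1.0,
            q_linear_vs_null=q,
            q_quad_vs_linear=1.0,
            fitted_means={13.0: 1.0, 29.0: fold},
            fold_change=fold,
            dispersion=0.05,
        )

    @pytest.mark.parametrize(
        "q,fold,expected",
        [
            (0.01, 1.20, False),  # significant but below the 1.25-fold rule
            (0.20, 3.00, False),  # large fold but not significant
            (0.01, 1.30, True),  # both conditions met
        ],
    )
    def test_both_conditions_required(self, q, fold, expected):
        assert call_differential(self._fit(q, fold)) is expected


def test_estimator_interface(mixed_run):
    model = tn.ReactionNormModel(alpha=0.05).set_params(min_fold=1.3)
    assert model.get_params()["min_fold"] == 1.3
    with pytest.raises(ValueError, match="unknown parameter"):
        model.set_params(bogus=1)
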
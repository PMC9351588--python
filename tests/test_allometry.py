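"""Power-law fitting of niche index against habitat index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import qdnet
from qdnet.io import AbundanceMatrix
from qdnet.studies import grid_search_power_oracle


@pytest.fixture(scope="module")
def habitat():
    rng = np.random.default_rng(42)
    return np.exp(rng.uniform(0, np.log(10), size=50))


class TestFitPower:
    def test_identity_curve_recovers_unit_parameters(self, habitat):
        fit = qdnet.fit_power(habitat, habitat)
        assert fit.alpha == pytest.approx(1.0, abs=1e-10)
        assert fit.beta == pytest.approx(1.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_abundance_degenerates_to_flat_fit(self, habitat):
        fit = qdnet.fit_power(np.full_like(habitat, 5.0), habitat)
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert fit.alpha == pytest.approx(5.0, rel=1e-12)
        assert fit.r2 == 1.0  # zero residual on a flat response

    def test_noisy_recovery_and_grid_search_oracle_agree(self):
        """Noisy beta lands within 0.05 of truth; closed-form OLS matches an
        independent 2-D grid search to 3 decimals."""
        res = grid_search_power_oracle(seed=0)
        assert res["beta_abs_err_vs_truth"] < 0.05
        assert res["beta_fit"] == pytest.approx(res["beta_grid"], abs=1e-3)
        assert res["logalpha_fit"] == pytest.approx(res["logalpha_grid"], abs=1e-3)

    def test_insufficient_positive_abundance_errors(self, habitat):
        y = np.zeros_like(habitat)
        y[:2] = 1.0
        with pytest.raises(ValueError, match="insufficient positive abundance"):
            qdnet.fit_power(y, habitat)

    def test_nls_refinement_never_worse_than_loglog_start(self, habitat):
        rng = np.random.default_rng(1)
        y = 2.0 * habitat ** 0.7 * np.exp(rng.normal(0, 0.3, size=50))
        ll = qdnet.fit_power(y, habitat, method="loglog")
        nls = qdnet.fit_power(y, habitat, method="nls")

        def sse(fit):
            return float(np.sum((y - fit.predict(habitat)) ** 2))

        assert sse(nls) <= sse(ll) + 1e-9
        assert nls.scale == "original"

    @given(st.floats(0.1, 10.0))
    def test_scale_equivariance(self, c):
        """Multiplying abundances by c multiplies alpha by c, leaves beta, r2."""
        rng = np.random.default_rng(3)
        H = np.exp(rng.uniform(0, 2, size=30))
        y = 1.5 * H ** 0.8 * np.exp(rng.normal(0, 0.2, size=30))
        base = qdnet.fit_power(y, H)
        scaled = qdnet.fit_power(c * y, H)
        assert scaled.alpha == pytest.approx(c * base.alpha, rel=1e-9)
        assert scaled.beta == pytest.approx(base.beta, abs=1e-9)
        assert scaled.r2 == pytest.approx(base.r2, abs=1e-9)


class TestPredict:
    def test_unit_power_law_is_identity(self):
        fit = qdnet.PowerFit(alpha=1.0, beta=1.0, r2=1.0, scale="log-log", n_used=10)
        assert np.allclose(qdnet.predict_power(fit, np.array([2.0, 3.0])), [2.0, 3.0])

    def test_zero_exponent_is_constant(self):
        fit = qdnet.PowerFit(alpha=4.0, beta=0.0, r2=1.0, scale="log-log", n_used=10)
        assert np.allclose(qdnet.predict_power(fit, np.array([1.0, 7.0])), 4.0)

    def test_positive_exponent_predictions_strictly_increase(self):
        fit = qdnet.PowerFit(alpha=2.0, beta=0.5, r2=1.0, scale="log-log", n_used=10)
        pred = qdnet.predict_power(fit, np.linspace(1, 9, 20))
        assert np.all(np.diff(pred) > 0)

    def test_non_positive_habitat_rejected(self):
        fit = qdnet.PowerFit(alpha=1.0, beta=1.0, r2=1.0, scale="log-log", n_used=10)
        with pytest.raises(ValueError):
            qdnet.predict_power(fit, np.array([1.0, 0.0]))


class TestFitAll:
    def test_noiseless_matrix_recovered_exactly(self):
        """Against the generative habitat axis, noiseless columns invert
        exactly (row-sum habitat index differs from the drawn axis; the
        truth bundle records both)."""
        cfg = qdnet.GeneratorConfig(n_samples=20, n_taxa=6, seed=5,
                                    sigma_bio=0.0, sigma_log=0.0)
        matrix, truth = qdnet.generate(cfg)
        for j in range(matrix.n_taxa):
            fit = qdnet.fit_power(matrix.values[:, j], truth.H)
            assert fit.beta == pytest.approx(truth.beta[j], abs=1e-6)
            assert np.log(fit.alpha) == pytest.approx(np.log(truth.alpha[j]), abs=1e-6)

    def test_all_equal_columns_give_zero_exponents(self):
        vals = np.tile(np.array([[3.0, 3.0, 3.0]]), (8, 1))
        mat = AbundanceMatrix(vals, [f"s{i}" for i in range(8)], list("abc"))
        # equal columns -> constant habitat index; the flat-H guard applies
        fits = qdnet.fit_all(mat)
        assert all(f.beta == 0.0 for f in fits.values())

    def test_decreasing_taxon_sign_recovered_among_increasing_ones(self):
        """A Firmicutes-like taxon declining with habitat index keeps its
        negative exponent when fitted alongside increasing taxa."""
        rng = np.random.default_rng(9)
        H = np.exp(rng.uniform(0, np.log(8), size=40))
        cols = {
            "down": 5.0 * H ** -0.8,
            "up1": 1.0 * H ** 0.9,
            "up2": 0.5 * H ** 1.2,
        }
        vals = np.column_stack([c * np.exp(rng.normal(0, 0.1, 40))
                                for c in cols.values()])
        mat = AbundanceMatrix(vals, [f"s{i}" for i in range(40)], list(cols))
        fits = qdnet.fit_all(mat)
        assert fits["down"].beta < 0
        assert fits["up1"].beta > 0 and fits["up2"].beta > 0

    def test_failing_taxon_yields_none_not_crash(self, toy_matrix):
        mat = AbundanceMatrix(
            np.column_stack([toy_matrix.values, np.zeros(4)]),
            toy_matrix.sample_ids, toy_matrix.taxon_ids + ["empty"],
        )
        fits = qdnet.fit_all(mat)
        assert fits["empty"] is None
        assert all(fits[t] is not None for t in toy_matrix.taxon_ids)
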
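"""Component decomposition along the habitat axis, and its likelihood."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import qdnet
from qdnet.qdode import CovarianceModel, estimate_covariance, loglik


@pytest.fixture(scope="module")
def fitted(planted_module):
    matrix, truth = planted_module
    fits = qdnet.fit_all(matrix)
    links = qdnet.select_links(matrix, fits, order=2)
    return matrix, truth, qdnet.fit_qdode(matrix, fits, links, order=2)


@pytest.fixture(scope="module")
def planted_module():
    cfg = qdnet.GeneratorConfig(n_samples=60, n_taxa=12, seed=11, n_partners=2,
                                sigma_log=0.01, beta_range=(-0.3, 0.5), h_max=4.0)
    return qdnet.generate(cfg)


class TestFit:
    def test_additivity_exact_at_every_grid_point(self, fitted):
        _, _, qfits = fitted
        for f in qfits.values():
            total = f.independent_traj + f.dependent_total()
            scale = np.maximum(np.abs(f.fitted), 1e-12)
            assert np.max(np.abs(f.fitted - total) / scale) < 1e-9

    def test_boundary_convention(self, fitted):
        """At the smallest habitat index the observed abundance is entirely
        independent; every dependent trajectory starts at zero."""
        _, _, qfits = fitted
        for f in qfits.values():
            assert f.independent_traj[0] == pytest.approx(f.observed[0])
            for traj in f.dependent_traj.values():
                assert traj[0] == 0.0

    def test_isolated_taxon_reproduces_noiseless_curve(self):
        cfg = qdnet.GeneratorConfig(n_samples=30, n_taxa=5, seed=2,
                                    sigma_bio=0.0, sigma_log=0.0)
        matrix, _ = qdnet.generate(cfg)
        qfits = qdnet.fit_qdode(matrix, links=None, order=3)
        for f in qfits.values():
            assert not f.dependent_traj
            resid = f.observed - f.independent_traj
            tss = np.sum((f.observed - f.observed.mean()) ** 2)
            assert 1.0 - float(resid @ resid) / tss >= 0.99

    @pytest.mark.parametrize("engine", ["pointwise", "integral"])
    def test_engines_share_the_component_contract(self, planted_module, engine):
        matrix, _ = planted_module
        links = {matrix.taxon_ids[0]: [matrix.taxon_ids[1]]}
        qfits = qdnet.fit_qdode(matrix, links=links, order=2, engine=engine)
        f = qfits[matrix.taxon_ids[0]]
        assert set(f.dependent_traj) == {matrix.taxon_ids[1]}
        total = f.independent_traj + f.dependent_total()
        assert np.allclose(f.fitted, total, rtol=1e-9)

    def test_integral_engine_trajectories_stable_under_step_halving(self, planted_module):
        matrix, _ = planted_module
        links = {matrix.taxon_ids[0]: [matrix.taxon_ids[1]]}
        coarse = qdnet.fit_qdode(matrix, links=links, order=2, engine="integral",
                                 resolution=400)[matrix.taxon_ids[0]]
        fine = qdnet.fit_qdode(matrix, links=links, order=2, engine="integral",
                               resolution=800)[matrix.taxon_ids[0]]
        scale = np.maximum(np.abs(fine.fitted), 1e-9)
        assert np.max(np.abs(coarse.fitted - fine.fitted) / scale) < 1e-6

    def test_sign_of_planted_links_recovered_on_selected_support(self):
        """On a planted community, edges the pipeline recovers carry the
        planted promotion/inhibition sign in >= 90% of cases."""
        from qdnet.studies import link_recovery
        result = link_recovery(seed=11, n_replicates=2)
        assert result["n_recovered_edges"] > 0
        assert result["sign_accuracy"] >= 0.9


class TestDecompose:
    def test_no_partner_taxon_has_zero_dependent_totals(self, fitted):
        matrix, _, qfits = fitted
        isolated = qdnet.fit_qdode(matrix, links=None, order=2)
        table = qdnet.decompose(next(iter(isolated.values())))
        assert np.all(table["dependent_pos"] == 0.0)
        assert np.all(table["dependent_neg"] == 0.0)

    def test_everywhere_positive_partner_fills_only_positive_total(self, fitted):
        matrix, _, qfits = fitted
        f = next(iter(qfits.values()))
        if not f.dependent_level:
            pytest.skip("no selected partner in this draw")
        pid = f.partners[0]
        forced = f.dependent_level[pid].copy()
        f.dependent_level[pid] = np.abs(forced) + 1e-6
        try:
            table = qdnet.decompose(f)
            others = sum((np.clip(f.dependent_level[p], None, 0)
                          for p in f.partners if p != pid), np.zeros_like(forced))
            assert np.allclose(table["dependent_neg"], others)
            assert np.all(table["dependent_pos"] > 0)
        finally:
            f.dependent_level[pid] = forced

    def test_sample_subset_restricts_rows(self, fitted):
        _, _, qfits = fitted
        f = next(iter(qfits.values()))
        table = qdnet.decompose(f, sample_subset=f.sample_ids[:5])
        assert len(table) == 5

    def test_decompose_additivity_with_zero_anchored_attribution(self, fitted):
        _, _, qfits = fitted
        for f in qfits.values():
            table = qdnet.decompose(f)
            total = table["independent"] + table["dependent_pos"] + table["dependent_neg"]
            assert np.allclose(total, f.fitted, rtol=1e-9)


class TestLoglik:
    def _toy_fits(self, resid_matrix, grid=None):
        """Wrap an n x m residual matrix into minimal QdODEFit objects."""
        n, m = resid_matrix.shape
        grid = grid if grid is not None else np.linspace(1, 2, n)
        out = {}
        for j in range(m):
            obs = 10.0 + resid_matrix[:, j]
            out[f"t{j}"] = qdnet.QdODEFit(
                focal=f"t{j}", theta_self=np.zeros(1), theta_partner={},
                grid=grid, sample_ids=[f"s{i}" for i in range(n)],
                observed=obs, independent_traj=np.full(n, 10.0),
                dependent_traj={}, dependent_level={},
                fitted=np.full(n, 10.0), sigma2=1.0, rss=float(resid_matrix[:, j] @ resid_matrix[:, j]),
            )
        return out

    def test_zero_residuals_with_unit_variance_closed_form(self):
        n, m = 6, 3
        fits = self._toy_fits(np.zeros((n, m)))
        cov = CovarianceModel(taxa=[f"t{j}" for j in range(m)], cov=np.eye(m))
        value = loglik(fits, cov)
        assert value == pytest.approx(-(n * m / 2) * np.log(2 * np.pi))

    def test_independent_errors_reduce_to_sum_of_univariate_logliks(self):
        rng = np.random.default_rng(0)
        R = rng.normal(0, 1.0, size=(8, 3))
        fits = self._toy_fits(R)
        sig = np.array([0.5, 1.0, 2.0])
        cov = CovarianceModel(taxa=list(fits), cov=np.diag(sig))
        total = loglik(fits, cov)
        per_taxon = sum(
            -0.5 * 8 * np.log(2 * np.pi * s) - 0.5 * float(R[:, j] @ R[:, j]) / s
            for j, s in enumerate(sig)
        )
        assert total == pytest.approx(per_taxon, rel=1e-12)

    def test_agrees_with_dense_multivariate_normal(self):
        """m=3, n=4 residuals against scipy's dense MVN with the kron
        covariance — the block-structure shortcut must match to 1e-8."""
        rng = np.random.default_rng(1)
        n, m = 4, 3
        R = rng.normal(0, 1.0, size=(n, m))
        fits = self._toy_fits(R)
        A = rng.normal(size=(m, m))
        C = A @ A.T + np.eye(m)
        cov = CovarianceModel(taxa=list(fits), cov=C)
        fast = loglik(fits, cov)
        dense = multivariate_normal(mean=np.zeros(n * m),
                                    cov=np.kron(C, np.eye(n)))
        # stack residuals taxon-major to match the kron(C, I_n) layout
        x = np.concatenate([R[:, j] for j in range(m)])
        assert fast == pytest.approx(dense.logpdf(x), abs=1e-8)

    def test_non_positive_definite_covariance_shrunk_not_fatal(self):
        R = np.random.default_rng(2).normal(size=(5, 2))
        fits = self._toy_fits(R)
        bad = np.array([[1.0, 1.5], [1.5, 1.0]])  # not PD
        value = loglik(fits, CovarianceModel(taxa=list(fits), cov=bad))
        assert np.isfinite(value)

    def test_estimate_covariance_matches_residuals(self):
        rng = np.random.default_rng(3)
        R = rng.normal(size=(10, 3))
        fits = self._toy_fits(R)
        cov = estimate_covariance(fits)
        assert np.allclose(cov.cov, R.T @ R / 10, atol=1e-9)
        assert np.all(cov.sigma2 > 0)
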
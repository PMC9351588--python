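"""Group LASSO / adaptive group LASSO partner selection."""

import numpy as np
import pytest

import qdnet
from qdnet.selection import (
    adaptive_group_lasso,
    build_design,
    group_lasso,
    lambda_grid_for,
    weight_function,
    _prepare,
    _solve_path,
)


@pytest.fixture(scope="module")
def design():
    cfg = qdnet.GeneratorConfig(n_samples=40, n_taxa=8, seed=11, n_partners=2,
                                sigma_log=0.02)
    matrix, _ = qdnet.generate(cfg)
    fits = qdnet.fit_all(matrix)
    return build_design(matrix, fits, matrix.taxon_ids[0], order=2)


class TestWeights:
    @pytest.mark.parametrize("kind", ["plateau", "parabolic"])
    def test_boundary_samples_get_zero_weight(self, kind):
        H = np.linspace(1, 10, 15)
        z = weight_function(H, kind)
        assert z[0] == 0.0 and z[-1] == 0.0
        assert np.all(z[1:-1] > 0) and z.max() == 1.0

    def test_adaptive_downweights_abundant_samples(self):
        H = np.linspace(1, 10, 15)
        curve = 2.0 * H
        z = weight_function(H, "adaptive", curve=curve)
        assert z[0] == 0.0 and z[-1] == 0.0
        inner = z[1:-1] * curve[1:-1] ** 2
        plateau = weight_function(H, "plateau")[1:-1]
        assert np.allclose(inner / inner.max(), plateau / plateau.max())


class TestDesign:
    def test_partner_values_map_to_unit_interval_endpoints(self, design):
        # the first Legendre column of an unscaled block is u - u0, so the
        # range of each scaled block's first column spans the mapped interval
        for pid, block in design.blocks.items():
            col = block[:, 0] * design.block_scales[pid]
            assert col.max() - col.min() == pytest.approx(2.0, rel=1e-9)

    def test_samples_sorted_by_habitat_index(self, design):
        assert np.all(np.diff(design.H) >= 0)

    def test_constant_partner_flagged_and_reduced(self):
        vals = np.column_stack([
            np.linspace(1, 5, 12) ** 1.2,
            np.full(12, 3.0),
            np.linspace(1, 5, 12) ** 0.5,
        ])
        mat = qdnet.AbundanceMatrix(vals, [f"s{i}" for i in range(12)], list("abc"))
        fits = qdnet.fit_all(mat)
        d = build_design(mat, fits, "a", order=2)
        assert "b" in d.flagged
        assert d.blocks["b"].shape[1] == 1

    def test_order_zero_rejected(self, design):
        cfg = qdnet.GeneratorConfig(n_samples=20, n_taxa=4, seed=0)
        matrix, _ = qdnet.generate(cfg)
        with pytest.raises(ValueError, match="order"):
            build_design(matrix, qdnet.fit_all(matrix), matrix.taxon_ids[0], order=0)


class TestGroupLasso:
    def test_lambda_above_critical_shrinks_everything(self, design):
        res = group_lasso(design, lambda_grid=np.array([1e9]), polish=False)
        assert res.selected == []

    def test_planted_single_signal_recovered(self):
        """Focal driven by exactly one strong partner among pure-noise decoys."""
        from qdnet.synth import PlantedLink
        cfg = qdnet.GeneratorConfig(n_samples=50, n_taxa=7, seed=3,
                                    links=[PlantedLink(0, 1, 1.2)], sigma_log=0.01)
        matrix, _ = qdnet.generate(cfg)
        fits = qdnet.fit_all(matrix)
        d = build_design(matrix, fits, matrix.taxon_ids[0], order=2)
        final = adaptive_group_lasso(d, group_lasso(d))
        assert matrix.taxon_ids[1] in final.selected

    def test_sparsity_monotone_along_grid_on_fixed_data(self, design):
        include = list(design.blocks)
        yp, Xp, slices = _prepare(design, include)
        gw = np.ones(len(include))
        grid = lambda_grid_for(yp, Xp, slices, gw)
        sols, _ = _solve_path(yp, Xp, slices, grid, gw)
        counts = [sum(np.linalg.norm(b[sl]) > 0 for sl in slices) for b in sols]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_solution_objective_not_worse_than_zero_vector(self, design):
        include = list(design.blocks)
        yp, Xp, slices = _prepare(design, include)
        gw = np.ones(len(include))
        grid = lambda_grid_for(yp, Xp, slices, gw)
        sols, _ = _solve_path(yp, Xp, slices, grid, gw)
        for lam, b in zip(grid, sols):
            pen = lam * sum(np.linalg.norm(b[sl]) for sl in slices)
            obj = float(np.sum((yp - Xp @ b) ** 2)) + pen
            assert obj <= float(yp @ yp) + 1e-9

    def test_needs_at_least_two_partner_blocks(self):
        vals = np.column_stack([np.linspace(1, 5, 10), np.linspace(2, 3, 10)])
        mat = qdnet.AbundanceMatrix(vals, [f"s{i}" for i in range(10)], ["a", "b"])
        d = build_design(mat, qdnet.fit_all(mat), "a", order=1)
        with pytest.raises(ValueError, match="2 partner blocks"):
            group_lasso(d)


class TestAdaptive:
    def test_empty_stage1_short_circuits(self, design):
        empty = group_lasso(design, lambda_grid=np.array([1e9]), polish=False)
        final = adaptive_group_lasso(design, empty)
        assert final.selected == [] and final.bic_path == []

    def test_dominant_partner_gets_smaller_weight(self):
        from qdnet.synth import PlantedLink
        cfg = qdnet.GeneratorConfig(n_samples=50, n_taxa=6, seed=4,
                                    links=[PlantedLink(0, 1, 1.2),
                                           PlantedLink(0, 2, 0.4)],
                                    sigma_log=0.01)
        matrix, _ = qdnet.generate(cfg)
        fits = qdnet.fit_all(matrix)
        d = build_design(matrix, fits, matrix.taxon_ids[0], order=2)
        stage1 = group_lasso(d)
        final = adaptive_group_lasso(d, stage1)
        strong, weak = matrix.taxon_ids[1], matrix.taxon_ids[2]
        if strong in final.weights and weak in final.weights:
            assert final.weights[strong] < final.weights[weak]
        else:  # at minimum the strong partner must survive
            assert strong in final.selected


def test_select_links_respects_max_links_cap(planted):
    matrix, _ = planted
    links = qdnet.select_links(matrix, order=2, max_links=1)
    assert all(len(res.selected) <= 1 for res in links.values())
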
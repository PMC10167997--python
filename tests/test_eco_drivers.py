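import numpy as np
import pandas as pd
import pytest

from httflow.core_io import demo_tree
from httflow.eco_drivers import (
    SuitabilityGrid,
    czechanowski,
    driver_table,
    fit_driver_model,
    niche_breadth,
    phylo_distance,
    range_overlap,
    richness_correlations,
    schoener_d,
)
from httflow.potential_effects import AlphaMatrix, muller_index
from httflow.synthetic_data import make_ecology, simulate_driver_dataset


def _grid(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, bool) if mask is None else mask
    return SuitabilityGrid(values=values, mask=mask)


class TestSchoenerD:
    def test_identical_grids(self):
        g = _grid([[1.0, 2.0], [3.0, 4.0]])
        assert schoener_d(g, g) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        g1 = _grid([[1.0, 0.0]])
        g2 = _grid([[0.0, 1.0]])
        assert schoener_d(g1, g2) == pytest.approx(0.0)

    def test_hand_computed_half_overlap(self):
        g1 = _grid([[0.5, 0.5, 0.0]])
        g2 = _grid([[0.0, 0.5, 0.5]])
        assert schoener_d(g1, g2) == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            schoener_d(_grid([[1.0]]), _grid([[1.0, 2.0]]))

    def test_same_functional_form_as_czechanowski(self):
        rng = np.random.default_rng(4)
        v1 = rng.uniform(0, 1, 12)
        v2 = rng.uniform(0, 1, 12)
        g1, g2 = _grid(v1.reshape(3, 4)), _grid(v2.reshape(3, 4))
        assert schoener_d(g1, g2) == pytest.approx(czechanowski(v1, v2))


class TestCzechanowski:
    def test_identical_use(self):
        assert czechanowski([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_disjoint_resources(self):
        assert czechanowski([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert czechanowski([0.75, 0.25], [0.25, 0.75]) == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            czechanowski([0, 0], [1, 2])


class TestRangeOverlap:
    def test_identical_point_sets(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        assert range_overlap(pts, pts) == (pytest.approx(100.0), pytest.approx(100.0))

    def test_nested_rectangles_analytic(self):
        # H_j strictly inside H_i with half its area (planar coordinates)
        outer = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], dtype=float)
        inner = np.array([[1, 0.5], [3, 0.5], [3, 1.5], [1, 1.5]], dtype=float)
        pct_i, pct_j = range_overlap(outer, inner, project=False)
        assert pct_i == pytest.approx(25.0)
        assert pct_j == pytest.approx(100.0)

    def test_disjoint_hulls(self):
        a = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        b = a + 10.0
        assert range_overlap(a, b) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0], [1, 1], [2, 2]], dtype=float)
        square = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        with pytest.raises(ValueError, match="i"):
            range_overlap(line, square, project=False)


class TestBreadthAndPhylo:
    def test_breadth_fractions(self):
        net = pd.DataFrame(
            [[1.0] * 12, [1.0, 1.0, 1.0] + [0.0] * 9],
            index=["gen", "spec"], columns=[f"f{i}" for i in range(12)],
        )
        assert niche_breadth(net, "gen") == pytest.approx(1.0)
        assert niche_breadth(net, "spec") == pytest.approx(0.25)
        with pytest.raises(KeyError):
            niche_breadth(net, "missing")

    def test_breadth_monotone_in_flower_use(self):
        base = pd.DataFrame(
            [[1.0, 0, 0, 0]], index=["s"], columns=list("abcd")
        )
        wider = base.copy()
        wider.loc["s", "b"] = 2.0
        assert niche_breadth(wider, "s") > niche_breadth(base, "s")

    def test_patristic_distances_on_demo_tree(self):
        tree = demo_tree()
        assert phylo_distance(tree, "BM", "BM") == 0.0
        assert phylo_distance(tree, "BM", "BD") == pytest.approx(5.3)
        assert phylo_distance(tree, "IC", "LT") == pytest.approx(70.0)

    def test_ultrametric_inequality_all_triples(self):
        tree = demo_tree()
        taxa = tree.taxa
        for a in taxa:
            for b in taxa:
                for c in taxa:
                    dab = phylo_distance(tree, a, b)
                    dac = phylo_distance(tree, a, c)
                    dbc = phylo_distance(tree, b, c)
                    assert dab <= max(dac, dbc) + 1e-9


class TestDriverModel:
    def test_logit_of_equal_sharing_is_zero(self):
        import math

        # two species sharing everything equally: d_ab = 0.5 -> logit 0
        alpha = AlphaMatrix(
            table=pd.DataFrame(
                [[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["t1", "t2"]
            ),
            resolution="family",
        )
        d = muller_index(alpha).table.loc["a", "b"]
        assert math.log(d / (1 - d)) == pytest.approx(0.0, abs=1e-9)

    def test_known_abiotic_effect_recovered_in_majority_of_runs(self):
        retained = 0
        for rep in range(10):
            data = simulate_driver_dataset(seed=500 + rep, beta_abiotic=0.5)
            result = fit_driver_model(data)
            in_set = any(
                "abiotic" in m.split("+") for m in result.best_models
            )
            coef = result.coefficients.set_index("term")
            positive = (
                coef.loc["abiotic", "beta"] > 0
                if "abiotic" in coef.index
                else True
            )
            retained += in_set and positive
        assert retained >= 6

    def test_ranking_contains_all_subsets_including_null(self):
        data = simulate_driver_dataset(seed=7, beta_abiotic=0.0)
        result = fit_driver_model(data)
        assert len(result.ranking) == 32  # all 2^5 subsets, empty = null
        assert "null" in set(result.ranking.model)
        assert (result.ranking.delta_aicc >= 0).all()
        assert result.best_models  # non-empty by construction

    def test_custom_fitter_matches_statsmodels(self):
        import warnings

        import statsmodels.api as sm

        from httflow._lmm import fit_lmm_crossed

        data = simulate_driver_dataset(seed=3, beta_abiotic=0.5)
        y = data.logit_dij.to_numpy()
        x = np.column_stack([np.ones(len(data)), data.abiotic.to_numpy()])
        ours = fit_lmm_crossed(
            y, x, data.acting.to_numpy(), data.target.to_numpy(), reml=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM.from_formula(
                "logit_dij ~ abiotic", groups="groups",
                vc_formula={
                    "acting": "0 + C(acting)", "target": "0 + C(target)"
                },
                data=data.assign(groups=1),
            ).fit(reml=False)
        # our optimizer must find at least as good a likelihood, with
        # coefficients agreeing to ~1%
        assert ours.llf >= res.llf - 1e-6
        assert ours.params == pytest.approx(res.fe_params.values, rel=0.02)


class TestCorrelations:
    def test_monotone_and_antimonotone_spearman(self):
        up = np.array([1, 2, 3, 4, 5], dtype=float)
        down = up[::-1].copy()
        out = richness_correlations(up, up, up, down)
        ab = out.set_index(["response", "predictor"])
        assert ab.loc[("abundance", "breadth"), "estimate"] == pytest.approx(1.0)
        assert ab.loc[("abundance", "area"), "estimate"] == pytest.approx(-1.0)

    def test_hand_constructed_pearson(self):
        # y = 0.9-correlated with x by construction
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        r_target = 0.9
        noise = np.array([1.0, -2.0, 0.0, 2.0, -1.0])  # orthogonal to x
        y = r_target * x / np.std(x) + np.sqrt(1 - r_target**2) * noise / np.std(noise)
        out = richness_correlations(x, x, y, y)
        r = out.set_index(["response", "predictor"]).loc[
            ("richness", "breadth"), "estimate"
        ]
        assert r == pytest.approx(0.9, abs=1e-9)

    def test_exact_permutation_p_at_small_n(self):
        # perfectly monotone n=5: exact two-sided permutation p = 2/120
        up = np.array([1, 2, 3, 4, 5], dtype=float)
        out = richness_correlations(up, up, up, up)
        p = out.set_index(["response", "predictor"]).loc[
            ("abundance", "breadth"), "p"
        ]
        assert p == pytest.approx(2 / 120)

    def test_constant_vector_rejected(self):
        v = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            richness_correlations(v, v, v, np.ones(3))
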
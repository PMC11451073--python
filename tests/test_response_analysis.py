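import numpy as np
import pandas as pd
import pytest

from _oracles import (
    anova_type2_ss,
    mannwhitney_two_sided_enumeration,
    mannwhitney_u_stat,
)
from vocalearn.response_analysis import (
    StageLabeledFeatures,
    compare_pre_post,
    mann_whitney_u,
    pca_project,
    two_way_anova_ss,
)


def _stage_table(cells: dict[tuple[int, str], dict[str, np.ndarray]], parameters):
    rows = []
    for (vtype, stage), params in cells.items():
        n = len(next(iter(params.values())))
        for i in range(n):
            rows.append({"type": vtype, "stage": stage, **{p: params[p][i] for p in parameters}})
    return StageLabeledFeatures(pd.DataFrame(rows), parameters=list(parameters))


class TestMannWhitney:
    def test_identical_samples_central_u(self):
        x = np.arange(8.0)
        u, p = mann_whitney_u(x, x)
        assert u == 8 * 8 / 2
        assert p > 0.9

    def test_fully_separated_tiny_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # one-sided exact 1/C(6,3) = 0.05; two-sided doubles it
        assert p == pytest.approx(0.1, rel=1e-9)

    def test_u_identity(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(0.5, 1, size=9)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == 12 * 9

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(20.0))[:6]
        y = rng.permutation(np.arange(100.0, 120.0))[:5] - rng.uniform(0, 30)
        u, p = mann_whitney_u(x, y, method="exact")
        assert u == mannwhitney_u_stat(x, y)
        assert p == pytest.approx(mannwhitney_two_sided_enumeration(x, y), rel=1e-9)

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestTwoWayAnova:
    def test_no_effects_zero_ss(self, rng):
        noise = lambda: rng.standard_normal(10)
        base = noise()
        cells = {
            (1, "pre"): {"duration": base},
            (1, "post"): {"duration": base},
            (2, "pre"): {"duration": base},
            (2, "post"): {"duration": base},
        }
        data = _stage_table(cells, ["duration"])
        ss = two_way_anova_ss(data, "duration")
        assert ss.loc["type", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert ss.loc["stage", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_type_effect_hand_value(self):
        n = 6  # cell means 0,0,1,1 varying only with type, no noise
        cells = {
            (1, "pre"): {"duration": np.zeros(n)},
            (1, "post"): {"duration": np.zeros(n)},
            (2, "pre"): {"duration": np.ones(n)},
            (2, "post"): {"duration": np.ones(n)},
        }
        data = _stage_table(cells, ["duration"])
        ss = two_way_anova_ss(data, "duration")
        assert ss.loc["stage", "sum_sq"] == pytest.approx(0.0, abs=1e-9)
        assert ss.loc["type", "sum_sq"] == pytest.approx(n * 0.25 * 4, rel=1e-9)

    def test_balanced_decomposition_sums_to_total(self, rng):
        n = 8
        cells = {
            (t, s): {"cog": rng.normal(10 * t + 3 * (s == "post"), 1, n)}
            for t in (1, 2)
            for s in ("pre", "post")
        }
        data = _stage_table(cells, ["cog"])
        ss = two_way_anova_ss(data, "cog")
        total = np.var(data.table["cog"].to_numpy(), ddof=0) * len(data.table)
        assert ss["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_unbalanced_matches_nested_model_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = {(1, "pre"): 5, (1, "post"): 9, (2, "pre"): 7, (2, "post"): 4}
        cells = {
            key: {"cog": rng.normal(2 * key[0] + (key[1] == "post"), 1, n)}
            for key, n in sizes.items()
        }
        data = _stage_table(cells, ["cog"])
        ss = two_way_anova_ss(data, "cog")
        oracle = anova_type2_ss(
            data.table["type"].to_numpy(),
            data.table["stage"].to_numpy(),
            data.table["cog"].to_numpy(),
        )
        for row in ["type", "stage", "type:stage", "residual"]:
            assert ss.loc[row, "sum_sq"] == pytest.approx(oracle[row], rel=1e-8), row

    def test_empty_cell_rejected(self):
        df = pd.DataFrame(
            {"type": [1, 1, 2], "stage": ["pre", "post", "pre"], "duration": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="empty cell"):
            StageLabeledFeatures(df, parameters=["duration"])

    def test_zero_variance_rejected(self):
        cells = {
            (t, s): {"duration": np.ones(3)} for t in (1, 2) for s in ("pre", "post")
        }
        data = _stage_table(cells, ["duration"])
        with pytest.raises(ValueError, match="variance"):
            two_way_anova_ss(data, "duration")


class TestPCA:
    def test_rank_one_data(self, rng):
        t = rng.standard_normal(50)
        X = np.outer(t, [1.0, -2.0, 0.5, 3.0, 1.5])
        X += rng.standard_normal(X.shape) * 1e-12
        _, _, evr = pca_project(X)
        assert evr[0] == pytest.approx(1.0, abs=1e-6)

    def test_orthonormal_loadings_and_score_geometry(self, rng):
        X = rng.standard_normal((80, 5)) @ rng.standard_normal((5, 5))
        loadings, scores, _ = pca_project(X, n_components=2)
        L = loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(2), atol=1e-10)
        assert np.allclose(scores.mean(axis=0), 0, atol=1e-10)
        cov = np.cov(scores.T)
        assert abs(cov[0, 1]) < 1e-8

    def test_correlated_gaussian_eigenvalues(self, rng):
        # correlation rho -> eigenvalues (1 +/- rho)/2 of the 2x2 correlation matrix
        rho = 0.8
        cov = [[1, rho], [rho, 1]]
        X = rng.multivariate_normal([0, 0], cov, size=20000)
        _, _, evr = pca_project(X)
        assert evr[0] == pytest.approx(0.9, abs=0.02)
        assert evr[1] == pytest.approx(0.1, abs=0.02)

    def test_constant_column_dropped(self, rng):
        X = pd.DataFrame(
            {"a": rng.standard_normal(30), "b": np.ones(30), "c": rng.standard_normal(30)}
        )
        loadings, _, _ = pca_project(X)
        assert list(loadings.index) == ["a", "c"]


class TestComparePrePost:
    def test_planted_duration_shift_recovered(self, rng):
        n = 40
        shift = 0.25
        pre1 = rng.lognormal(np.log(0.5), 0.2, n)
        pre2 = rng.lognormal(np.log(0.6), 0.2, n)
        cells = {
            (1, "pre"): {"duration": pre1, "cog": rng.normal(1500, 100, n)},
            (1, "post"): {"duration": pre1 - shift, "cog": rng.normal(1500, 100, n)},
            (2, "pre"): {"duration": pre2, "cog": rng.normal(800, 100, n)},
            (2, "post"): {"duration": pre2 - shift, "cog": rng.normal(800, 100, n)},
        }
        report = compare_pre_post(_stage_table(cells, ["duration", "cog"]))
        for vtype in (1, 2):
            entry = report["per_type"][vtype]["duration"]
            assert entry["median_shift"] == pytest.approx(-shift, abs=1e-9)
            assert entry["p"] < 0.001
        # planted effects: stage drives duration, type drives spectrum
        anova = report["anova"]
        assert anova["duration"]["stage"]["sum_sq"] > anova["duration"]["type"]["sum_sq"]
        assert anova["cog"]["type"]["sum_sq"] > anova["cog"]["stage"]["sum_sq"]

    def test_identical_stages_null_report(self, rng):
        n = 25
        d1 = rng.normal(0.5, 0.05, n)
        d2 = rng.normal(0.9, 0.05, n)
        c1 = rng.normal(1500, 100, n)
        c2 = rng.normal(800, 100, n)
        cells = {
            (1, "pre"): {"duration": d1, "cog": c1},
            (1, "post"): {"duration": d1, "cog": c1},
            (2, "pre"): {"duration": d2, "cog": c2},
            (2, "post"): {"duration": d2, "cog": c2},
        }
        report = compare_pre_post(_stage_table(cells, ["duration", "cog"]))
        for vtype in (1, 2):
            for param in ("duration", "cog"):
                assert report["per_type"][vtype][param]["p"] > 0.9
        assert report["anova"]["duration"]["stage"]["sum_sq"] == pytest.approx(0.0, abs=1e-9)
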
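from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from alienphylo.stats import (
    aggregate_climate,
    aicc,
    climate_regressions,
    community_type_correlations,
    glm_fit,
    holm_adjust,
    posthoc_pairwise,
    select_data_mode,
    spearman,
    two_way_anova,
)


def brute_force_holm(pvals):
    """Step-down definition: sort ascending, p~_(i) = max_{j<=i}
    min(1, (m-j+1) p_(j)), mapped back to input order."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj_sorted[rank] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestGlmFit:
    def _table(self, n=10):
        x = np.arange(n, dtype=float)
        return pd.DataFrame({"x": x, "y": 2 * x + 1})

    def test_exact_linear_fit(self):
        fit = glm_fit(self._table(), "y", ["x"])
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.params["Intercept"] == pytest.approx(1.0)
        assert fit.result.ssr == pytest.approx(0.0, abs=1e-18)

    def test_aicc_formula(self):
        assert aicc(10.0, n=10, k=2) == pytest.approx(10 + 12 / 7)
        assert np.isnan(aicc(10.0, n=3, k=2))

    def test_row_permutation_invariance(self):
        t = self._table(12)
        t["y"] += np.sin(t["x"])  # non-trivial residuals
        f1 = glm_fit(t, "y", ["x"])
        f2 = glm_fit(t.sample(frac=1, random_state=3), "y", ["x"])
        assert f1.params["x"] == pytest.approx(f2.params["x"])
        assert f1.aicc == pytest.approx(f2.aicc)

    def test_rank_deficient_design_rejected(self):
        t = self._table()
        t["x2"] = 2 * t["x"]
        with pytest.raises(ValueError, match="rank"):
            glm_fit(t, "y", ["x", "x2"])

    def test_k_counts_variance_parameter(self):
        fit = glm_fit(self._table() + np.random.default_rng(0).normal(
            0, 1, size=(10, 2)), "y", ["x"])
        assert fit.k == 3  # intercept + slope + residual variance


class TestModeSelection:
    def _metrics_table(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for ctype in ("Inv", "Nat", "Int"):
            for scale in ("eco", "hab"):
                for u in range(8):
                    rows.append(
                        {
                            "scale": scale, "unit": f"{scale}{u}",
                            "community_type": ctype,
                            "NRI": rng.normal(shift, 1),
                            "NTI": rng.normal(shift, 1),
                        }
                    )
        return pd.DataFrame(rows)

    def test_tie_selects_abundance(self):
        t = self._metrics_table()
        out = select_data_mode({"presence": t, "abundance": t.copy()})
        assert out["selected"] == "abundance" and out["tie"]

    def test_lower_aicc_wins(self):
        base = self._metrics_table(seed=1)
        noisy = base.copy()
        noisy["NRI"] = noisy["NRI"] * 10  # inflated variance -> higher AICc
        noisy["NTI"] = noisy["NTI"] * 10
        out = select_data_mode({"presence": noisy, "abundance": base})
        assert out["selected"] == "abundance"
        out2 = select_data_mode({"presence": base, "abundance": noisy})
        assert out2["selected"] == "presence"

    def test_delta_aicc_reported(self):
        out = select_data_mode(
            {"presence": self._metrics_table(seed=2),
             "abundance": self._metrics_table(seed=3)}
        )
        assert out["delta_aicc"] == pytest.approx(
            abs(out["aicc"]["presence"] - out["aicc"]["abundance"])
        )


class TestTwoWayAnova:
    def _balanced_toy(self):
        # textbook 2x2 with cells {1,2},{3,4},{5,6},{7,8}
        rows = []
        for a, b, vals in (
            ("a1", "b1", (1, 2)), ("a1", "b2", (3, 4)),
            ("a2", "b1", (5, 6)), ("a2", "b2", (7, 8)),
        ):
            rows += [{"A": a, "B": b, "y": v} for v in vals]
        return pd.DataFrame(rows)

    def test_balanced_textbook_f_values(self):
        out = two_way_anova(self._balanced_toy(), "y", "A", "B")
        f = dict(zip(out["term"], out["F"]))
        assert f["A"] == pytest.approx(64.0, abs=1e-9)
        assert f["B"] == pytest.approx(16.0, abs=1e-9)
        assert f["A:B"] == pytest.approx(0.0, abs=1e-9)
        assert (out["df1"] == [1, 1, 1]).all() and (out["df2"] == 4).all()

    def test_type2_equals_type1_when_balanced(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        data = self._balanced_toy()
        model = smf.ols("y ~ C(A) * C(B)", data=data).fit()
        t1 = sm.stats.anova_lm(model, typ=1)
        out = two_way_anova(data, "y", "A", "B")
        np.testing.assert_allclose(
            out["sum_sq"], t1["sum_sq"].iloc[:3], atol=1e-9
        )

    def test_constant_response_flagged(self):
        data = self._balanced_toy()
        data["y"] = 7.0
        out = two_way_anova(data, "y", "A", "B")
        assert out.attrs["degenerate"]
        assert (out["F"] == 0).all()

    def test_empty_cell_rejected(self):
        data = self._balanced_toy()
        data = data[~((data["A"] == "a1") & (data["B"] == "b2"))]
        with pytest.raises(ValueError, match="cell"):
            two_way_anova(data, "y", "A", "B")

    def test_single_level_factor_rejected(self):
        data = self._balanced_toy()
        with pytest.raises(ValueError, match="levels"):
            two_way_anova(data[data["A"] == "a1"], "y", "A", "B")


class TestHolm:
    def test_hand_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.03, 0.04]), [0.03, 0.06, 0.06]
        )

    def test_single_comparison_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_on_all_orderings(self):
        base = np.array([0.001, 0.011, 0.02, 0.04, 0.3, 0.9])
        for m in range(2, 7):
            for perm in permutations(base[:m]):
                np.testing.assert_allclose(
                    holm_adjust(list(perm)), brute_force_holm(perm)
                )

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = rng.uniform(0, 1, size=rng.integers(1, 9))
            np.testing.assert_allclose(holm_adjust(p), brute_force_holm(p))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(31)
        for _ in range(10):
            p = rng.uniform(0, 1, size=6)
            np.testing.assert_allclose(
                holm_adjust(p), multipletests(p, method="holm")[1]
            )


class TestPosthoc:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "g": np.repeat(["x", "y", "z"], 12),
                "v": np.concatenate(
                    [rng.normal(0, 1, 12), rng.normal(2, 1, 12),
                     rng.normal(0.2, 1, 12)]
                ),
            }
        )

    def test_all_pairs_present_with_holm(self):
        out = posthoc_pairwise(self._table(), "v", "g")
        assert len(out) == 3
        assert (out["p_adj"] >= out["p_raw"] - 1e-15).all()
        assert (out["p_adj"] <= 1).all()

    def test_adjusted_monotone_in_raw_order(self):
        out = posthoc_pairwise(self._table(3), "v", "g").sort_values("p_raw")
        assert out["p_adj"].is_monotonic_increasing

    def test_small_group_rejected(self):
        t = pd.DataFrame({"g": ["x", "y", "y"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="< 2 observations"):
            posthoc_pairwise(t, "v", "g")


class TestSpearman:
    def test_monotone_antitone(self):
        assert spearman([1, 2, 3], [10, 20, 300]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [300, 20, 10]).rho == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]).rho == pytest.approx(0.8)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = spearman(x, y).rho
        r2 = spearman(np.exp(x), y ** 3).rho
        assert r1 == pytest.approx(r2)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


class TestClimate:
    UNITS = {"s": [("u1", box(0, 0, 1, 1)), ("u2", box(1, 0, 2, 1)),
                   ("u3", box(5, 5, 6, 6))]}

    def _grid(self):
        return pd.DataFrame(
            {
                "lon": [0.25, 0.75, 1.5],
                "lat": [0.5, 0.5, 0.5],
                "bio1": [1.0, 3.0, 10.0],
                "bio12": [100.0, 100.0, 400.0],
            }
        )

    def test_unit_means(self):
        out = aggregate_climate(self._grid(), self.UNITS).set_index("unit")
        assert out.loc["u1", "bio1"] == pytest.approx(2.0)  # mean of 1 and 3
        assert out.loc["u2", "bio1"] == pytest.approx(10.0)

    def test_uniform_grid(self):
        g = self._grid()
        g["bio1"] = 10.0
        out = aggregate_climate(g, self.UNITS)
        assert (out.dropna()["bio1"] == 10.0).all()

    def test_unit_without_cells_flagged_missing(self):
        out = aggregate_climate(self._grid(), self.UNITS).set_index("unit")
        assert np.isnan(out.loc["u3", "bio1"])

    def test_regression_slope_recovery(self):
        rng = np.random.default_rng(21)
        n = 120
        bio1 = rng.uniform(0, 20, n)
        results = pd.DataFrame(
            {
                "scale": "s", "unit": [f"u{i}" for i in range(n)],
                "community_type": "Inv",
                "NRI": 0.5 * bio1 + rng.normal(0, 0.5, n),
                "NTI": rng.normal(0, 1, n),
            }
        )
        covs = pd.DataFrame(
            {"scale": "s", "unit": [f"u{i}" for i in range(n)],
             "bio1": bio1, "bio12": rng.uniform(0, 100, n)}
        )
        regs = climate_regressions(results, covs)
        row = regs[(regs["metric"] == "NRI") & (regs["climate_var"] == "bio1")]
        assert abs(row["slope"].iloc[0] - 0.5) < 2 * row["se"].iloc[0]

    def test_strata_independent(self):
        rng = np.random.default_rng(2)
        n = 40
        results = pd.DataFrame(
            {
                "scale": "s", "unit": [f"u{i}" for i in range(n)],
                "community_type": np.repeat(["Inv", "Nat"], n // 2),
                "NRI": rng.normal(size=n), "NTI": rng.normal(size=n),
            }
        )
        covs = pd.DataFrame(
            {"scale": "s", "unit": [f"u{i}" for i in range(n)],
             "bio1": rng.uniform(0, 10, n), "bio12": rng.uniform(0, 10, n)}
        )
        both = climate_regressions(results, covs)
        only_inv = climate_regressions(
            results[results["community_type"] == "Inv"], covs
        )
        pd.testing.assert_frame_equal(
            both[both["community_type"] == "Inv"].reset_index(drop=True),
            only_inv.reset_index(drop=True),
        )


def test_community_type_correlations_structure():
    rng = np.random.default_rng(9)
    rows = []
    for ctype in ("Inv", "Nat"):
        for u in range(10):
            rows.append(
                {"scale": "s", "unit": f"u{u}", "community_type": ctype,
                 "NRI": rng.normal(), "NTI": rng.normal()}
            )
    out = community_type_correlations(pd.DataFrame(rows))
    assert set(out["metric"]) == {"NRI", "NTI"}
    assert ((out["rho"] <= 1) & (out["rho"] >= -1)).all()
    assert (out["n"] == 10).all()
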
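"""Ranking statistics: two-stage FDR, overlap coefficient, ANOVA, scaling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

import leukosig as lk
from leukosig.stats import group_contrast_pvalues
from conftest import small_config


# --------------------------------------------------------------------------
# Benjamini-Krieger-Yekutieli two-stage step-up
# --------------------------------------------------------------------------

def bky_oracle(p, q):
    """Literal step-by-step two-stage evaluation, independent of the package.

    Runs BH by explicitly scanning thresholds from the largest sorted
    p-value downward, estimates m0 from the first pass, and repeats at the
    inflated level.
    """

    def bh(pv, alpha):
        m = len(pv)
        order = sorted(range(m), key=lambda i: pv[i])
        k_star = 0
        for k in range(m, 0, -1):
            if pv[order[k - 1]] <= alpha * k / m:
                k_star = k
                break
        rejected = [False] * m
        for i in range(k_star):
            rejected[order[i]] = True
        return rejected

    m = len(p)
    q1 = q / (1 + q)
    stage1 = bh(p, q1)
    r1 = sum(stage1)
    if r1 == 0 or r1 == m:
        return stage1
    return bh(p, q1 * m / (m - r1))


class TestBkyAdjust:
    def test_worked_example(self):
        res = lk.bky_adjust([0.001, 0.01, 0.02, 0.8], q=0.05)
        assert list(res.reject) == [True, True, True, False]
        assert res.n_stage1 == 3 and res.m0_hat == 1

    def test_all_ones_reject_nothing(self):
        assert not lk.bky_adjust([1.0, 1.0, 1.0, 1.0]).reject.any()

    def test_exhaustive_grid_vectors_match_step_by_step_oracle(self):
        grid = [0.001, 0.004, 0.01, 0.02, 0.04, 0.08, 0.2, 0.5, 0.8, 1.0]
        for length in range(1, 7):
            for combo in itertools.combinations_with_replacement(grid, length):
                got = lk.bky_adjust(list(combo), q=0.05).reject
                assert list(got) == bky_oracle(list(combo), 0.05), combo

    def test_superset_of_plain_bh_and_statsmodels_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
            res = lk.bky_adjust(p, q=0.05)
            # guaranteed containment: BH at the deflated stage-1 level
            # q/(1+q) is a subset of the two-stage rejections (when stage 1
            # rejects nothing the two coincide)
            bh = multipletests(p, alpha=0.05 / 1.05, method="fdr_bh")[0]
            assert (res.reject | ~bh).all()
            sm = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
            assert (res.reject == sm).all()

    def test_adjusted_values_encode_rejections(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 25) ** 2
        res = lk.bky_adjust(p, q=0.05)
        assert ((res.adjusted <= 0.05) == res.reject).all()

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan], []])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            lk.bky_adjust(bad)


from hypothesis import given, settings, strategies as st


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
def test_bky_matches_oracle_on_arbitrary_vectors(p):
    """Property: the two-stage step-up agrees with its literal evaluation."""
    got = list(lk.bky_adjust(p, q=0.05).reject)
    assert got == bky_oracle(p, 0.05)


# --------------------------------------------------------------------------
# Overlap coefficient
# --------------------------------------------------------------------------

class TestOverlapCoefficient:
    def test_self_overlap_near_one(self):
        x = np.random.default_rng(0).normal(0, 1, 1000)
        assert lk.overlap_coefficient(x, x) >= 0.99

    def test_gaussian_closed_form(self):
        # equal-variance normals separated by 2 sigma overlap by 2*Phi(-1)
        target = 2 * norm.cdf(-1.0)
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals.append(
                lk.overlap_coefficient(rng.normal(0, 1, 10000), rng.normal(2, 1, 10000))
            )
        assert np.mean(vals) == pytest.approx(target, abs=0.02)

    def test_disjoint_supports(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 500)
        b = rng.normal(100, 1, 500)
        assert lk.overlap_coefficient(a, b) <= 0.01

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(4)
        a, b = rng.exponential(2, 300), rng.normal(3, 2, 200)
        ov = lk.overlap_coefficient(a, b)
        assert 0.0 <= ov <= 1.0
        assert ov == pytest.approx(lk.overlap_coefficient(b, a), abs=1e-9)

    def test_degenerate_samples_do_not_crash(self):
        assert lk.overlap_coefficient([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0
        ov = lk.overlap_coefficient([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert 0.0 <= ov <= 0.01

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            lk.overlap_coefficient([1.0], [1.0, 2.0])


# --------------------------------------------------------------------------
# Two-way ANOVA contrasts + pooled BKY
# --------------------------------------------------------------------------

class TestAnova:
    def test_matches_statsmodels_ols_contrast(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "group": np.repeat(["Nil", "CT26", "4T1"], 8),
                "batch": np.tile(np.repeat(["e1", "e2"], 4), 3),
                "y": rng.lognormal(5, 0.5, 24),
            }
        )
        counts = pd.DataFrame({"pop": df["y"].to_numpy()})
        ours = group_contrast_pvalues(
            counts, df["group"], df["batch"], [("CT26", "Nil"), ("4T1", "CT26")]
        )
        df["logy"] = np.log10(df["y"] + 1)
        fit = smf.ols("logy ~ C(group) + C(batch)", data=df).fit()
        for _, row in ours.iterrows():
            contrast = (
                f"C(group)[T.{row['test']}]"
                if row["ref"] == "4T1"
                else f"C(group)[T.{row['test']}] - C(group)[T.{row['ref']}]"
            )
            # reference level of the treatment coding is '4T1' (sorted first)
            if row["test"] == "4T1":
                contrast = f"-C(group)[T.{row['ref']}]"
            expected = float(fit.t_test(contrast).pvalue)
            assert row["p"] == pytest.approx(expected, rel=1e-8)

    def test_identical_groups_not_significant(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "group": np.tile(["Nil", "CT26", "4T1"], 4),
                "batch": np.repeat(["e1", "e2"], 6),
                "beads": 5000,
                "pop": np.tile([100.0, 100.0, 100.0], 4),
            }
        )
        table = lk.CountTable(df, stage="rescaled")
        out = lk.anova_bky(table, [("CT26", "Nil"), ("4T1", "Nil")])
        assert not out["significant"].any()
        assert (out["p"] >= 0.99).all()

    def test_confounded_design_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(8)],
                "group": ["Nil"] * 4 + ["CT26"] * 4,
                "batch": ["e1"] * 4 + ["e2"] * 4,  # batch == group
                "beads": 5000,
                "pop": np.arange(8, dtype=float),
            }
        )
        table = lk.CountTable(df, stage="rescaled")
        with pytest.raises(lk.SchemaError, match="confounded"):
            lk.anova_bky(table, [("CT26", "Nil")])

    def test_null_rejection_rate_bounded(self):
        # type-I error of the pooled ANOVA+BKY family under the global null
        reps, rejected, total = 300, 0, 0
        for seed in range(reps):
            cfg = small_config(seed=seed + 10_000, effect_matrix={}, batch_sd=0.1)
            raw, _ = lk.simulate_cohort(cfg)
            table = lk.normalize_counts(raw, "Nil")
            out = lk.anova_bky(table, [("CT26", "Nil"), ("4T1", "Nil")])
            rejected += int(out["significant"].sum())
            total += len(out)
        rate = rejected / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert rate <= 0.05 + 3 * se

    def test_planted_fourfold_effect_detected(self):
        # power at n=15/group, CV 0.5, 4-fold planted effect
        hits = 0
        reps = 100
        for seed in range(reps):
            cfg = small_config(
                seed=seed + 20_000,
                count_cv=0.5,
                effect_matrix={("Mo F+L+", "CT26"): 4.0, ("Mo F+L+", "4T1"): 4.0},
            )
            raw, _ = lk.simulate_cohort(cfg)
            table = lk.normalize_counts(raw, "Nil")
            out = lk.anova_bky(table, [("CT26", "Nil"), ("4T1", "Nil")])
            hit = out[(out["population"] == "Mo F+L+") & (out["test"] == "CT26")]
            hits += int(hit["significant"].iloc[0])
        assert hits / reps >= 0.95


# --------------------------------------------------------------------------
# Pairwise stats, scaling, cumulative score, clustering
# --------------------------------------------------------------------------

@pytest.fixture(scope="module")
def stats_df(rescaled):
    return lk.build_pairwise_stats(
        rescaled, [("CT26", "Nil"), ("4T1", "Nil"), ("4T1", "CT26")]
    )


class TestPairwiseStats:

    def test_ma_values_and_antisymmetry(self, stats_df, rescaled):
        flipped = lk.build_pairwise_stats(rescaled, [("Nil", "CT26")])
        orig = stats_df[stats_df["comparison"] == "CT26 vs Nil"].set_index("population")
        flip = flipped.set_index("population")
        assert np.allclose(orig["M"], -flip["M"])
        assert np.allclose(orig["abs_lgfc"], flip["abs_lgfc"])
        assert np.allclose(orig["OV"], flip["OV"], atol=1e-9)
        assert np.allclose(orig["A"], flip["A"])

    def test_equal_means_give_zero_fold_change(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "group": np.tile(["Nil", "CT26"], 6),
                "batch": np.repeat(["e1", "e2"], 6),
                "beads": 5000,
                "pop": np.tile([50.0, 50.0], 6) + np.repeat(np.arange(6.0), 2),
            }
        )
        table = lk.CountTable(df, stage="rescaled")
        out = lk.build_pairwise_stats(table, [("CT26", "Nil")])
        assert out["M"].iloc[0] == pytest.approx(0.0)
        assert out["abs_lgfc"].iloc[0] == pytest.approx(0.0)
        assert out["lgfc_over_ov"].iloc[0] == pytest.approx(0.0)

    def test_invariants(self, stats_df):
        assert stats_df["OV"].between(0, 1).all()
        assert np.allclose(stats_df["one_minus_ov"], 1 - stats_df["OV"])
        assert np.allclose(stats_df["abs_lgfc"], stats_df["M"].abs())
        ns = stats_df[~stats_df["significant"]]
        assert (ns["direction"] == "NS").all()

    def test_row_order_invariance(self, rescaled):
        shuffled = lk.CountTable(
            rescaled.data.sample(frac=1, random_state=9).reset_index(drop=True),
            stage="rescaled",
        )
        a = lk.build_pairwise_stats(rescaled, [("CT26", "Nil")])
        b = lk.build_pairwise_stats(shuffled, [("CT26", "Nil")])
        pd.testing.assert_frame_equal(
            a.set_index("population"), b.set_index("population")
        )

    def test_unknown_group_rejected(self, rescaled):
        with pytest.raises(lk.SchemaError, match="B16"):
            lk.build_pairwise_stats(rescaled, [("B16", "Nil")])


class TestScaling:
    def test_minmax_example(self):
        df = pd.DataFrame(
            {
                "population": ["a", "b", "c"],
                "comparison": "CT26 vs Nil",
                "abs_lgfc": [2.0, 4.0, 6.0],
                "OV": [0.2, 0.4, 0.6],
                "one_minus_ov": [0.8, 0.6, 0.4],
                "lgfc_over_ov": [10.0, 10.0, 10.0],
                "neg_lg_p": [1.0, 2.0, 3.0],
            }
        )
        wide = lk.scale_metrics(df)
        assert list(wide["abs_lgfc|CT26 vs Nil"]) == pytest.approx([0.0, 0.5, 1.0])
        # constant column maps to zero
        assert list(wide["lgfc_over_ov|CT26 vs Nil"]) == pytest.approx([0.0, 0.0, 0.0])

    def test_neg_lg_p_scaled_across_pooled_comparisons(self, fitted):
        cols = [c for c in fitted.scaled_metrics if c.startswith("neg_lg_p|")]
        pooled = fitted.scaled_metrics[cols].to_numpy()
        assert pooled.max() == pytest.approx(1.0)
        # the single global smallest adjusted p attains the pooled maximum
        best = fitted.pairwise.loc[fitted.pairwise["neg_lg_p"].idxmax()]
        col = f"neg_lg_p|{best['comparison']}"
        assert fitted.scaled_metrics.loc[best["population"], col] == pytest.approx(1.0)

    def test_all_scaled_columns_in_unit_interval(self, fitted):
        m = fitted.scaled_metrics.to_numpy()
        assert (m >= 0).all() and (m <= 1).all()


class TestCumulativeScore:
    def make_scaled(self, values):
        return pd.DataFrame(
            {
                "neg_lg_p|CT26 vs Nil": values,
                "lgfc_over_ov|CT26 vs Nil": values,
            },
            index=[f"p{i}" for i in range(len(values))],
        )

    def test_best_everywhere_attains_component_count(self):
        scaled = self.make_scaled([1.0, 0.0, 0.5])
        ranks = pd.Series([1, 3, 2], index=scaled.index)
        score = lk.cumulative_score(scaled, ranks, ranks)
        assert score["p0"] == pytest.approx(4.0)  # 2 metrics + 2 rank scores
        assert score["p1"] == pytest.approx(0.0)

    def test_monotone_in_any_component(self):
        scaled = self.make_scaled([0.2, 0.6, 0.4])
        ranks = pd.Series([2, 1, 3], index=scaled.index)
        base = lk.cumulative_score(scaled, ranks, ranks)
        improved = scaled.copy()
        improved.loc["p0", "neg_lg_p|CT26 vs Nil"] = 0.9
        up = lk.cumulative_score(improved, ranks, ranks)
        assert up["p0"] > base["p0"]

    def test_missing_ranks_rejected(self):
        scaled = self.make_scaled([0.2, 0.6])
        with pytest.raises(ValueError, match="rank"):
            lk.cumulative_score(scaled, None, None)


class TestClusterPopulations:
    def test_k_equals_n_gives_singletons(self):
        m = pd.DataFrame(np.eye(5), index=list("abcde"))
        labels = lk.cluster_populations(m, k=5)
        assert sorted(labels) == [1, 2, 3, 4, 5]

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(0, 0.01, (6, 4))
        blob2 = rng.normal(5, 0.01, (5, 4))
        m = pd.DataFrame(np.vstack([blob1, blob2]), index=[f"p{i}" for i in range(11)])
        labels = lk.cluster_populations(m, k=2)
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_duplicate_rows_share_cluster(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 5.0]], index=list("abcd")
        )
        labels = lk.cluster_populations(m, k=3)
        assert labels["a"] == labels["b"]

    def test_k_larger_than_n_rejected(self):
        m = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            lk.cluster_populations(m, k=4)
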
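"""Biomarker statistics: FDR control, distribution overlap, pairwise metrics.

For every leukocyte population and every ordered pair of groups (test vs
reference) the pipeline computes:

* M = log2 fold change of group mean counts and A = log2 average count
  (MA-plot coordinates), with a +1 pseudocount so zero counts stay finite;
* a two-way ANOVA p-value on log10(Y+1)-transformed counts (group and
  experiment batch as crossed fixed effects), corrected across the whole
  family of populations x comparisons by the Benjamini-Krieger-Yekutieli
  two-stage step-up FDR procedure;
* the overlap coefficient OV of the two groups' per-animal count
  distributions (integral of the pointwise minimum of Gaussian kernel
  density estimates), and the discriminating statistic |LgFC| / OV.

Metrics are min-max scaled to [0, 1] (per comparison, except -Lg(p) which is
scaled across all comparisons pooled), summed with machine-learning
importance rank scores into a cumulative group-discriminating score, and the
populations grouped by Euclidean-distance hierarchical clustering over the
scaled metric columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .counts import CountTable
from .errors import SchemaError

__all__ = [
    "bky_adjust",
    "BkyResult",
    "overlap_coefficient",
    "anova_bky",
    "build_pairwise_stats",
    "scale_metrics",
    "cumulative_score",
    "cluster_populations",
]


# --------------------------------------------------------------------------
# Benjamini-Krieger-Yekutieli two-stage step-up FDR
# --------------------------------------------------------------------------

@dataclass
class BkyResult:
    reject: np.ndarray      # bool, per hypothesis, original order
    adjusted: np.ndarray    # adjusted p-values; reject == (adjusted <= q)
    n_stage1: int           # rejections of the first (BH at q/(1+q)) pass
    m0_hat: int             # estimated number of true nulls


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags (original order)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * np.arange(1, m + 1) / m
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        reject[order[: kmax + 1]] = True
    return reject


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def bky_adjust(pvalues, q: float = 0.05) -> BkyResult:
    """Two-stage step-up false-discovery-rate procedure.

    Stage 1 runs Benjamini-Hochberg at the deflated level q' = q / (1 + q);
    its rejection count r1 estimates the number of true nulls as
    m0 = m - r1.  If 0 < r1 < m, stage 2 reruns BH at the inflated level
    q* = q' * m / m0 and those rejections are final; r1 = 0 rejects nothing
    and r1 = m rejects everything.  More powerful than plain BH whenever a
    fraction of hypotheses is truly non-null.

    Returns a :class:`BkyResult`; ``adjusted`` satisfies
    ``reject == (adjusted <= q)`` and mirrors the convention of
    ``statsmodels`` (BH-adjusted p times (1 + q) * m0 / m).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = _bh_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        reject = stage1
        m0 = m
    elif r1 == m:
        reject = stage1
        m0 = 0
    else:
        m0 = m - r1
        reject = _bh_reject(p, q1 * m / m0)
    scale = (1.0 + q) * (m0 if m0 > 0 else 1) / m
    adjusted = np.minimum(_bh_adjust(p) * scale, 1.0)
    return BkyResult(reject=reject, adjusted=adjusted, n_stage1=r1, m0_hat=m0)


# --------------------------------------------------------------------------
# Kernel-density overlap coefficient
# --------------------------------------------------------------------------

def _nrd0(x: np.ndarray, floor: float) -> float:
    """Silverman's rule-of-thumb bandwidth (R's bw.nrd0) with a floor."""
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return floor
    return max(0.9 * spread * x.size ** (-0.2), floor)


def _kde(x: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    z = (grid[:, None] - x[None, :]) / bw
    return np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))


def overlap_coefficient(
    sample_a, sample_b, grid_size: int = 512, bw_floor_frac: float = 1e-6
) -> float:
    """Overlap OV of two empirical distributions, estimated by Gaussian KDE.

    OV is the integral of min(f_a, f_b) over a shared grid spanning the
    pooled range plus 3 bandwidths on each side; f are Gaussian kernel
    density estimates on the linear scale with Silverman (nrd0) bandwidths.
    OV = 1 means identical distributions, 0 disjoint ones.  Degenerate
    samples (zero spread) fall back to a floor bandwidth of
    ``bw_floor_frac`` times the pooled range, so the estimate is always
    defined.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for name, x in (("sample_a", a), ("sample_b", b)):
        if x.ndim != 1 or x.size < 2 or not np.all(np.isfinite(x)):
            raise ValueError(f"{name} must be 1-D with >= 2 finite values")
    pooled_range = float(max(a.max(), b.max()) - min(a.min(), b.min()))
    if pooled_range == 0:
        return 1.0  # all observations identical across both samples
    floor = bw_floor_frac * pooled_range
    bw_a, bw_b = _nrd0(a, floor), _nrd0(b, floor)
    pad = 3.0 * max(bw_a, bw_b)
    grid = np.linspace(
        min(a.min(), b.min()) - pad, max(a.max(), b.max()) + pad, grid_size
    )
    ov = float(np.trapezoid(np.minimum(_kde(a, grid, bw_a), _kde(b, grid, bw_b)), grid))
    return float(np.clip(ov, 0.0, 1.0))


# --------------------------------------------------------------------------
# Two-way ANOVA on log10(Y+1) counts with pooled BKY correction
# --------------------------------------------------------------------------

def _design_matrix(groups: pd.Series, batches: pd.Series):
    g_levels = sorted(groups.unique())
    b_levels = sorted(batches.unique())
    n = len(groups)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for g in g_levels[1:]:
        cols.append((groups == g).to_numpy(dtype=float))
        names.append(f"group[{g}]")
    for b in b_levels[1:]:
        cols.append((batches == b).to_numpy(dtype=float))
        names.append(f"batch[{b}]")
    X = np.column_stack(cols)
    return X, names, g_levels


def group_contrast_pvalues(
    counts: pd.DataFrame,
    groups: pd.Series,
    batches: pd.Series,
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Raw p-values for pairwise group contrasts from a two-factor OLS fit.

    Counts are transformed as log10(Y+1); per population an additive
    group + batch fixed-effects linear model is fitted (equivalent to
    two-way ANOVA without interaction), and each comparison (test, ref) is
    tested as the contrast of the two group coefficients using the pooled
    residual variance.  The design matrix is shared across populations, so
    all populations are solved in one multi-RHS least-squares pass.
    """
    X, names, g_levels = _design_matrix(groups, batches)
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise SchemaError(
            "singular two-way design: group and batch are confounded "
            "(some batch contains only one group)"
        )
    if n - k < 1:
        raise SchemaError("not enough samples for residual degrees of freedom")
    Y = np.log10(counts.to_numpy(dtype=float) + 1.0)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof

    known = set(g_levels)
    rows = []
    for test, ref in comparisons:
        for lab in (test, ref):
            if lab not in known:
                raise SchemaError(f"unknown group label {lab!r} in comparisons")
        c = np.zeros(k)
        if test != g_levels[0]:
            c[names.index(f"group[{test}]")] = 1.0
        if ref != g_levels[0]:
            c[names.index(f"group[{ref}]")] = -1.0
        var_c = float(c @ XtX_inv @ c)
        est = c @ beta
        # guard the zero-residual case (e.g. literally identical data in all
        # groups): a zero contrast over zero noise is "no evidence", p = 1
        scale = np.maximum((Y**2).mean(axis=0), 1.0)
        degenerate = sigma2 <= 1e-14 * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            t = est / np.sqrt(sigma2 * var_c)
        p = 2.0 * sps.t.sf(np.abs(t), dof)
        p = np.where(degenerate, np.where(np.abs(est) <= 1e-8 * np.sqrt(scale), 1.0, 0.0), p)
        p = np.where(np.isfinite(p), p, 1.0)
        for pop, pv, e in zip(counts.columns, p, est):
            rows.append((pop, test, ref, float(pv), float(e)))
    return pd.DataFrame(rows, columns=["population", "test", "ref", "p", "log10_diff"])


def anova_bky(
    table: CountTable,
    comparisons: list[tuple[str, str]],
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-(population, comparison) raw and BKY-adjusted two-way ANOVA p-values.

    All p-values across populations x comparisons form one multiple-testing
    family (matching the pooled scaling of -Lg(p) downstream).
    """
    if table.stage != "rescaled":
        raise SchemaError(f"anova_bky expects a rescaled table, got stage {table.stage!r}")
    for g in table.data["group"].unique():
        if (table.data["group"] == g).sum() < 2:
            raise SchemaError(f"group {g!r} has fewer than 2 samples")
    out = group_contrast_pvalues(
        table.counts(),
        table.data.set_index("sample_id")["group"],
        table.data.set_index("sample_id")["batch"],
        comparisons,
    )
    res = bky_adjust(out["p"].to_numpy(), q=q)
    out["p_adjusted"] = res.adjusted
    out["significant"] = res.reject
    return out


# --------------------------------------------------------------------------
# Pairwise statistics table
# --------------------------------------------------------------------------

def build_pairwise_stats(
    table: CountTable,
    comparisons: list[tuple[str, str]],
    q: float = 0.05,
    ov_floor: float = 0.01,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """One row per (population, test-vs-ref comparison) of ranking metrics.

    Columns: group means, MA coordinates (M, A with +1 pseudocount),
    |LgFC|, raw and BKY-adjusted p, -Lg(p) = -log2(adjusted p), overlap OV
    and 1-OV, |LgFC|/OV (OV floored at ``ov_floor`` so disjoint
    distributions stay finite), and an Up/Down/NS direction call
    (significant and at least ``fold_threshold``-fold).
    """
    pvals = anova_bky(table, comparisons, q=q)
    counts = table.counts()
    groups = table.data.set_index("sample_id")["group"]

    rows = []
    for _, r in pvals.iterrows():
        pop, test, ref = r["population"], r["test"], r["ref"]
        x = counts.loc[groups == test, pop].to_numpy(dtype=float)
        y = counts.loc[groups == ref, pop].to_numpy(dtype=float)
        mean_test, mean_ref = float(x.mean()), float(y.mean())
        m = float(np.log2((mean_test + 1.0) / (mean_ref + 1.0)))
        a = float(np.log2((mean_test + mean_ref) / 2.0 + 1.0))
        ov = overlap_coefficient(x, y)
        p_adj = max(float(r["p_adjusted"]), 1e-300)
        abs_lgfc = abs(m)
        fc = (mean_test + 1.0) / (mean_ref + 1.0)
        if r["significant"] and max(fc, 1.0 / fc) >= fold_threshold:
            direction = "Up" if m > 0 else "Down"
        else:
            direction = "NS"
        rows.append(
            {
                "population": pop,
                "test": test,
                "ref": ref,
                "comparison": f"{test} vs {ref}",
                "mean_test": mean_test,
                "mean_ref": mean_ref,
                "M": m,
                "A": a,
                "abs_lgfc": abs_lgfc,
                "p": float(r["p"]),
                "p_adjusted": float(r["p_adjusted"]),
                "significant": bool(r["significant"]),
                "neg_lg_p": float(-np.log2(p_adj)),
                "OV": ov,
                "one_minus_ov": 1.0 - ov,
                "lgfc_over_ov": abs_lgfc / max(ov, ov_floor),
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Metric scaling, cumulative score, clustering
# --------------------------------------------------------------------------

PER_COMPARISON_METRICS = ("abs_lgfc", "OV", "one_minus_ov", "lgfc_over_ov")
POOLED_METRICS = ("neg_lg_p",)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def scale_metrics(stats: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each ranking metric to [0, 1].

    Scaling is within each pairwise comparison for every metric except
    -Lg(p), which is scaled over the pooled values of all comparisons so
    the single smallest adjusted p attains 1.  Constant columns map to 0.
    The result is wide: one row per population, one column per
    (metric, comparison).
    """
    if stats["population"].nunique() < 2:
        raise SchemaError("metric scaling needs at least 2 populations")
    df = stats.copy()
    for metric in PER_COMPARISON_METRICS:
        df[f"scaled_{metric}"] = df.groupby("comparison")[metric].transform(
            lambda v: _minmax(v.to_numpy())
        )
    for metric in POOLED_METRICS:
        df[f"scaled_{metric}"] = _minmax(df[metric].to_numpy())
    wide = df.pivot(
        index="population",
        columns="comparison",
        values=[f"scaled_{m}" for m in PER_COMPARISON_METRICS + POOLED_METRICS],
    )
    wide.columns = [f"{m.removeprefix('scaled_')}|{c}" for m, c in wide.columns]
    return wide.sort_index()


def rank_to_score(ranks: pd.Series) -> pd.Series:
    """Map importance rank r in 1..n to a [0, 1] score, rank 1 -> 1."""
    n = len(ranks)
    if n < 2:
        return pd.Series(1.0, index=ranks.index)
    return (n - ranks.astype(float)) / (n - 1)


def cumulative_score(
    scaled: pd.DataFrame,
    rf_ranks: pd.Series,
    gbt_ranks: pd.Series,
) -> pd.Series:
    """Cumulative group-discriminating score per population.

    Sum over comparisons of scaled -Lg(p), plus sum over comparisons of
    scaled |LgFC|/OV, plus the scaled random-forest and gradient-boosted-tree
    importance rank scores ((n - rank) / (n - 1), so the top-ranked
    population contributes 1).
    """
    if rf_ranks is None or gbt_ranks is None:
        raise ValueError(
            "ML importance ranks are required; run feature ranking first"
        )
    idx = scaled.index
    for name, r in (("rf_ranks", rf_ranks), ("gbt_ranks", gbt_ranks)):
        if not idx.isin(r.index).all():
            raise ValueError(f"{name} does not cover all populations")
    comps = [c for c in scaled.columns if c.startswith("neg_lg_p|")]
    ratios = [c for c in scaled.columns if c.startswith("lgfc_over_ov|")]
    score = scaled[comps].sum(axis=1) + scaled[ratios].sum(axis=1)
    score = score + rank_to_score(rf_ranks.loc[idx]) + rank_to_score(gbt_ranks.loc[idx])
    score.name = "cumulative_score"
    return score


def cluster_populations(
    metric_matrix: pd.DataFrame, k: int = 9, linkage: str = "complete"
) -> pd.Series:
    """Cut a Euclidean-distance hierarchical tree into exactly k clusters.

    Labels are integers 1..k indexed by population; rows with identical
    metrics always share a cluster for k < n.
    """
    n = len(metric_matrix)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of populations ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    Z = hierarchy.linkage(metric_matrix.to_numpy(dtype=float), method=linkage)
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel() + 1
    return pd.Series(labels, index=metric_matrix.index, name="cluster_id")
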
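"""Model/Results interface tying the ranking statistics to the classifiers.

:class:`BiomarkerModel` is built from a fully normalized (rescaled) cohort
count table; ``fit()`` computes the pairwise statistics, the random-forest
and gradient-boosted-tree importance ranks, the 0-1 scaled metric table,
the cumulative group-discriminating score and the population clustering,
and returns a :class:`BiomarkerResults` carrying them.  Evaluation
(repeated holdout, learning curve, 6+2 feature selection, classical MDS)
hangs off the results object.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import ml, stats
from .counts import CountTable, normalize_counts
from .errors import SchemaError


def default_comparisons(groups: list[str], control_group: str) -> list[tuple[str, str]]:
    """Every tumor group vs control, then tumor-vs-tumor pairs in sorted order."""
    tumors = sorted(g for g in groups if g != control_group)
    pairs = [(t, control_group) for t in tumors]
    pairs += [(b, a) for i, a in enumerate(tumors) for b in tumors[i + 1:]]
    return pairs


class BiomarkerModel:
    """Leukocyte-count biomarker ranking model.

    Parameters
    ----------
    counts : CountTable
        Cohort table in the ``rescaled`` stage (per-animal normalized counts).
    control_group : str
        Label of the no-tumor control group.
    comparisons : list of (test, ref) pairs, optional
        Defaults to every tumor group vs control plus tumor-vs-tumor pairs.
    q : float
        Target false-discovery rate of the BKY correction.
    ov_floor : float
        Lower bound on OV inside |LgFC|/OV so disjoint distributions stay
        finite.
    fold_threshold : float
        Minimum fold change (with BKY significance) for an Up/Down call.
    linkage : str
        Hierarchical-clustering linkage over the scaled metric columns.
    """

    def __init__(
        self,
        counts: CountTable,
        control_group: str = "Nil",
        comparisons: list[tuple[str, str]] | None = None,
        q: float = 0.05,
        ov_floor: float = 0.01,
        fold_threshold: float = 2.0,
        linkage: str = "complete",
    ):
        if counts.stage != "rescaled":
            raise SchemaError(
                f"BiomarkerModel expects a rescaled count table, got stage {counts.stage!r};"
                " use BiomarkerModel.from_raw to run the normalization chain"
            )
        if control_group not in counts.groups:
            raise SchemaError(f"control group {control_group!r} not in table")
        self.counts = counts
        self.control_group = control_group
        self.comparisons = comparisons or default_comparisons(counts.groups, control_group)
        self.q = q
        self.ov_floor = ov_floor
        self.fold_threshold = fold_threshold
        self.linkage = linkage

    @classmethod
    def from_raw(cls, raw: CountTable, control_group: str = "Nil", **kwargs) -> "BiomarkerModel":
        """Normalize a raw cohort (bead -> nil -> rescale) and build the model."""
        return cls(normalize_counts(raw, control_group), control_group, **kwargs)

    @property
    def feature_table(self) -> pd.DataFrame:
        return self.counts.counts()

    @property
    def labels(self) -> pd.Series:
        return self.counts.data.set_index("sample_id")["group"]

    def fit(
        self,
        k_clusters: int = 9,
        ml_params: ml.ModelParams | None = None,
        seed: int = 0,
    ) -> "BiomarkerResults":
        """Compute pairwise stats, ML ranks, scaled metrics, scores and clusters."""
        pairwise = stats.build_pairwise_stats(
            self.counts,
            self.comparisons,
            q=self.q,
            ov_floor=self.ov_floor,
            fold_threshold=self.fold_threshold,
        )
        base = ml_params or ml.ModelParams(seed=seed)
        gbt = replace(base, model_kind="gbt", seed=seed)
        rf = replace(base, model_kind="rf", seed=seed)
        X, y = self.feature_table, self.labels
        gbt_ranks = ml.feature_ranks(X, y, gbt)
        rf_ranks = ml.feature_ranks(X, y, rf)
        scaled = stats.scale_metrics(pairwise)
        score = stats.cumulative_score(scaled, rf_ranks, gbt_ranks)
        k = min(k_clusters, len(scaled))
        clusters = stats.cluster_populations(scaled, k=k, linkage=self.linkage)
        return BiomarkerResults(
            model=self,
            pairwise=pairwise,
            scaled_metrics=scaled,
            rf_ranks=rf_ranks,
            gbt_ranks=gbt_ranks,
            cumulative=score,
            clusters=clusters,
            gbt_params=gbt,
        )


class BiomarkerResults:
    """Fitted ranking results with evaluation helpers.

    Attributes
    ----------
    pairwise : DataFrame
        One row per (population, comparison): means, M, A, |LgFC|, p,
        adjusted p, -Lg(p), OV, 1-OV, |LgFC|/OV, direction.
    scaled_metrics : DataFrame
        Population x (metric | comparison) 0-1 scaled columns.
    rf_ranks, gbt_ranks : Series
        Importance ranks (1 = most important) per population.
    cumulative : Series
        Cumulative group-discriminating score per population.
    clusters : Series
        Hierarchical cluster labels 1..k per population.
    """

    def __init__(
        self, model, pairwise, scaled_metrics, rf_ranks, gbt_ranks, cumulative,
        clusters, gbt_params,
    ):
        self.model = model
        self.pairwise = pairwise
        self.scaled_metrics = scaled_metrics
        self.rf_ranks = rf_ranks
        self.gbt_ranks = gbt_ranks
        self.cumulative = cumulative
        self.clusters = clusters
        self.gbt_params = gbt_params

    # ------------------------------------------------------------- tables

    @property
    def rank_table(self) -> pd.DataFrame:
        """Scaled metrics with ML ranks, cumulative score and cluster id."""
        out = self.scaled_metrics.copy()
        out["rf_rank"] = self.rf_ranks.reindex(out.index)
        out["gbt_rank"] = self.gbt_ranks.reindex(out.index)
        out["cumulative_score"] = self.cumulative.reindex(out.index)
        out["cluster_id"] = self.clusters.reindex(out.index)
        return out.sort_values("cumulative_score", ascending=False)

    def top_populations(self, n: int = 10) -> list[str]:
        return list(self.rank_table.index[:n])

    # --------------------------------------------------------- evaluation

    def evaluate(
        self,
        features: list[str] | None = None,
        repeats: int = 100,
        train_fraction: float = 0.66,
        seed: int | None = None,
    ) -> ml.EvaluationResult:
        """Repeated-holdout GBT evaluation on a feature subset (default: all)."""
        X = self.model.feature_table
        if features is not None:
            X = X[list(features)]
        params = self.gbt_params if seed is None else replace(self.gbt_params, seed=seed)
        return ml.repeated_holdout(
            X, self.model.labels, params, repeats=repeats, train_fraction=train_fraction
        )

    def learning_curve(
        self, repeats: int = 100, train_fraction: float = 0.66
    ) -> pd.DataFrame:
        """Metrics vs number of features, dropping lowest GBT rank first."""
        return ml.learning_curve(
            self.model.feature_table,
            self.model.labels,
            self.gbt_ranks,
            self.gbt_params,
            repeats=repeats,
            train_fraction=train_fraction,
        )

    def select_features(self, n_top: int = 6, n_extra: int = 2) -> ml.FeatureSelection:
        """Top GBT-ranked populations unioned with top cumulative-score ones."""
        return ml.select_features(self.gbt_ranks, self.cumulative, n_top, n_extra)

    def mds(self, features: list[str] | None = None) -> pd.DataFrame:
        """Classical MDS coordinates of samples on a feature subset."""
        return ml.classical_mds(self.model.feature_table, features)

    # ------------------------------------------------------------ summary

    def summary(self, n: int = 10) -> str:
        """Human-readable overview of the fitted ranking."""
        lines = []
        lines.append("Leukocyte biomarker ranking")
        lines.append("=" * 64)
        n_pop = len(self.scaled_metrics)
        n_samp = len(self.model.labels)
        lines.append(f"Populations: {n_pop}    Samples: {n_samp}")
        lines.append(f"Groups: {', '.join(self.model.counts.groups)}"
                     f" (control: {self.model.control_group})")
        lines.append(
            "Comparisons: " + ", ".join(f"{t} vs {r}" for t, r in self.model.comparisons)
        )
        n_sig = int(self.pairwise["significant"].sum())
        lines.append(
            f"BKY-significant contrasts (q={self.model.q}): {n_sig}"
            f" / {len(self.pairwise)}"
        )
        lines.append("-" * 64)
        lines.append(f"Top {min(n, n_pop)} populations by cumulative score:")
        header = f"{'population':<14}{'score':>8}{'RF':>5}{'GBT':>5}{'cluster':>9}"
        lines.append(header)
        for pop in self.top_populations(n):
            lines.append(
                f"{pop:<14}{self.cumulative[pop]:>8.3f}"
                f"{int(self.rf_ranks[pop]):>5}{int(self.gbt_ranks[pop]):>5}"
                f"{int(self.clusters[pop]):>9}"
            )
        return "\n".join(lines)
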
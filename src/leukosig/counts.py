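"""Blood-leukocyte count tables and the three-stage count normalization.

A cohort is stored wide: one row per animal sample with its group label,
experiment batch, counting-bead events, and one column per gated leukocyte
population.  Counts move through an ordered chain of stages:

``raw`` -> ``bead_normalized`` -> ``nil_normalized`` -> ``rescaled``

1. *Counting-bead normalization* converts raw event counts into absolute
   cells per a fixed blood volume by scaling each sample to the full spiked
   bead load (5000 Flow-Count Fluorospheres, roughly 5 uL of blood).
2. *Nil normalization* divides each bead-normalized count by the mean count
   of the no-tumor control animals of the same experiment batch and
   population, removing multiplicative batch effects.
3. *Rescaling* multiplies the nil-normalized ratios by the grand mean of the
   bead-normalized control counts (pooled over all batches) so values are
   again interpretable as cells per ~5 uL.

Applying a stage to a table that is not in its required input stage raises
:class:`~leukosig.errors.StageError`; the chain is strictly forward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, StageError

META_COLUMNS = ("sample_id", "group", "batch", "beads")

STAGES = ("raw", "bead_normalized", "nil_normalized", "rescaled")


@dataclass
class CountTable:
    """Wide per-sample population count table with a normalization stage tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``sample_id``, ``group``, ``batch``, ``beads`` followed by one
        numeric column per leukocyte population.
    stage : str
        One of ``raw``, ``bead_normalized``, ``nil_normalized``, ``rescaled``.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"count table is missing columns: {missing}")
        if self.stage not in STAGES:
            raise SchemaError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        counts = self.data[self.populations].to_numpy(dtype=float)
        if not np.all(np.isfinite(counts)):
            raise SchemaError("count table contains non-finite population counts")
        if (counts < 0).any():
            raise SchemaError("count table contains negative population counts")
        if self.stage == "raw" and (self.data["beads"] <= 0).any():
            bad = self.data.loc[self.data["beads"] <= 0, "sample_id"].tolist()
            raise SchemaError(f"raw count table has non-positive bead counts for samples {bad}")

    @property
    def populations(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS and c != "stage"]

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def batches(self) -> list[str]:
        return sorted(self.data["batch"].astype(str).unique())

    def counts(self) -> pd.DataFrame:
        """Population count matrix indexed by sample_id."""
        return self.data.set_index("sample_id")[self.populations]

    def _require_stage(self, expected: str, op: str) -> None:
        if self.stage != expected:
            raise StageError(
                f"{op} requires a table in stage {expected!r}, got {self.stage!r}; "
                "stages advance strictly raw -> bead_normalized -> nil_normalized -> rescaled"
            )

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(4, "stage", self.stage)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        df = pd.read_csv(path)
        if "stage" not in df.columns:
            raise SchemaError(f"{path}: count CSV is missing the 'stage' column")
        stages = df["stage"].unique()
        if len(stages) != 1:
            raise SchemaError(f"{path}: count CSV mixes stages {sorted(stages)}")
        stage = str(stages[0])
        df = df.drop(columns="stage")
        df["group"] = df["group"].astype(str).str.strip()
        df["batch"] = df["batch"].astype(str).str.strip()
        return cls(df, stage=stage)


def bead_normalize(table: CountTable, target_beads: int = 5000) -> CountTable:
    """Scale each sample's counts to a fixed counting-bead load.

    ``count' = count * target_beads / beads`` converts raw event counts to
    absolute cells per the spiked bead volume (~5 uL of blood at the default
    5000-bead load).
    """
    table._require_stage("raw", "bead_normalize")
    if target_beads <= 0:
        raise ValueError("target_beads must be positive")
    out = table.data.copy()
    factor = target_beads / out["beads"].to_numpy(dtype=float)
    for pop in table.populations:
        out[pop] = out[pop].to_numpy(dtype=float) * factor
    return CountTable(out, stage="bead_normalized")


def nil_normalize(table: CountTable, control_group: str) -> CountTable:
    """Divide counts by the same-batch control-group mean, per population.

    Control animals average to exactly 1 within each (batch, population),
    which removes multiplicative batch effects shared by all groups of an
    experiment.
    """
    table._require_stage("bead_normalized", "nil_normalize")
    if control_group not in set(table.data["group"]):
        raise SchemaError(f"control group {control_group!r} not present in table")
    out = table.data.copy()
    pops = table.populations
    for batch, idx in out.groupby("batch").groups.items():
        block = out.loc[idx]
        ctrl = block[block["group"] == control_group]
        if ctrl.empty:
            raise SchemaError(f"batch {batch!r} has no {control_group!r} control samples")
        means = ctrl[pops].mean(axis=0)
        zero = means[means <= 0]
        if not zero.empty:
            raise SchemaError(
                f"zero control mean in batch {batch!r} for populations {zero.index.tolist()}"
            )
        out.loc[idx, pops] = block[pops].to_numpy(dtype=float) / means.to_numpy(dtype=float)
    return CountTable(out, stage="nil_normalized")


def grand_control_means(bead_normalized: CountTable, control_group: str) -> pd.Series:
    """Per-population mean bead-normalized count of all control animals.

    Pooled over every batch, unweighted by batch size; this is the scale the
    nil-normalized ratios are multiplied back onto.
    """
    bead_normalized._require_stage("bead_normalized", "grand_control_means")
    ctrl = bead_normalized.data[bead_normalized.data["group"] == control_group]
    if ctrl.empty:
        raise SchemaError(f"control group {control_group!r} not present in table")
    return ctrl[bead_normalized.populations].mean(axis=0)


def rescale_to_counts(table: CountTable, grand_means: pd.Series) -> CountTable:
    """Multiply nil-normalized ratios by per-population grand control means."""
    table._require_stage("nil_normalized", "rescale_to_counts")
    missing = [p for p in table.populations if p not in grand_means.index]
    if missing:
        raise SchemaError(f"grand means missing for populations {missing}")
    out = table.data.copy()
    for pop in table.populations:
        out[pop] = out[pop].to_numpy(dtype=float) * float(grand_means[pop])
    return CountTable(out, stage="rescaled")


def normalize_counts(
    raw: CountTable, control_group: str, target_beads: int = 5000
) -> CountTable:
    """Run the full chain raw -> bead-normalized -> nil-normalized -> rescaled."""
    bead = bead_normalize(raw, target_beads=target_beads)
    grand = grand_control_means(bead, control_group)
    return rescale_to_counts(nil_normalize(bead, control_group), grand)
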
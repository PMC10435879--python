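"""Antibody-screen (MedFI) normalization chain.

A surface-marker screen measures, for every gated leukocyte population in
every barcoded sample group, the median fluorescence intensity of the PE
reporter channel (MedFI-PE) of one antibody per well, alongside two kinds of
control wells:

* FMO ("fluorescence minus one") wells per (population, group), which define
  the PE-channel background in the absence of the screened antibody;
* isotype-control wells per (population, isotype class), which estimate
  non-specific antibody binding.

The normalization chain is:

1. :func:`fmo_correct` — subtract the mean FMO MedFI-PE of each
   (population, group) from every screen entry, giving background-corrected
   BC-MedFI-PE values.
2. :func:`tumor_delta_scale` — subtract the matched no-tumor control group's
   BC-MedFI-PE, then divide each (population, marker)'s deltas by the
   maximum positive delta across tumor groups, flooring at -1.  The result
   is a dimensionless cancer-specific change scale in [-1, 1] with 0 at
   control level.
3. :func:`isotype_qc` — flag markers whose average expression falls below
   their matched isotype control (negative specific signal is a technical
   anomaly and the marker is excluded from ranking).
4. :func:`sum_abs_change` — per-marker sum of absolute raw MedFI deltas
   across all populations and tumor groups (the cumulative change S|I|).
5. :func:`top_fraction_filter` — keep the markers whose largest absolute
   scaled change is in the top fraction (default 30%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

ENTRY_TYPES = ("screen", "fmo", "isotype")

_COLUMNS = ["population", "group", "marker", "value", "entry_type"]


@dataclass
class ScreenTable:
    """Long-format screen table.

    ``data`` columns: ``population``, ``group``, ``marker``, ``value``,
    ``entry_type`` in {"screen", "fmo", "isotype"}.  For FMO rows the marker
    column is empty; for isotype rows the marker column holds the isotype
    class label and the group column is empty.  ``marker_meta`` maps each
    screened marker to its isotype class.  ``stage`` is ``"medfi"`` for raw
    values and ``"bc_medfi"`` after FMO correction.
    """

    data: pd.DataFrame
    marker_meta: dict[str, str] = field(default_factory=dict)
    stage: str = "medfi"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"screen table is missing columns: {missing}")
        bad = set(self.data["entry_type"]) - set(ENTRY_TYPES)
        if bad:
            raise SchemaError(f"unknown entry_type values {sorted(bad)}")
        if not np.all(np.isfinite(self.data["value"].to_numpy(dtype=float))):
            raise SchemaError("screen table contains non-finite MedFI values")
        ent = self.entries()
        fmo = self.data[self.data["entry_type"] == "fmo"]
        have_fmo = set(zip(fmo["population"], fmo["group"]))
        need = set(zip(ent["population"], ent["group"]))
        lacking = sorted(need - have_fmo)
        if lacking:
            raise SchemaError(f"missing FMO control for (population, group): {lacking}")

    def entries(self) -> pd.DataFrame:
        return self.data[self.data["entry_type"] == "screen"]

    @property
    def markers(self) -> list[str]:
        return sorted(self.entries()["marker"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.entries()["population"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.entries()["group"].unique())

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["isotype_class"] = out["marker"].map(self.marker_meta).where(
            out["entry_type"] == "screen", ""
        )
        out.insert(0, "stage", self.stage)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScreenTable":
        df = pd.read_csv(path, keep_default_na=False)
        stage = "medfi"
        if "stage" in df.columns:
            stages = set(df["stage"])
            if len(stages) != 1:
                raise SchemaError(f"{path}: screen CSV mixes stages {sorted(stages)}")
            stage = str(df["stage"].iloc[0])
            df = df.drop(columns="stage")
        meta: dict[str, str] = {}
        if "isotype_class" in df.columns:
            scr = df[df["entry_type"] == "screen"]
            meta = {
                m: c
                for m, c in zip(scr["marker"], scr["isotype_class"])
                if isinstance(c, str) and c
            }
            df = df.drop(columns="isotype_class")
        df["value"] = df["value"].astype(float)
        return cls(df, marker_meta=meta, stage=stage)


@dataclass
class ScaledChangeTable:
    """Cancer-specific marker changes on the -1..1 scale.

    One row per (population, group, marker) with the FMO-corrected value
    (``bc_medfi``), the raw delta from the matched no-tumor control in MedFI
    units (``delta``), and the scaled change ``s`` in [-1, 1].  Control-group
    rows carry ``s = 0`` and ``delta = 0`` by construction.
    """

    data: pd.DataFrame
    control_groups: tuple[str, ...] = ()

    @property
    def tumor_rows(self) -> pd.DataFrame:
        return self.data[~self.data["group"].isin(self.control_groups)]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, control_groups=()) -> "ScaledChangeTable":
        return cls(pd.read_csv(path, keep_default_na=False), tuple(control_groups))


def fmo_correct(screen: ScreenTable) -> ScreenTable:
    """Subtract the mean FMO MedFI-PE of each (population, group).

    Screen entries become BC-MedFI-PE.  Isotype-control rows, which carry no
    group of their own, are corrected by the population's mean FMO value
    across groups.
    """
    if screen.stage != "medfi":
        raise SchemaError(f"fmo_correct expects stage 'medfi', got {screen.stage!r}")
    fmo = screen.data[screen.data["entry_type"] == "fmo"]
    pg_mean = fmo.groupby(["population", "group"])["value"].mean()
    pop_mean = fmo.groupby("population")["value"].mean()
    out = screen.data.copy()
    is_screen = out["entry_type"] == "screen"
    is_iso = out["entry_type"] == "isotype"
    keys = pd.MultiIndex.from_arrays([out["population"], out["group"]])
    corr = pg_mean.reindex(keys).to_numpy()
    out.loc[is_screen, "value"] = out.loc[is_screen, "value"] - corr[is_screen.to_numpy()]
    out.loc[is_iso, "value"] = (
        out.loc[is_iso, "value"]
        - pop_mean.reindex(out.loc[is_iso, "population"]).to_numpy()
    )
    out = out[out["entry_type"] != "fmo"].reset_index(drop=True)
    # re-attach a zero FMO row per (population, group) so the schema invariant holds
    zeros = pg_mean.reset_index()
    zeros["value"] = 0.0
    zeros["marker"] = ""
    zeros["entry_type"] = "fmo"
    out = pd.concat([out, zeros[_COLUMNS]], ignore_index=True)
    return ScreenTable(out, marker_meta=dict(screen.marker_meta), stage="bc_medfi")


def tumor_delta_scale(
    corrected: ScreenTable,
    control_group_map: dict[str, str],
    per_population: bool = True,
) -> ScaledChangeTable:
    """Subtract matched-control BC-MedFI-PE and max-scale per (population, marker).

    ``delta(p, g, m) = BC(p, g, m) - BC(p, control(g), m)`` for each tumor
    group; the divisor is the maximum signed (largest positive) delta across
    tumor groups for that (population, marker), falling back to the maximum
    absolute delta when no positive delta exists.  ``s = delta / divisor``
    floor-clipped at -1, so the strongest increase maps to exactly 1 and
    decreases larger than the strongest increase saturate at -1.  With
    ``per_population=False`` the divisor is shared across populations per
    marker.
    """
    if corrected.stage != "bc_medfi":
        raise SchemaError("tumor_delta_scale expects an FMO-corrected (bc_medfi) table")
    ent = corrected.entries()
    controls = set(control_group_map.values())
    missing = controls - set(ent["group"])
    if missing:
        raise SchemaError(f"control groups absent from screen table: {sorted(missing)}")
    bc = ent.set_index(["population", "group", "marker"])["value"]

    rows = []
    for (pop, group, marker), value in bc.items():
        if group in controls:
            rows.append((pop, group, marker, value, 0.0))
            continue
        ctrl = control_group_map.get(group)
        if ctrl is None:
            raise SchemaError(f"tumor group {group!r} has no control mapping")
        delta = value - bc.loc[(pop, ctrl, marker)]
        rows.append((pop, group, marker, value, delta))
    df = pd.DataFrame(rows, columns=["population", "group", "marker", "bc_medfi", "delta"])

    tumor = ~df["group"].isin(controls)
    keys = ["population", "marker"] if per_population else ["marker"]
    grp = df.loc[tumor].groupby(keys)["delta"]
    pos_max = grp.max()
    abs_max = grp.apply(lambda d: d.abs().max())
    divisor = pos_max.where(pos_max > 0, abs_max)

    div = divisor.reindex(pd.MultiIndex.from_frame(df[keys]) if per_population else df["marker"])
    div = div.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(div > 0, df["delta"].to_numpy() / div, 0.0)
    s = np.maximum(s, -1.0)
    s[~tumor.to_numpy()] = 0.0
    df["s"] = s
    return ScaledChangeTable(df, control_groups=tuple(sorted(controls)))


def isotype_qc(corrected: ScreenTable) -> pd.DataFrame:
    """Per-marker isotype-corrected expression and QC pass flag.

    For each screen entry the matched isotype-class control value of the same
    population is subtracted; the per-marker average of these differences is
    the isotype-corrected expression.  Markers with a negative value fail QC
    (zero passes: exclusion is only for fluorescence below the isotype
    control) and are dropped from downstream ranking.
    """
    ent = corrected.entries()
    iso = corrected.data[corrected.data["entry_type"] == "isotype"]
    iso_val = iso.set_index(["population", "marker"])["value"]
    unmapped = [m for m in ent["marker"].unique() if m not in corrected.marker_meta]
    if unmapped:
        raise SchemaError(f"markers with no isotype class mapping: {sorted(unmapped)}")
    classes = ent["marker"].map(corrected.marker_meta)
    keys = pd.MultiIndex.from_arrays([ent["population"], classes])
    matched = iso_val.reindex(keys).to_numpy(dtype=float)
    if np.isnan(matched).any():
        bad = sorted({k for k, v in zip(keys, matched) if np.isnan(v)})
        raise SchemaError(f"missing isotype control entries for (population, class): {bad}")
    diff = ent["value"].to_numpy(dtype=float) - matched
    expr = pd.Series(diff, index=ent["marker"].to_numpy()).groupby(level=0).mean()
    out = pd.DataFrame(
        {"isotype_corrected_expression": expr, "qc_pass": expr >= 0.0}
    )
    out.index.name = "marker"
    return out.sort_index()


def sum_abs_change(scaled: ScaledChangeTable) -> pd.Series:
    """Per-marker sum of |delta| in raw MedFI units over populations and tumor groups."""
    tumor = scaled.tumor_rows
    s = tumor.groupby("marker")["delta"].apply(lambda d: d.abs().sum())
    s.name = "s_abs"
    return s.sort_index()


def top_fraction_filter(
    scaled: ScaledChangeTable,
    fraction: float = 0.30,
    qc: pd.DataFrame | None = None,
    score_on: str = "delta",
) -> list[str]:
    """Markers whose peak absolute MedFI change is in the top ``fraction``.

    Each marker is scored by max over (population, tumor group) of the
    absolute change; the top ``ceil(fraction * n)`` scores are kept, with
    all markers tied at the cut retained.  Markers failing isotype QC are
    removed before scoring.  ``score_on="delta"`` (default) scores raw
    MedFI deltas; ``"scaled"`` scores |s| instead, but note that per-cell
    max-scaling sends the peak |s| of nearly every marker to exactly 1, so
    the scaled variant only discriminates through the -1 clip.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if score_on not in ("delta", "scaled"):
        raise ValueError("score_on must be 'delta' or 'scaled'")
    tumor = scaled.tumor_rows
    if tumor.empty:
        raise SchemaError("scaled change table has no tumor-group rows")
    col = "delta" if score_on == "delta" else "s"
    scores = tumor.groupby("marker")[col].apply(lambda v: v.abs().max())
    if qc is not None:
        passing = qc.index[qc["qc_pass"]]
        scores = scores[scores.index.isin(passing)]
    if scores.empty:
        raise SchemaError("no markers remain after QC filtering")
    k = max(1, int(np.ceil(fraction * len(scores))))
    cutoff = np.sort(scores.to_numpy())[::-1][k - 1]
    kept = scores[scores >= cutoff]
    return sorted(kept.index, key=lambda m: (-kept[m], m))
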
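"""Synthetic cytometry cohorts and antibody screens with known ground truth.

The generator emulates the statistical structure the analysis assumes,
so planted effects can be recovered and quantified:

* a cohort of mice in a no-tumor control group ("Nil") and tumor-bearing
  groups, spread over independent experiment batches (default 3 batches of
  5 animals per group, with one animal missing from the last 4T1 batch,
  i.e. 15/15/14 animals in total);
* per-animal event counts for ~39 gated blood leukocyte populations, drawn
  log-normally around a per-population baseline times a planted
  group-specific fold change times a multiplicative per-(batch, population)
  effect;
* counting-bead events per sample (acquisition stops near 2000 collected
  beads out of a 5000-bead spike);
* a marker screen with per-(population, marker) background MedFI, a
  constant additive FMO channel offset, isotype-control offsets, planted
  tumor-specific MedFI shifts, and additive Gaussian well noise.

Both generators are deterministic given ``SimConfig.seed`` and return a
:class:`PlantedTruth` describing which populations/markers were perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .counts import CountTable
from .errors import ConfigError
from .screen import ScreenTable

# 39 gated blood leukocyte subsets: monocyte (Mo) subsets by SiglecF (F) and
# CD62L (L), neutrophil (N) subsets by CD45RB (B) and CD66a (6a), dendritic
# cells, T/B/NK lineages.
DEFAULT_POPULATIONS: tuple[str, ...] = (
    "Mo F+L+", "Mo F+L-", "Mo F-L+", "Mo F-L-", "Mo Ly6Chi", "Mo Ly6Clo",
    "N B-6a+", "N B+6a-", "N B+6a+", "N B-6a-", "Eos", "Bas",
    "pDC", "cDC1", "cDC2", "MDSC PMN", "MDSC Mono",
    "CD4 T Naive", "CD4 T CM", "CD4 T EM", "CD4 T Act", "CD4 Treg",
    "CD8 T Naive", "CD8 T CM", "CD8 T EM", "CD8 T Act", "CD8 T L-",
    "gdT", "NKT", "NK imm", "NK mat",
    "B Fo", "B MZ", "B1a", "B1b", "B GC", "B IgD-", "Plasma", "ILC2",
)

# Planted fold changes relative to Nil: myeloid expansion (monocyte and
# neutrophil subsets, stronger under 4T1) and mild lymphoid contraction.
DEFAULT_EFFECTS: dict[tuple[str, str], float] = {
    ("Mo F+L+", "CT26"): 5.0, ("Mo F+L+", "4T1"): 8.0,
    ("Mo F+L-", "CT26"): 1.2, ("Mo F+L-", "4T1"): 8.0,
    ("N B-6a+", "CT26"): 1.5, ("N B-6a+", "4T1"): 4.0,
    ("MDSC PMN", "CT26"): 2.0, ("MDSC PMN", "4T1"): 6.0,
    ("Mo Ly6Chi", "CT26"): 2.0, ("Mo Ly6Chi", "4T1"): 3.0,
    ("N B+6a+", "CT26"): 1.4, ("N B+6a+", "4T1"): 2.5,
    ("Eos", "4T1"): 0.5,
    ("CD8 T L-", "CT26"): 0.8, ("CD8 T L-", "4T1"): 0.4,
    ("B Fo", "CT26"): 0.9, ("B Fo", "4T1"): 0.6,
    ("CD4 T Naive", "CT26"): 0.9, ("CD4 T Naive", "4T1"): 0.7,
    ("NK mat", "CT26"): 1.3, ("NK mat", "4T1"): 0.7,
}

DEFAULT_MARKERS: tuple[str, ...] = (
    "CD24", "CD44", "CD45RB", "CD62L", "CD66a", "IgD", "CD69", "CD86",
    "PD-L1", "PD-1", "CD115", "Ly6C", "Ly6G", "CD11b", "CD11c", "MHC-II",
    "CD19", "CD3", "NK1.1", "CD8a", "CD4", "CD25", "CD138", "CXCR4",
    "CCR2", "CX3CR1", "CD38", "CD73", "CD357", "CD28",
)

# Planted tumor-specific MedFI shifts per (population, marker, group).
DEFAULT_MARKER_SHIFTS: dict[tuple[str, str, str], float] = {
    ("Mo F+L+", "CD62L", "CT26"): 400.0,
    ("Mo F+L+", "CD62L", "4T1"): 800.0,
    ("CD8 T EM", "CD62L", "4T1"): -600.0,
    ("CD8 T EM", "CD62L", "4T1.2"): -550.0,
    ("N B-6a+", "CD66a", "CT26"): 300.0,
    ("N B-6a+", "CD66a", "4T1"): 500.0,
    ("Mo Ly6Chi", "CD24", "CT26"): 250.0,
    ("Mo Ly6Chi", "CD24", "4T1"): 450.0,
    ("Mo Ly6Chi", "CD24", "4T1.2"): 380.0,
    ("CD8 T EM", "CD44", "CT26"): 200.0,
    ("CD8 T EM", "CD44", "4T1"): 350.0,
    ("CD8 T EM", "CD44", "4T1.2"): 320.0,
    ("N B+6a+", "CD45RB", "4T1"): -300.0,
    ("B Fo", "IgD", "4T1.2"): -500.0,
    ("Mo F+L-", "PD-L1", "4T1"): 420.0,
    # opposite-sign pair: the 4T1 decrease exceeds the CT26 increase, so the
    # scaled change saturates at the -1 floor
    ("B Fo", "CXCR4", "CT26"): 200.0,
    ("B Fo", "CXCR4", "4T1"): -500.0,
}

_ISOTYPE_CLASSES = ("Rat IgG1", "Rat IgG2a", "Rat IgG2b", "Mouse IgG1")


@dataclass
class ScreenConfig:
    """Parameters of the synthetic marker screen.

    MedFI in arbitrary fluorescence units.  ``qc_fail_markers`` get a
    background below the isotype offset, emulating markers whose specific
    signal sits below isotype-control binding and must be excluded by QC.
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    groups: tuple[str, ...] = ("Nil", "CT26", "4T1", "4T1.2")
    populations: tuple[str, ...] | None = None  # None -> cohort populations
    background_range: tuple[float, float] = (200.0, 1500.0)
    fmo_offset: float = 120.0
    isotype_offset: float = 60.0
    noise_sd: float = 10.0
    n_fmo_replicates: int = 2
    shifts: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SHIFTS)
    )
    qc_fail_markers: tuple[str, ...] = ("CD357", "CD28")

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("screen.noise_sd must be non-negative")
        if self.n_fmo_replicates < 1:
            raise ConfigError("screen.n_fmo_replicates must be >= 1")
        lo, hi = self.background_range
        if not (0 <= lo <= hi):
            raise ConfigError("screen.background_range must satisfy 0 <= lo <= hi")


def _default_baselines() -> dict[str, float]:
    # order-of-magnitude cells per ~5 uL of blood: abundant neutrophil/B/T
    # majors down to rare innate subsets, spread log-evenly 3000 -> 20
    levels = np.linspace(np.log(3000.0), np.log(20.0), len(DEFAULT_POPULATIONS))
    return {p: float(v) for p, v in zip(DEFAULT_POPULATIONS, levels)}


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    ``n_per_group`` is animals per group *per batch*; ``missing`` removes
    animals from a group's final batch (default mirrors a cohort of 15/15/14
    animals over 3 batches).  ``effect_matrix`` maps (population, group) to a
    fold change relative to the control group; absent entries are 1.
    ``count_cv`` is the coefficient of variation of the log-normal counts and
    ``batch_sd`` the standard deviation of the per-(batch, population)
    multiplicative log effect.
    """

    group_names: tuple[str, ...] = ("Nil", "CT26", "4T1")
    control_group: str = "Nil"
    n_per_group: int = 5
    n_batches: int = 3
    missing: dict[str, int] = field(default_factory=lambda: {"4T1": 1})
    population_names: tuple[str, ...] = DEFAULT_POPULATIONS
    baseline_log_mean: dict[str, float] = field(default_factory=_default_baselines)
    count_cv: float = 0.4
    effect_matrix: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    batch_sd: float = 0.15
    bead_mean: float = 2000.0
    bead_sd: float = 200.0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.control_group not in self.group_names:
            raise ConfigError(
                f"control_group {self.control_group!r} not in group_names"
            )
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if self.count_cv < 0:
            raise ConfigError("count_cv must be non-negative")
        if self.batch_sd < 0:
            raise ConfigError("batch_sd must be non-negative")
        if self.bead_mean < 1:
            raise ConfigError("bead_mean must be >= 1")
        for (pop, grp), fc in self.effect_matrix.items():
            if fc <= 0:
                raise ConfigError(f"effect_matrix[{(pop, grp)}] must be > 0, got {fc}")
            if grp == self.control_group and fc != 1.0:
                raise ConfigError(
                    f"effect_matrix[{(pop, grp)}]: control-group fold changes must be 1"
                )
            if pop not in self.population_names:
                raise ConfigError(f"effect_matrix population {pop!r} unknown")
            if grp not in self.group_names:
                raise ConfigError(f"effect_matrix group {grp!r} unknown")
        for pop in self.population_names:
            if pop not in self.baseline_log_mean:
                raise ConfigError(f"baseline_log_mean missing population {pop!r}")
        for grp, k in self.missing.items():
            if grp not in self.group_names:
                raise ConfigError(f"missing group {grp!r} unknown")
            if not 0 <= k < self.n_per_group:
                raise ConfigError("missing counts must be in [0, n_per_group)")
        self.screen.validate()

    def effect(self, population: str, group: str) -> float:
        if group == self.control_group:
            return 1.0
        return self.effect_matrix.get((population, group), 1.0)


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``discriminating_populations`` are populations with any non-unit fold
    change, ranked by composite effect size (max over groups of
    ``|ln fold change|``, largest first).  ``marker_shifts`` are the planted
    (population, marker, group) MedFI deltas of the screen.
    """

    discriminating_populations: list[str] = field(default_factory=list)
    effect_sizes: dict[str, float] = field(default_factory=dict)
    marker_shifts: dict[tuple[str, str, str], float] = field(default_factory=dict)


def _ranked_truth(config: SimConfig) -> tuple[list[str], dict[str, float]]:
    sizes: dict[str, float] = {}
    for pop in config.population_names:
        comp = max(
            abs(np.log(config.effect(pop, g))) for g in config.group_names
        )
        if comp > 0:
            sizes[pop] = float(comp)
    ranked = sorted(sizes, key=lambda p: (-sizes[p], p))
    return ranked, sizes


def simulate_cohort(config: SimConfig) -> tuple[CountTable, PlantedTruth]:
    """Draw a raw per-animal count table with planted group and batch effects.

    The count of population ``p`` for an animal of group ``g`` in batch ``b``
    is log-normal with median ``exp(baseline_p) * effect(g, p) *
    batch_factor(b, p)`` and log-scale sigma ``sqrt(ln(1 + cv^2))``, rounded
    to a non-negative integer.  Bead events are a truncated normal draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pops = list(config.population_names)
    sigma = float(np.sqrt(np.log1p(config.count_cv**2)))

    batch_factors = {
        (b, p): float(np.exp(rng.normal(0.0, config.batch_sd))) if config.batch_sd > 0 else 1.0
        for b in range(1, config.n_batches + 1)
        for p in pops
    }

    rows = []
    for batch in range(1, config.n_batches + 1):
        for group in config.group_names:
            n = config.n_per_group
            if batch == config.n_batches:
                n -= config.missing.get(group, 0)
            for i in range(1, n + 1):
                beads = max(1, int(round(rng.normal(config.bead_mean, config.bead_sd))))
                row = {
                    "sample_id": f"{group}-b{batch}-{i:02d}",
                    "group": group,
                    "batch": f"exp{batch}",
                    "beads": beads,
                }
                for pop in pops:
                    median = (
                        np.exp(config.baseline_log_mean[pop])
                        * config.effect(pop, group)
                        * batch_factors[(batch, pop)]
                    )
                    noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                    row[pop] = max(0, int(round(median * np.exp(noise))))
                rows.append(row)

    table = CountTable(pd.DataFrame(rows), stage="raw")
    ranked, sizes = _ranked_truth(config)
    return table, PlantedTruth(discriminating_populations=ranked, effect_sizes=sizes)


def simulate_screen(config: SimConfig) -> tuple[ScreenTable, PlantedTruth]:
    """Draw a synthetic marker screen with planted MedFI shifts.

    Well MedFI-PE = per-(population, marker) background + FMO channel offset
    + planted shift (tumor groups only) + Gaussian noise.  FMO wells measure
    the channel offset alone; isotype wells measure offset + isotype binding.
    """
    config.validate()
    sc = config.screen
    rng = np.random.default_rng(config.seed + 1)
    pops = list(sc.populations or config.population_names)
    lo, hi = sc.background_range

    def noise() -> float:
        return float(rng.normal(0.0, sc.noise_sd)) if sc.noise_sd > 0 else 0.0

    background = {}
    for pop in pops:
        for m in sc.markers:
            if m in sc.qc_fail_markers:
                background[(pop, m)] = float(rng.uniform(0.0, 0.6 * sc.isotype_offset))
            else:
                background[(pop, m)] = float(rng.uniform(lo, hi))

    meta = {
        m: _ISOTYPE_CLASSES[i % len(_ISOTYPE_CLASSES)] for i, m in enumerate(sc.markers)
    }
    rows = []
    for pop in pops:
        for g in sc.groups:
            for m in sc.markers:
                shift = 0.0 if g == "Nil" else sc.shifts.get((pop, m, g), 0.0)
                val = background[(pop, m)] + sc.fmo_offset + shift + noise()
                rows.append((pop, g, m, val, "screen"))
            for _ in range(sc.n_fmo_replicates):
                rows.append((pop, g, "", sc.fmo_offset + noise(), "fmo"))
        for cls in sorted(set(meta.values())):
            rows.append(
                (pop, "", cls, sc.fmo_offset + sc.isotype_offset + noise(), "isotype")
            )

    table = ScreenTable(
        pd.DataFrame(rows, columns=["population", "group", "marker", "value", "entry_type"]),
        marker_meta=meta,
        stage="medfi",
    )
    truth = PlantedTruth(marker_shifts=dict(sc.shifts))
    ranked, sizes = _ranked_truth(config)
    truth.discriminating_populations = ranked
    truth.effect_sizes = sizes
    return table, truth


def dominant_discriminator_config(
    seed: int = 0, dominant: str = "Mo F+L+", n_populations: int = 39
) -> SimConfig:
    """Cohort with one population carrying a dominant planted effect.

    The dominant population changes strongly and distinctly in every tumor
    group (large fold changes, near-disjoint distributions in all pairwise
    comparisons); a handful of other populations carry weak (~1.3-fold)
    changes so the recovery task is non-trivial.
    """
    pops = DEFAULT_POPULATIONS[:n_populations]
    if dominant not in pops:
        raise ConfigError(f"dominant population {dominant!r} not among populations")
    effects: dict[tuple[str, str], float] = {
        (dominant, "CT26"): 4.0,
        (dominant, "4T1"): 16.0,
    }
    weak = [p for p in pops if p != dominant][:6]
    for i, p in enumerate(weak):
        effects[(p, "CT26")] = 1.3 if i % 2 == 0 else 0.8
        effects[(p, "4T1")] = 0.75 if i % 2 == 0 else 1.3
    return SimConfig(
        population_names=pops,
        baseline_log_mean={p: _default_baselines()[p] for p in pops},
        effect_matrix=effects,
        count_cv=0.3,
        seed=seed,
    )


def monocyte_signature_config(seed: int = 0, n_populations: int = 12) -> SimConfig:
    """Cohort whose two monocyte subsets jointly separate all three groups.

    Emulates the signature structure where one monocyte subset expands in
    every tumor-bearing group (distinguishing cancer presence) and a second
    expands only under one tumor type (distinguishing the cancers), each
    with near-zero overlap between the groups it separates.  A few weak
    nuisance effects keep the selection task non-trivial.
    """
    pops = DEFAULT_POPULATIONS[:n_populations]
    effects: dict[tuple[str, str], float] = {
        ("Mo F+L+", "CT26"): 6.0,
        ("Mo F+L+", "4T1"): 6.0,
        ("Mo F+L-", "4T1"): 10.0,
    }
    weak = [p for p in pops if p not in ("Mo F+L+", "Mo F+L-")][:4]
    for i, p in enumerate(weak):
        effects[(p, "CT26")] = 1.25 if i % 2 == 0 else 0.8
        effects[(p, "4T1")] = 0.8 if i % 2 == 0 else 1.25
    return SimConfig(
        population_names=pops,
        baseline_log_mean={p: _default_baselines()[p] for p in pops},
        effect_matrix=effects,
        count_cv=0.3,
        seed=seed,
    )
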
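import numpy as np
import pandas as pd
import pytest

import leukosig as lk


def small_config(seed: int = 0, **overrides) -> lk.SimConfig:
    """A 12-population cohort that keeps simulation-heavy tests fast."""
    pops = lk.simulate.DEFAULT_POPULATIONS[:12]
    base = {p: lk.simulate._default_baselines()[p] for p in pops}
    effects = {
        k: v for k, v in lk.simulate.DEFAULT_EFFECTS.items() if k[0] in pops
    }
    kwargs = dict(
        population_names=pops,
        baseline_log_mean=base,
        effect_matrix=effects,
        seed=seed,
    )
    kwargs.update(overrides)
    return lk.SimConfig(**kwargs)


@pytest.fixture(scope="session")
def cohort():
    """Default small cohort: raw counts plus planted truth."""
    return lk.simulate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def rescaled(cohort):
    raw, _ = cohort
    return lk.normalize_counts(raw, "Nil")


@pytest.fixture(scope="session")
def screen_pair():
    """Synthetic screen (raw) and its config."""
    cfg = small_config(seed=7)
    table, truth = lk.simulate_screen(cfg)
    return table, cfg


@pytest.fixture(scope="session")
def fitted(rescaled):
    """Fitted biomarker results on the small cohort (shared across tests)."""
    return lk.BiomarkerModel(rescaled).fit(k_clusters=5, seed=3)


@pytest.fixture()
def tiny_counts():
    """Hand-written 2-batch raw count table for arithmetic checks."""
    df = pd.DataFrame(
        {
            "sample_id": ["n1", "n2", "t1", "n3", "n4", "t2"],
            "group": ["Nil", "Nil", "CT26", "Nil", "Nil", "CT26"],
            "batch": ["e1", "e1", "e1", "e2", "e2", "e2"],
            "beads": [2000, 2500, 2000, 5000, 4000, 2500],
            "Mo": [200, 250, 400, 500, 360, 500],
            "B": [100, 150, 120, 300, 260, 250],
        }
    )
    return lk.CountTable(df, stage="raw")
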
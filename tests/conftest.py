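import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import shscreen as sh

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_screen_config(**overrides) -> sh.SimScreenConfig:
    """A scaled-down screen that keeps the full design structure."""
    base = dict(
        n_hairpins=600,
        n_genes=200,
        n_neg_controls=60,
        frac_depleted=10 / 600,
        depth=600_000,
        seed=0,
    )
    base.update(overrides)
    return sh.SimScreenConfig(**base)


@pytest.fixture(scope="session")
def small_screen():
    """One small simulated screen shared across read-only tests."""
    return sh.simulate_screen(small_screen_config(seed=42))


@pytest.fixture()
def tiny_annotation():
    return pd.DataFrame(
        {
            "probe_id": ["P1", "P2", "P3", "N1"],
            "target_gene": ["GA", "GA", "GB", ""],
            "is_negative_control": [False, False, False, True],
            "description": ["", "", "", "control"],
        }
    )


def make_sheet(doses=(0.0, 0.4, 1.0), replicates=(1, 2, 3),
               timepoints=("T0", "T1", "T2"), cell_line="LNCaP"):
    """Sample sheet with one specimen per cell; T0 is shared pre-selection.

    Defaults mirror the screen layout: vehicle plus two pooled drug doses.
    """
    rows = []
    for tp in timepoints:
        if tp == "T0":
            for rep in replicates:
                rows.append(
                    dict(sample_id=f"T0_r{rep}", cell_line=cell_line, arm="vehicle",
                         dose=0.0, timepoint="T0", replicate=rep,
                         acquisition_date="2010-01-01", is_preselection=True)
                )
            continue
        for dose in doses:
            arm = "treated" if dose > 0 else "vehicle"
            for rep in replicates:
                rows.append(
                    dict(sample_id=f"{tp}_d{dose}_r{rep}", cell_line=cell_line,
                         arm=arm, dose=dose, timepoint=tp, replicate=rep,
                         acquisition_date="2010-01-10", is_preselection=False)
                )
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_sheet():
    return make_sheet()


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
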
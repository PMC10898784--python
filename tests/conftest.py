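"""Shared fixtures: desk-scale synthetic cohorts and the study-scale recovery runs."""

from __future__ import annotations

import numpy as np
import pytest

from connectoprint import (
    SimConfig,
    build_edge_index,
    fc_pairs_by_condition,
    generate_cohort,
    make_parcellation,
    recovery_summary,
)

#: Seeds of the replicate recovery runs at study scale.
RECOVERY_SEEDS = tuple(range(1, 21))


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """A 40-region, 8+8-subject configuration for fast unit tests."""
    defaults = dict(
        seed=seed,
        n_drug=8,
        n_placebo=8,
        rsn_sizes={"Vis": 6, "SM": 6, "DA": 4, "VA": 4, "LIM": 4, "FPN": 6, "DMN": 10},
        timepoints=128,
        pattern_core_per_hemi=4,
        planted_n=100,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=1))


@pytest.fixture(scope="session")
def small_parc(small_cohort):
    return small_cohort.parcellation


@pytest.fixture(scope="session")
def small_pairs(small_cohort):
    return fc_pairs_by_condition(small_cohort.timeseries)


@pytest.fixture(scope="session")
def small_idx(small_parc):
    return build_edge_index(small_parc)


@pytest.fixture(scope="session")
def tiny_parc():
    """A 14-region parcellation (2 regions per RSN, one per hemisphere)."""
    cfg = SimConfig(
        seed=0,
        n_drug=2,
        n_placebo=2,
        rsn_sizes={r: 2 for r in ("Vis", "SM", "DA", "VA", "LIM", "FPN", "DMN")},
        timepoints=16,
        pattern_core_per_hemi=1,
        planted_n=3,
    )
    return make_parcellation(cfg)


@pytest.fixture(scope="session")
def recovery_runs():
    """Study-scale recovery runs (default generator, 20 replicate seeds).

    Each run generates a fresh 46-subject cohort at N=200, T=256, runs the
    full pipeline, and summarizes the quantities the recovery checks assert.
    Shared session-wide because several acceptance checks read it.
    """
    runs = []
    for seed in RECOVERY_SEEDS:
        cohort = generate_cohort(SimConfig(seed=seed))
        summary = recovery_summary(
            cohort,
            ensemble_size=100,
            seed=seed,
            ensembles=("random", "spin"),
        )
        summary.pop("analysis")  # keep only scalars; the full objects are large
        runs.append(summary)
    return runs


def fraction(runs, predicate) -> float:
    return float(np.mean([bool(predicate(r)) for r in runs]))
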
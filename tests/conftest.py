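"""Shared fixtures: a reference trial design, weight schemes, and a
session-scoped batch of simulated trials reused by the heavier checks."""

import numpy as np
import pytest
from hypothesis import settings

from titecrm import (
    DesignSpec,
    EscalationRules,
    ScenarioSpec,
    WeightSpec,
    simulate_trial,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design() -> DesignSpec:
    """Four-dose radiotherapy-style design: 24-week DLT window, TTL 25%."""
    return DesignSpec(
        skeleton=(0.05, 0.12, 0.22, 0.35),
        ttl=0.25,
        dlt_window=168.0,
        n_max=21,
    )


@pytest.fixture(scope="session")
def closest_design(design) -> DesignSpec:
    """Same design with the closest-to-target MTD definition."""
    import dataclasses

    return dataclasses.replace(design, mtd_rule="closest")


@pytest.fixture(scope="session")
def olaparib_weights() -> WeightSpec:
    """1-year window, first 3 months carrying half the total weight."""
    return WeightSpec.piecewise([(91.0, 0.5), (274.0, 0.5)])


@pytest.fixture(scope="session")
def simulated_batch(closest_design):
    """500 seed-pinned trials under a scenario whose unique dose closest to
    the TTL is dose 2; shared across rule-enforcement and OC checks."""
    scenario = ScenarioSpec(
        true_probs=(0.10, 0.25, 0.45, 0.60),
        n_sims=500,
        master_seed=20260925,
    )
    streams = [
        np.random.Generator(np.random.PCG64(child))
        for child in np.random.SeedSequence(scenario.master_seed).spawn(scenario.n_sims)
    ]
    results = [
        simulate_trial(scenario, closest_design, rng=rng) for rng in streams
    ]
    return scenario, results


def make_snapshots(rng, labels, n, force_weight_one=False):
    """Random valid snapshot sets for property checks."""
    from titecrm import ParticipantSnapshot

    snaps = []
    for j in range(n):
        label = float(labels[rng.integers(0, len(labels))])
        tox = int(rng.random() < 0.3)
        w = 1.0 if (tox or force_weight_one) else float(rng.uniform(0.05, 1.0))
        t = float(rng.uniform(1.0, 168.0))
        snaps.append(
            ParticipantSnapshot(
                participant_id=f"p{j}",
                dose_index=1,
                dose_label=label,
                tox=tox,
                followup=t,
                weight=w,
            )
        )
    return snaps
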
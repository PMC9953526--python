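"""Shared fixtures: synthetic trajectories with planted, recorded truth.

Heavy trajectories are session-scoped so recovery tests and acceptance
checks share one generation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from gagtraj.synthetic import (
    HBondPlant,
    LinkageComponent,
    SyntheticSpec,
    WaterPlant,
    chain_composition,
    generate,
    preset_specs,
)


def recovery_spec(n_frames: int = 10_000, seed: int = 123) -> SyntheticSpec:
    """A dermatan-like tetrasaccharide with round planted rates, used for
    parameter-recovery testing: 60/40 uronic pucker, 0.70 hydrogen-bond
    fractions, 0.25 ion contact rates, a two-component linkage mixture and
    two planted waters."""
    chain = chain_composition("DS", "dp4", "Set1")
    pucker_truth = {
        1: {"4C1": 0.90, "1C4": 0.10},
        2: {"1C4": 0.60, "4C1": 0.40},
        3: {"4C1": 0.97, "1C4": 0.03},
        4: {"1C4": 0.60, "4C1": 0.40},
    }
    comps = [
        LinkageComponent(0.6, -75.0, -110.0),
        LinkageComponent(0.4, -75.0, 60.0),
    ]
    return SyntheticSpec(
        name="recovery dp4",
        chain=chain,
        n_frames=n_frames,
        seed=seed,
        pucker_truth=pucker_truth,
        linkage_truth={k: list(comps) for k in range(3)},
        hbond_truth=[
            HBondPlant(2, "O3", 1, "O7", 0.70),
            HBondPlant(3, "N2", 2, "O2", 0.70),
        ],
        ion_truth={"carboxyl": 0.25, "sulfate": 0.25},
        water_truth=WaterPlant(count=2, fraction=0.5),
        set_label="Set1",
    )


@pytest.fixture(scope="session")
def recovery_run():
    spec = recovery_spec()
    topo, traj, charge_map, truth = generate(spec)
    return spec, topo, traj, charge_map, truth


@pytest.fixture(scope="session")
def dp2_run():
    spec = preset_specs("CS4 dp2 Set1", n_frames=200, seed=7)
    topo, traj, charge_map, truth = generate(spec)
    return spec, topo, traj, charge_map, truth


@pytest.fixture(scope="session")
def dp6_run():
    spec = preset_specs("CS6 dp6 Set1", n_frames=100, seed=3)
    topo, traj, charge_map, truth = generate(spec)
    return spec, topo, traj, charge_map, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
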
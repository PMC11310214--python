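"""Shared fixtures: noise-free scenes and scripted trajectories.

Trajectory fixtures use a 10 ns frame spacing (coarser than the 0.1 ns
production default) so SASA-bearing analyses stay fast; event detection is
spacing-invariant, so nothing tested depends on the stride.
"""

import numpy as np
import pytest

from hydrosense.synthetic import (
    LigandScript,
    ThzSceneSpec,
    TrajectoryScript,
    gen_thz_scene,
    gen_trajectory,
)


@pytest.fixture(scope="session")
def noise_free_scene():
    return gen_thz_scene(ThzSceneSpec(noise_sd=0.0, seed=42))


@pytest.fixture(scope="session")
def mixed_trajectory():
    """One surface ligand (long + short + gapped events) and one corona ligand."""
    script = TrajectoryScript(
        n_frames=300, frame_dt=10.0,
        ligands=[
            LigandScript("dopamine", [
                (100.0, 600.0, "SURFACE"),    # long: one mode-1 event
                (800.0, 1100.0, "SURFACE"),   # 300 ns: below the 400 ns threshold
                (1400.0, 1900.0, "SURFACE"),  # long again
            ]),
            LigandScript("riboflavin", [(300.0, 1800.0, "CORONA")]),
        ],
    )
    system, truth = gen_trajectory(script, seed=11)
    return script, system, truth


@pytest.fixture(scope="session")
def surface_system():
    script = TrajectoryScript(
        n_frames=100, frame_dt=10.0,
        ligands=[LigandScript("dopamine", [(200.0, 700.0, "SURFACE")])],
        n_waters=600,
    )
    return gen_trajectory(script, seed=7)


@pytest.fixture(scope="session")
def corona_system():
    script = TrajectoryScript(
        n_frames=100, frame_dt=10.0,
        ligands=[LigandScript("riboflavin", [(200.0, 700.0, "CORONA")])],
        n_waters=600,
    )
    return gen_trajectory(script, seed=7)
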
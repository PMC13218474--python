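"""Shared fixtures: hand-built micro-topologies and cached synthetic scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from rhpdimer.model import AnalysisConfig, SystemTopology, Trajectory
from rhpdimer.synthetic import ScenarioSpec, generate_dimer_trajectory


def build_topology(
    polymer_atoms,
    water_positions=None,
    box=(50.0, 50.0, 50.0),
    water_sites=1,
):
    """Construct a SystemTopology from explicit per-atom tuples.

    ``polymer_atoms``: list of (chain, resid, code, name, element, backbone).
    ``water_positions`` only sets the water count here; coordinates come from
    the frames the test builds.  Single-site waters unless ``water_sites=3``.
    """
    n_poly = len(polymer_atoms)
    n_wat = 0 if water_positions is None else len(water_positions)
    wnames = ["O"] if water_sites == 1 else ["O", "H1", "H2"]
    welems = ["O"] if water_sites == 1 else ["O", "H", "H"]
    n = n_poly + n_wat * water_sites

    names = np.empty(n, dtype=object)
    elements = np.empty(n, dtype=object)
    chain_ids = np.empty(n, dtype=object)
    resid = np.zeros(n, dtype=np.int64)
    code = np.asarray([""] * n, dtype=object)
    backbone = np.zeros(n, dtype=bool)
    for i, (ch, r, c, nm, el, bb) in enumerate(polymer_atoms):
        chain_ids[i], resid[i], code[i], names[i], elements[i], backbone[i] = (
            ch, r, c, nm, el, bb,
        )
    waters, oxy = [], []
    for w in range(n_wat):
        ids = np.arange(n_poly + w * water_sites, n_poly + (w + 1) * water_sites)
        waters.append(ids)
        oxy.append(int(ids[0]))
        names[ids] = wnames
        elements[ids] = welems
        chain_ids[ids] = "W"
    return SystemTopology(
        atom_names=names,
        elements=elements,
        chain_ids=chain_ids,
        residue_index=resid,
        monomer_code=code,
        is_backbone=backbone,
        waters=waters,
        water_oxygen=np.asarray(oxy, dtype=np.int64),
        ions=np.empty(0, dtype=np.int64),
        box=np.asarray(box, dtype=float),
    )


def build_trajectory(topology, frames, times=None):
    """Stack per-frame (n_atoms, 3) coordinate arrays into a Trajectory."""
    coords = np.asarray(frames, dtype=np.float32)
    if times is None:
        times = np.arange(len(coords), dtype=float)
    return Trajectory(topology, coords, np.asarray(times, dtype=float))


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def assoc_scenario():
    """A 75%-adsorbed scenario with planted truth (shared across tests)."""
    spec = ScenarioSpec.from_fraction(0.75, seed=7)
    traj, truth = generate_dimer_trajectory(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def null_scenario():
    """A never-adsorbed scenario (chains always dissociated)."""
    spec = ScenarioSpec.from_fraction(0.0, seed=3)
    traj, truth = generate_dimer_trajectory(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def small_scenario():
    """A fast low-water scenario for I/O and pipeline tests."""
    spec = ScenarioSpec.from_fraction(0.5, seed=11, n_frames=40, n_waters=250)
    traj, truth = generate_dimer_trajectory(spec)
    return spec, traj, truth
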
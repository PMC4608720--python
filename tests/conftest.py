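"""Shared fixtures: one coarse synthetic scaffold and a small state panel,
built once per session so individual tests stay fast."""

import numpy as np
import pytest

from kinastate.io import Topology, default_element_table
from kinastate.synthetic import (
    GeneratorConfig,
    build_topology,
    default_profiles,
    simulate_panel,
)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(n_frames=400, seed=123)


@pytest.fixture(scope="session")
def scaffold(gen_config):
    top, roles, ref = build_topology(gen_config)
    return top, roles, ref


@pytest.fixture(scope="session")
def small_panel(gen_config):
    return simulate_panel(gen_config)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


def make_topology(n_atoms=4, resids=None, names=None, element="C"):
    """Minimal hand-built topology for unit fixtures."""
    table = default_element_table()
    resids = np.arange(n_atoms) + 1 if resids is None else np.asarray(resids)
    names = np.asarray(["CA"] * n_atoms if names is None else names, dtype=object)
    return Topology(
        names=names,
        resnames=np.asarray(["ALA"] * n_atoms, dtype=object),
        resids=np.asarray(resids, dtype=np.int64),
        elements=np.asarray([element] * n_atoms, dtype=object),
        masses=np.full(n_atoms, table["masses"][element]),
        vdw_radii=np.full(n_atoms, table["radii"][element]),
    )


@pytest.fixture
def tiny_topology():
    return make_topology(3, resids=[479, 480, 481])
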
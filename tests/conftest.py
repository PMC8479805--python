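import numpy as np
import pytest

from tunnelprof import fixtures, structio
from tunnelprof.structio import Atom, TypedMolecule, assign_sybyl_types


def build_molecule(elements, positions, bonds):
    """Helper: TypedMolecule from flat element/position/bond lists."""
    atoms = [Atom(i + 1, f"{e}{i + 1}", e, "LIG", 1, "L",
                  np.asarray(p, float), True)
             for i, (e, p) in enumerate(zip(elements, positions))]
    return TypedMolecule(atoms=atoms, bonds=[tuple(b) for b in bonds])


@pytest.fixture(scope="session")
def methane():
    d = 1.09 / np.sqrt(3)
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) * d
    els = ["C"] + ["H"] * 4
    pos = [np.zeros(3)] + list(dirs)
    bonds = [(0, i, 1) for i in range(1, 5)]
    return assign_sybyl_types(build_molecule(els, pos, bonds))


@pytest.fixture(scope="session")
def ethane():
    pos = [(0.0, 0, 0), (1.53, 0, 0)]
    els = ["C", "C"]
    bonds = [(0, 1, 1)]
    for i, x in enumerate((0.0, 1.53)):
        s = -1 if i == 0 else 1
        for k in range(3):
            ang = 2 * np.pi * k / 3
            pos.append((x + s * 0.4, 0.9 * np.cos(ang), 0.9 * np.sin(ang)))
            els.append("H")
            bonds.append((i, len(pos) - 1, 1))
    return assign_sybyl_types(build_molecule(els, pos, bonds))


@pytest.fixture(scope="session")
def benzene():
    R = 1.39 / (2 * np.sin(np.pi / 6))
    pos, els, bonds = [], [], []
    for k in range(6):
        ang = 2 * np.pi * k / 6
        pos.append((R * np.cos(ang), R * np.sin(ang), 0.0))
        els.append("C")
        bonds.append((k, (k + 1) % 6, 1))
    for k in range(6):
        ang = 2 * np.pi * k / 6
        pos.append(((R + 1.09) * np.cos(ang), (R + 1.09) * np.sin(ang), 0.0))
        els.append("H")
        bonds.append((k, 6 + k, 1))
    return assign_sybyl_types(build_molecule(els, pos, bonds))


@pytest.fixture(scope="session")
def straight_channel():
    spec = fixtures.ChannelSpec(shape="straight", centerline_length=20.0,
                                base_radius=3.0)
    return fixtures.make_channel(spec)


@pytest.fixture(scope="session")
def pinched_channel():
    spec = fixtures.ChannelSpec(shape="straight", centerline_length=20.0,
                                base_radius=3.0, bottleneck=(10.0, 1.2))
    return fixtures.make_channel(spec)


@pytest.fixture(scope="session")
def l_channel():
    spec = fixtures.ChannelSpec(shape="L", centerline_length=20.0,
                                base_radius=3.0)
    return fixtures.make_channel(spec)


@pytest.fixture(scope="session")
def semicircle_channel():
    spec = fixtures.ChannelSpec(shape="semicircle", centerline_length=20.0,
                                base_radius=3.0)
    return fixtures.make_channel(spec)


@pytest.fixture(scope="session")
def planted_ensemble():
    """Two internally distinct conformations x 10 jittered snapshots each."""
    base, _ = fixtures.make_channel(fixtures.ChannelSpec(
        shape="straight", centerline_length=10.0, base_radius=2.0))
    rng = np.random.default_rng(42)
    deform = rng.normal(0.0, 1.0, size=base.coords[0].shape)
    conf_b = structio.StructureEnsemble(base.atoms, base.coords[0] + deform)
    traj_a = fixtures.make_trajectory(base, 10, 0.1, seed=1)
    traj_b = fixtures.make_trajectory(conf_b, 10, 0.1, seed=2)
    both = structio.StructureEnsemble(
        base.atoms, np.concatenate([traj_a.coords, traj_b.coords]))
    labels = np.array([0] * 10 + [1] * 10)
    return both, labels
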
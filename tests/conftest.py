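import numpy as np
import pytest

from emassemble.densmap import GaussianParams, simulate_map
from emassemble.structures import Assembly, CoarseModel, RigidPose
from emassemble.synthetic import RingSpec, ToySpec, make_toy_assembly


@pytest.fixture(scope="session")
def toy_ring_spec():
    """Single C7 ring, small bead count: fast fixtures for unit tests."""
    return ToySpec(rings=(RingSpec(count=7, radius=28.0, z=0.0),),
                   beads_per_subunit=20, seed=0)


@pytest.fixture(scope="session")
def toy_ring(toy_ring_spec):
    assembly, subunit = make_toy_assembly(toy_ring_spec)
    return assembly, subunit


@pytest.fixture(scope="session")
def toy_map40(toy_ring):
    assembly, _ = toy_ring
    return simulate_map(assembly, 40.0, voxel_size=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tetra_model():
    """Small 4-bead asymmetric model with distinct weights."""
    return CoarseModel(
        bead_positions=np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0],
                                 [0.0, 4.0, 0.0], [0.0, 0.0, 5.0]]),
        bead_weights=np.array([1.0, 2.0, 3.0, 4.0]),
        bead_kinds=np.array(["BB", "BB", "SC", "SC"]),
        residue_index=np.array([1, 1, 2, 2]),
        name="tetra",
    )


def fd_force_check(energy_fn, coords, forces, rng, n_checks=20, h=1e-5,
                   rel_tol=1e-4):
    """Central finite-difference check of analytic forces at random DOFs.

    ``energy_fn(coords) -> energy``; ``forces`` is the analytic force array
    matching ``coords``.  Returns the worst relative error observed.
    """
    worst = 0.0
    for _ in range(n_checks):
        b = rng.integers(len(coords))
        d = rng.integers(3)
        cp = coords.copy()
        cp[b, d] += h
        cm = coords.copy()
        cm[b, d] -= h
        fd = -(energy_fn(cp) - energy_fn(cm)) / (2 * h)
        scale = max(abs(fd), abs(forces[b, d]))
        if scale < 1e-9:
            continue
        worst = max(worst, abs(fd - forces[b, d]) / scale)
    assert worst < rel_tol, f"finite-difference mismatch: {worst:.2e}"
    return worst
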
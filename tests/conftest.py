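import numpy as np
import pytest

from vibrobody import (
    Coupling,
    FrequencyGrid,
    ModelTopology,
    ParameterSet,
    SegmentSpec,
    SyntheticSpec,
    default_grid,
    female_10dof_topology,
    female_reference_parameters,
    generate_targets,
)


@pytest.fixture(scope="session")
def female_topology():
    return female_10dof_topology()


@pytest.fixture(scope="session")
def female_params():
    return female_reference_parameters()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def noiseless_targets(female_topology, female_params, grid):
    targets, _ = generate_targets(
        SyntheticSpec(true_params=female_params, grid=grid, noise_cv=0.0, seed=0),
        female_topology,
    )
    return targets


def single_dof_topology(m: float = 1.0, k: float = 1.0, c: float = 0.0) -> ModelTopology:
    """One mass grounded to the seat: the simplest closed-form testbed."""
    return ModelTopology(
        "one-dof",
        [SegmentSpec(1, "mass", m)],
        [Coupling(1, 1, None, k, c)],
        total_mass=m,
    )


def two_dof_chain(
    m1: float = 1.0, m2: float = 1.0, k1: float = 1.0, k2: float = 1.0,
    c1: float = 0.0, c2: float = 0.0,
) -> ModelTopology:
    """Chain head(1)–segment(2)–seat; closed-form eigenvalues are known."""
    return ModelTopology(
        "two-dof",
        [SegmentSpec(1, "head", m1), SegmentSpec(2, "torso", m2)],
        [Coupling(1, 1, 2, k1, c1), Coupling(2, 2, None, k2, c2)],
        total_mass=m1 + m2,
    )


def random_tree_topology(rng: np.random.Generator, n: int | None = None) -> ModelTopology:
    """Random connected chain/branch model with a random seat attachment.

    Segments form a random spanning tree (each node attaches to a random
    earlier node), and one random segment couples to the seat — the
    generic shape of a lumped-parameter body model.
    """
    if n is None:
        n = int(rng.integers(2, 9))
    segments = [SegmentSpec(i, f"seg{i}", float(rng.uniform(0.5, 20.0))) for i in range(1, n + 1)]
    couplings = []
    cid = 1
    for i in range(2, n + 1):
        parent = int(rng.integers(1, i))
        couplings.append(
            Coupling(cid, i, parent, float(rng.uniform(1e2, 3e5)), float(rng.uniform(0, 4e3)))
        )
        cid += 1
    base = int(rng.integers(1, n + 1))
    couplings.append(
        Coupling(cid, base, None, float(rng.uniform(1e2, 3e5)), float(rng.uniform(0, 4e3)))
    )
    total = sum(s.mass for s in segments)
    return ModelTopology(f"random-{n}dof", segments, couplings, total_mass=total)
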
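import numpy as np
import pytest

from cambind.model_io import Trajectory
from cambind.synthetic import (EnsembleScript, HelixSpec, MELITTIN_SEQUENCE,
                               ScaffoldSpec, build_complex, build_ensemble,
                               build_helix, build_scaffold)


@pytest.fixture(scope="session")
def melittin_helix():
    return build_helix(HelixSpec(MELITTIN_SEQUENCE))


@pytest.fixture(scope="session")
def kinked_helix():
    return build_helix(HelixSpec(MELITTIN_SEQUENCE, kink_residue=14,
                                 kink_angle=150.0))


@pytest.fixture(scope="session")
def scaffold():
    return build_scaffold(ScaffoldSpec(ion_dihedral=117.5))


@pytest.fixture()
def complex_fixture():
    """(frame, pairing, pockets) with Leu6 / Leu16 in anchoring position."""
    return build_complex()


@pytest.fixture()
def small_ensemble(complex_fixture):
    frame, pairing, pockets = complex_fixture
    script = EnsembleScript(n_frames=10, noise_sigma=0.05, seed=11,
                            anchor_schedule={("N", 6): 0.7})
    return build_ensemble(frame, script, pairing, pockets), pairing, pockets


@pytest.fixture()
def conformer_bundles():
    """10 frames in two conformational bundles (6 straight + 4 kinked)."""
    straight = build_helix(HelixSpec(MELITTIN_SEQUENCE))
    kinked = build_helix(HelixSpec(MELITTIN_SEQUENCE, kink_residue=14,
                                   kink_angle=120.0))
    rng = np.random.default_rng(7)
    frames = []
    for base, count in ((straight, 6), (kinked, 4)):
        for _ in range(count):
            f = base.copy()
            for a in f.atoms:
                a.coords = a.coords + rng.normal(0.0, 0.02, 3)
            f.model_index = len(frames) + 1
            frames.append(f)
    return Trajectory(frames)
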
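import warnings

import numpy as np
import pytest

from corkscrew.phantom import (PhantomSpec, VesselInstance, make_curve,
                               straight_vessel)


@pytest.fixture(autouse=True)
def _silence_subvoxel_warning():
    # default phantom vessels are deliberately sub-voxel in z (blooming
    # compensates); the warning contract is tested explicitly once
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*sub-voxel.*")
        yield


@pytest.fixture
def helix_curve():
    """Dense analytic helix: r=0.15 mm, pitch=0.4 mm, 5 turns."""
    return make_curve("helix", {"radius_mm": 0.15, "pitch_mm": 0.4,
                                "n_turns": 5, "n_samples": 2000})


@pytest.fixture
def t3_helix_spec():
    """Noise-free 5-turn corkscrew phantom on the anisotropic grid."""
    helix = make_curve("helix", {
        "radius_mm": 0.15, "pitch_mm": 0.5, "n_turns": 5,
        "axis": (0.0, 1.0, 0.0), "origin": (4.0, 2.75, 2.5)})
    vessel = VesselInstance(curve=helix, radius_mm=0.1, vclass="artery",
                            truth_tortuous=True)
    return PhantomSpec(fov_mm=(8.0, 8.0, 5.0), spacing_mm=(0.25, 0.25, 1.0),
                       vessels=[vessel], seed=0, noise_sigma=0.0)


@pytest.fixture
def two_vessel_spec():
    """Noise-free scene with one artery and one vein, well separated."""
    fov, sp = (10.0, 8.0, 5.0), (0.25, 0.25, 1.0)
    return PhantomSpec(
        fov_mm=fov, spacing_mm=sp, seed=0, noise_sigma=0.0,
        vessels=[straight_vessel(3.0, 2.5, fov, sp, vclass="artery"),
                 straight_vessel(7.0, 2.5, fov, sp, vclass="vein")])


def semicircle(radius=1.0, n=2000):
    """Dense planar semicircular arc of the given radius (mm)."""
    theta = np.linspace(0.0, np.pi, n)
    return np.column_stack([radius * np.cos(theta),
                            radius * np.sin(theta),
                            np.zeros(n)])
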
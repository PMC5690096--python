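import numpy as np
import pytest

from mrsimqa import synthetic as syn


@pytest.fixture(scope="session")
def cubic_model():
    """Radial cubic distortion reaching 2 mm at 150 mm from isocenter."""
    return syn.DistortionModel.cubic(2.0, 150.0)


@pytest.fixture(scope="session")
def small_grid_pair(cubic_model):
    """Reduced-extent capsule grid pair (fast) with ground truth."""
    lat = syn.LatticeSpec(extent=200.0, voxel_size=2.0,
                          fov_semi_axes=(110.0, 110.0, 110.0))
    ref, meas, truth = syn.gen_grid_phantom_pair(lat, cubic_model)
    return lat, ref, meas, truth


@pytest.fixture(scope="session")
def phase_pair_09ppm():
    """Dual-echo phase pair of a parabolic field with 0.9 ppm sphere RMS."""
    field = syn.ParabolicPPMField.from_sphere_rms(0.9, radius=155.0)
    p1, p2, truth = syn.gen_phase_pair(field)
    return field, p1, p2, truth


@pytest.fixture(scope="session")
def multiecho_phantom():
    """Noiseless water/fat/bone/air phantom at the triple-echo TEs."""
    pairs, truth = syn.gen_multiecho_phantom(tes_ms=[0.144, 2.44, 4.74])
    return pairs, truth


@pytest.fixture(scope="session")
def breathing_3s():
    return syn.gen_waveform(period=3.0, duration=240.0, dt=0.02)
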
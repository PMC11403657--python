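import numpy as np
import pytest

from memcurv import ProfileRecipe, StressProfile, make_profile_ensemble


@pytest.fixture
def symmetric_grid():
    """Uniform grid on [-8, 8] nm, 0.01 nm spacing, symmetric about 0."""
    return np.arange(-8.0, 8.0 + 1e-12, 0.01)


@pytest.fixture
def gaussian_odd_profile(symmetric_grid):
    """s(z) = A*z*exp(-z^2/(2w^2)) with A = 1 bar, w = 1 nm.

    Closed-form first moment: integral z*s dz = sqrt(2*pi)*A*w^3.
    """
    z = symmetric_grid
    s = z * np.exp(-(z**2) / 2.0)
    return StressProfile(z=z, s=s, exterior_at_positive_z=True, centered=True)


@pytest.fixture
def noiseless_ensemble():
    recipe = ProfileRecipe(planted_first_moment=-3.0, spacing=0.02, n_frames=1)
    frames, truth = make_profile_ensemble(recipe)
    return frames, truth
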
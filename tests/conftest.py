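import numpy as np
import pytest

from gingrec.curve import curvature_profile
from gingrec.synthetic import ProfileSpec, generate_profile


@pytest.fixture(scope="session")
def default_profile():
    """Noise-free default synthetic profile with ground truth."""
    return generate_profile(ProfileSpec())


@pytest.fixture(scope="session")
def default_curvature(default_profile):
    """Spline curvature profile of the default synthetic section."""
    return curvature_profile(default_profile.curve.points, site_id=default_profile.site_id)


def circle_points(radius, theta_start, theta_end, n, center=(0.0, 0.0)):
    """Points on a circular arc; theta decreasing gives the convex orientation
    (material on the right of the direction of travel)."""
    theta = np.linspace(theta_start, theta_end, n)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
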
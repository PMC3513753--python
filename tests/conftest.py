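"""Shared fixtures: small analytic phantoms built at test time."""

import numpy as np
import pytest

from vesseltrace.synthetic import (
    ArcSpec,
    GroundTruth,
    LesionSpec,
    VesselPhantom,
    build_phantom,
    chain_centerline,
    radius_profile,
    render_image,
)
from vesseltrace.vesselness import HessianField


@pytest.fixture(scope="session")
def straight_phantom():
    """Noiseless straight vessel, half-width 4, length 150 px."""
    ph = VesselPhantom(arcs=(ArcSpec(0.0, 150.0),), base_half_width=4.0)
    return build_phantom(ph)


@pytest.fixture(scope="session")
def straight_field(straight_phantom):
    img, _ = straight_phantom
    return HessianField(img)


@pytest.fixture(scope="session")
def stenosed_phantom():
    """Straight vessel with a 95% stenosis at mid-length."""
    ph = VesselPhantom(
        arcs=(ArcSpec(0.0, 300.0),),
        base_half_width=5.0,
        lesions=(LesionSpec(150.0, 95.0, 40.0),),
    )
    return build_phantom(ph)


def render_tree(ground_truths, contrast=100.0, background=200.0, pad=8.0):
    """Render several vessels into one image (darkest structure wins)."""
    pts = np.concatenate([g.points for g in ground_truths])
    margin = max(float(np.max(g.radii)) for g in ground_truths) + pad
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = (int(np.ceil(hi[1] - lo[1])) + 1, int(np.ceil(hi[0] - lo[0])) + 1)
    shifted = [
        GroundTruth(g.points - lo, g.tangents, g.radii) for g in ground_truths
    ]
    img = np.full(shape, background)
    for g in shifted:
        img = np.minimum(img, render_image(g, contrast, background, shape))
    return img, shifted


def straight_gt(length, half_width, t0=(1.0, 0.0), r0=(0.0, 0.0)):
    pts, tans = chain_centerline((ArcSpec(0.0, length),), r0=r0, t0=np.asarray(t0) / np.linalg.norm(t0))
    radii = radius_profile(length, half_width, 0.0)
    n = min(len(pts), len(radii))
    return GroundTruth(pts[:n], tans[:n], radii[:n])


@pytest.fixture(scope="session")
def y_phantom():
    """A main vessel with one branch leaving at 45 degrees."""
    main = straight_gt(220.0, 4.0)
    ang = np.radians(45.0)
    branch = straight_gt(110.0, 3.0, t0=(np.cos(ang), np.sin(ang)), r0=(110.0, 0.0))
    img, gts = render_tree([main, branch], pad=20.0)
    return img, gts
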
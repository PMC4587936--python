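import numpy as np
import pytest

import vortexflow as vf
from vortexflow.phantom import build_phantom_field, canonical_spec


def make_rigid_rotation(omega=5.0, n=9, spacing=1.0, nt=1):
    """Rigid-body rotation about +z: v = (-w y, w x, 0); curl = (0, 0, 2w)."""
    xs = spacing * (np.arange(n) - (n - 1) / 2)
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    zero = np.zeros_like(X)
    rep = lambda a: np.repeat(a[None], nt, axis=0)
    return vf.VelocityField4D(rep(-omega * Y), rep(omega * X), rep(zero),
                              spacing=spacing, origin=(xs[0],) * 3)


def make_uniform(c=(7.0, -3.0, 2.0), n=9, spacing=1.0):
    shape = (1, n, n, n)
    return vf.VelocityField4D(np.full(shape, c[0]), np.full(shape, c[1]),
                              np.full(shape, c[2]), spacing=spacing)


def make_shear(k=3.0, n=9, spacing=1.0):
    """Planar shear v = (k y, 0, 0); curl = (0, 0, -k)."""
    xs = spacing * (np.arange(n) - (n - 1) / 2)
    X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
    zero = np.zeros_like(X)
    return vf.VelocityField4D((k * Y)[None], zero[None], zero[None],
                              spacing=spacing, origin=(xs[0],) * 3)


@pytest.fixture(scope="session")
def canonical_field_1mm():
    """Canonical phantom lattice at 1 mm, single phase."""
    return build_phantom_field(canonical_spec(spacing=1.0))


@pytest.fixture(scope="session")
def canonical_measurement_1mm():
    """Full pipeline run (vorticity, seeding, tracking) at 1 mm."""
    from vortexflow.validate import measure_phantom

    return measure_phantom(1.0)
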
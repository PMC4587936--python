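"""The lambda2 vortex criterion.

Decompose the velocity Jacobian J (J[a][b] = dv_a/dx_b, s^-1) into its
symmetric strain-rate part S = (J + J^T)/2 and antisymmetric rotation part
W = (J - J^T)/2.  The matrix M = S^2 + W^2 is real symmetric; a point lies
inside a vortex when two of M's eigenvalues are negative, i.e. when the
middle eigenvalue lambda2 < 0 (units s^-2).

Two evaluation routes share one eigen-solver:

* on the lattice, J comes from a finite-difference scheme (``central2`` or
  ``central4``) and lambda2 is computed voxelwise;
* at arbitrary world points, J is the analytic derivative of the dynamic-
  degree spatial interpolant of the velocity components - this is what the
  core-tracking corrector minimises, keeping it consistent with sub-voxel
  structure instead of re-interpolating the lambda2 lattice.

The 3x3 symmetric eigenvalues are evaluated with the closed-form
trigonometric solution, vectorised over millions of voxels.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .fields import ScalarField3, VelocityField4D
from .vorticity import _central2_partial, _central4_partial, _erode, _footprint_cross

__all__ = [
    "Lambda2Value",
    "velocity_jacobian",
    "jacobian_lattice",
    "lambda2_at",
    "lambda2_field",
    "lambda2_at_points",
    "eigvalsh3",
]

_PARTIALS = {"central2": (_central2_partial, 1), "central4": (_central4_partial, 2)}


class Lambda2Value(NamedTuple):
    """Sorted eigenvalues of S^2 + W^2; ``l2`` is the exported scalar."""

    l1: float
    l2: float
    l3: float


def eigvalsh3(M: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of symmetric 3x3 matrices, shape (..., 3, 3) -> (..., 3).

    Closed-form trigonometric solution (deterministic and far faster than a
    LAPACK round trip on multi-million-voxel batches).  Non-finite input rows
    yield NaN eigenvalues.
    """
    M = np.asarray(M, dtype=np.float64)
    a, b, c = M[..., 0, 0], M[..., 1, 1], M[..., 2, 2]
    d, e, f = M[..., 0, 1], M[..., 0, 2], M[..., 1, 2]
    q = (a + b + c) / 3.0
    p2 = ((a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * (d * d + e * e + f * f)) / 6.0
    p = np.sqrt(p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_, b_, c_ = (a - q) / p, (b - q) / p, (c - q) / p
        d_, e_, f_ = d / p, e / p, f / p
        detB = (a_ * (b_ * c_ - f_ * f_) - d_ * (d_ * c_ - f_ * e_)
                + e_ * (d_ * f_ - b_ * e_))
        r = np.clip(detB / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    big = q + 2.0 * p * np.cos(phi)
    small = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    mid = 3.0 * q - big - small
    out = np.stack([small, mid, big], axis=-1)
    # degenerate (p ~ 0): all eigenvalues equal the mean
    degen = ~(p > 0)
    if np.any(degen):
        out[degen] = q[degen][..., None]
    nonfinite = ~np.isfinite(M).all(axis=(-2, -1))
    if np.any(nonfinite):
        out[nonfinite] = np.nan
    return out


def _lambda2_from_jacobian(J: np.ndarray) -> np.ndarray:
    """Eigenvalues (ascending) of S^2 + W^2 for Jacobians of shape (..., 3, 3)."""
    Jt = np.swapaxes(J, -1, -2)
    S = 0.5 * (J + Jt)
    W = 0.5 * (J - Jt)
    M = np.einsum("...ij,...jk->...ik", S, S) + np.einsum("...ij,...jk->...ik", W, W)
    M = 0.5 * (M + np.swapaxes(M, -1, -2))  # symmetric by construction; enforce exactly
    return eigvalsh3(M)


def lambda2_at(J: np.ndarray) -> Lambda2Value:
    """All three sorted eigenvalues of S^2 + W^2 for a single 3x3 Jacobian."""
    J = np.asarray(J, dtype=np.float64)
    if J.shape != (3, 3):
        raise ValueError("expected a single 3x3 Jacobian")
    if not np.isfinite(J).all():
        raise ValueError("non-finite Jacobian")
    return Lambda2Value(*_lambda2_from_jacobian(J))


def jacobian_lattice(field: VelocityField4D, t: int, scheme: str = "central2"):
    """Velocity Jacobian at every voxel: (nx, ny, nz, 3, 3) plus validity."""
    try:
        partial, radius = _PARTIALS[scheme]
    except KeyError:
        raise ValueError(
            f"Jacobian scheme must be one of {sorted(_PARTIALS)}, got {scheme!r}"
        ) from None
    comps = field.frame(t)
    h = field.spacing
    J = np.empty(field.spatial_shape + (3, 3))
    for a, v in enumerate(comps):
        for b in range(3):
            J[..., a, b] = partial(v, b, h[b])
    valid = _erode(field.mask_at(t), _footprint_cross(radius))
    J[~valid] = np.nan
    return J, valid


def velocity_jacobian(field: VelocityField4D, t: int, p=None, voxel=None,
                      scheme: str = "central2") -> np.ndarray:
    """Velocity Jacobian at a voxel (finite differences) or a world point
    (analytic derivative of the interpolant)."""
    if (p is None) == (voxel is None):
        raise ValueError("pass exactly one of p (world mm) or voxel (index triple)")
    if voxel is not None:
        J, valid = jacobian_lattice(field, t, scheme)
        voxel = tuple(int(i) for i in voxel)
        if not valid[voxel]:
            raise ValueError(f"stencil invalid at voxel {voxel}")
        return J[voxel]
    J, degree = field.sampler(t).jacobian(p, with_degree=True)
    if degree < 1:
        raise ValueError("no differentiable interpolant at this point")
    return J


def lambda2_field(field: VelocityField4D, t: int, scheme: str = "central2") -> ScalarField3:
    """lambda2 at every valid voxel (NaN elsewhere), unit s^-2."""
    J, valid = jacobian_lattice(field, t, scheme)
    lam = _lambda2_from_jacobian(J)[..., 1]
    lam[~valid] = np.nan
    return ScalarField3(lam, field.spacing, field.origin, unit="1/s^2", valid=valid)


def lambda2_at_points(sampler, pts) -> np.ndarray:
    """lambda2 at world points from a velocity ``LatticeSampler``.

    Points where the interpolant is not differentiable (degree < 1, e.g.
    outside the grid or mask) come back NaN.
    """
    J, degree = sampler.jacobian(pts, with_degree=True)
    lam = _lambda2_from_jacobian(J)[..., 1]
    return np.where(degree >= 1, lam, np.nan)
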
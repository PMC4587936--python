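"""Spatial and temporal interpolation of velocity lattices.

Spatial interpolation is "cubic of dynamic degree": at each query point the
degree adapts to how much of the local neighbourhood is valid (inside the
lumen mask and the grid):

* full 4x4x4 window valid  -> tensor-product cubic Lagrange (exact for
  tricubic polynomials, analytic derivatives),
* inner 2x2x2 cell valid   -> trilinear,
* otherwise                -> value of the nearest valid voxel in the window,
* no valid voxel at all    -> NaN (degree -1).

The degree actually used is reported per point.  The same machinery serves
velocities, vorticity lattices and any other per-voxel scalar set, and it is
the differentiable interpolant whose analytic Jacobian drives sub-voxel
vorticity and lambda2 evaluation during core tracking.

Temporal refinement is a per-voxel periodic cubic spline over the cardiac
cycle (retrospectively gated data is cyclic), exact at the original phases.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .fields import VelocityField4D

__all__ = ["LatticeSampler", "sample_velocity", "interpolate_time"]

_CHUNK = 32768


def _cubic_weights(s: np.ndarray) -> np.ndarray:
    """Cubic Lagrange weights for nodes at offsets (-1, 0, 1, 2), s in [0, 1]."""
    w = np.empty(s.shape + (4,))
    w[..., 0] = -s * (s - 1.0) * (s - 2.0) / 6.0
    w[..., 1] = (s + 1.0) * (s - 1.0) * (s - 2.0) / 2.0
    w[..., 2] = -(s + 1.0) * s * (s - 2.0) / 2.0
    w[..., 3] = (s + 1.0) * s * (s - 1.0) / 6.0
    return w


def _cubic_dweights(s: np.ndarray) -> np.ndarray:
    """d/ds of the cubic Lagrange weights."""
    w = np.empty(s.shape + (4,))
    w[..., 0] = -(3.0 * s * s - 6.0 * s + 2.0) / 6.0
    w[..., 1] = (3.0 * s * s - 4.0 * s - 1.0) / 2.0
    w[..., 2] = -(3.0 * s * s - 2.0 * s - 2.0) / 2.0
    w[..., 3] = (3.0 * s * s - 1.0) / 6.0
    return w


class LatticeSampler:
    """Vectorised dynamic-degree interpolant over one or more scalar lattices.

    Parameters
    ----------
    components : sequence of (nx, ny, nz) arrays sharing one grid
    spacing, origin : grid geometry in mm
    valid : optional boolean lattice; non-finite lattice values are always
        treated as invalid
    out_of_bounds : 'raise' or 'nan' for query points outside the grid box
    """

    def __init__(self, components, spacing, origin=(0.0, 0.0, 0.0),
                 valid=None, out_of_bounds="raise"):
        self.comps = [np.ascontiguousarray(np.asarray(c, dtype=np.float64)) for c in components]
        self.shape = self.comps[0].shape
        if any(c.shape != self.shape for c in self.comps) or len(self.shape) != 3:
            raise ValueError("all component lattices must share one 3D shape")
        self.spacing = np.asarray(np.broadcast_to(spacing, (3,)), dtype=np.float64)
        self.origin = np.asarray(np.broadcast_to(origin, (3,)), dtype=np.float64)
        finite = np.ones(self.shape, dtype=bool)
        for c in self.comps:
            finite &= np.isfinite(c)
        self.valid = finite if valid is None else (np.asarray(valid, dtype=bool) & finite)
        if not self.valid.all():
            # invalid voxels only ever receive zero weight, but 0 * NaN would
            # poison the tensor contraction - store them zero-filled
            self.comps = [np.where(self.valid, c, 0.0) for c in self.comps]
        if out_of_bounds not in ("raise", "nan"):
            raise ValueError("out_of_bounds must be 'raise' or 'nan'")
        self.out_of_bounds = out_of_bounds

    # -- internals ----------------------------------------------------------

    def _window(self, pts):
        """Gather the 4^3 neighbourhood around each point.

        Returns (vals, Vw, s, inside) where vals is a list of (N,4,4,4)
        per-component windows, Vw the matching validity, s the fractional
        coordinates and inside the in-box flags.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        u = (pts - self.origin) / self.spacing
        # snap to exact nodes so voxel centres reproduce stored values exactly
        u_round = np.rint(u)
        u = np.where(np.abs(u - u_round) < 1e-9, u_round, u)
        n = np.array(self.shape)
        inside = np.all((u >= 0) & (u <= n - 1), axis=1) & np.all(np.isfinite(u), axis=1)
        uc = np.clip(np.nan_to_num(u, nan=0.0), 0, n - 1)
        i1 = np.minimum(np.floor(uc).astype(np.int64), n - 2)
        s = uc - i1
        idx, inb = [], []
        for a in range(3):
            ia = i1[:, a, None] + np.arange(-1, 3)
            inb.append((ia >= 0) & (ia < n[a]))
            idx.append(np.clip(ia, 0, n[a] - 1))
        Vw = (self.valid[idx[0][:, :, None, None], idx[1][:, None, :, None],
                         idx[2][:, None, None, :]]
              & inb[0][:, :, None, None] & inb[1][:, None, :, None]
              & inb[2][:, None, None, :])
        vals = [c[idx[0][:, :, None, None], idx[1][:, None, :, None],
                  idx[2][:, None, None, :]] for c in self.comps]
        return vals, Vw, s, inside, idx

    def _axis_weights(self, Vw, s, inside, idx, derivative=False):
        """Per-axis weight vectors implementing the degree cascade.

        Returns (wx, wy, wz [, dwx, dwy, dwz], degree).  Nearest-neighbour
        rows get one-hot weights (and zero derivative weights).
        """
        npts = s.shape[0]
        tri = Vw.all(axis=(1, 2, 3)) & inside
        lin = Vw[:, 1:3, 1:3, 1:3].all(axis=(1, 2, 3)) & inside
        any_valid = Vw.any(axis=(1, 2, 3)) & inside
        degree = np.full(npts, -1, dtype=np.int8)
        degree[any_valid] = 0
        degree[lin] = 1
        degree[tri] = 3
        ws = [_cubic_weights(s[:, a]) for a in range(3)]
        dws = [_cubic_dweights(s[:, a]) for a in range(3)] if derivative else None
        # degrade to linear weights on the inner cell
        need_lin = lin & ~tri
        if need_lin.any():
            for a in range(3):
                sl = s[need_lin, a]
                ws[a][need_lin] = np.stack(
                    [np.zeros_like(sl), 1.0 - sl, sl, np.zeros_like(sl)], axis=-1)
                if derivative:
                    dws[a][need_lin] = np.stack(
                        [np.zeros_like(sl), -np.ones_like(sl), np.ones_like(sl),
                         np.zeros_like(sl)], axis=-1)
        # degrade to nearest valid voxel in the window
        need_nn = any_valid & ~lin & ~tri
        if need_nn.any():
            sub = np.nonzero(need_nn)[0]
            d2 = np.zeros((sub.size, 4, 4, 4))
            off = np.arange(-1, 3, dtype=np.float64)
            for a, bshape in zip(range(3), [(1, 4, 1, 1), (1, 1, 4, 1), (1, 1, 1, 4)]):
                da = (off.reshape(bshape[1:]) - s[sub, a][:, None, None, None]) * self.spacing[a]
                d2 = d2 + da * da
            d2 = np.where(Vw[sub], d2, np.inf)
            flat = d2.reshape(sub.size, -1).argmin(axis=1)
            onehot = np.eye(4)
            for a, pos in zip(range(3), np.unravel_index(flat, (4, 4, 4))):
                ws[a][sub] = onehot[pos]
                if derivative:
                    dws[a][sub] = 0.0
        bad = ~any_valid
        if bad.any():
            for a in range(3):
                ws[a][bad] = np.nan
                if derivative:
                    dws[a][bad] = np.nan
        return ws, dws, degree

    def _eval_chunk(self, pts, derivative):
        vals, Vw, s, inside, idx = self._window(pts)
        ws, dws, degree = self._axis_weights(Vw, s, inside, idx, derivative=derivative)
        wx, wy, wz = ws
        ncomp = len(self.comps)
        npts = s.shape[0]
        out = np.empty((npts, ncomp))
        for c, v in enumerate(vals):
            out[:, c] = np.einsum("nijk,ni,nj,nk->n", v, wx, wy, wz)
        jac = None
        if derivative:
            dwx, dwy, dwz = dws
            jac = np.empty((npts, ncomp, 3))
            for c, v in enumerate(vals):
                jac[:, c, 0] = np.einsum("nijk,ni,nj,nk->n", v, dwx, wy, wz) / self.spacing[0]
                jac[:, c, 1] = np.einsum("nijk,ni,nj,nk->n", v, wx, dwy, wz) / self.spacing[1]
                jac[:, c, 2] = np.einsum("nijk,ni,nj,nk->n", v, wx, wy, dwz) / self.spacing[2]
        return out, jac, degree

    def _evaluate(self, pts, derivative):
        pts = np.asarray(pts, dtype=np.float64)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if pts.shape[-1] != 3:
            raise ValueError("points must be (..., 3) world coordinates in mm")
        if self.out_of_bounds == "raise":
            u = (pts - self.origin) / self.spacing
            n = np.array(self.shape)
            if not np.all((u >= 0) & (u <= n - 1)):
                raise ValueError("query point outside the grid bounding box")
        outs, jacs, degs = [], [], []
        for start in range(0, pts.shape[0], _CHUNK):
            o, j, d = self._eval_chunk(pts[start:start + _CHUNK], derivative)
            outs.append(o)
            jacs.append(j)
            degs.append(d)
        out = np.concatenate(outs)
        degree = np.concatenate(degs)
        jac = np.concatenate(jacs) if derivative else None
        if single:
            out, degree = out[0], degree[0]
            if derivative:
                jac = jac[0]
        return out, jac, degree

    # -- public API ---------------------------------------------------------

    def sample(self, pts, with_degree: bool = False):
        """Interpolated component values at world points ``pts`` ((..., 3) mm)."""
        out, _, degree = self._evaluate(pts, derivative=False)
        return (out, degree) if with_degree else out

    def jacobian(self, pts, with_degree: bool = False):
        """Analytic derivative of the interpolant: (..., ncomp, 3) with
        entry [c, a] = d(component c)/d(world axis a)."""
        _, jac, degree = self._evaluate(pts, derivative=True)
        return (jac, degree) if with_degree else jac

    def sample_and_jacobian(self, pts):
        out, jac, degree = self._evaluate(pts, derivative=True)
        return out, jac, degree


def sample_velocity(field: VelocityField4D, p, t: int):
    """Velocity (mm/s) at world point ``p`` and phase index ``t``.

    Returns ``(vec, degree)`` where degree is the interpolation degree used
    (3 tricubic, 1 trilinear, 0 nearest-valid).  Raises when ``p`` lies
    outside the grid box or no valid neighbour exists.
    """
    vec, degree = field.sampler(t).sample(p, with_degree=True)
    if np.ndim(degree) == 0 and degree < 0:
        raise ValueError("no valid voxel near the query point")
    return vec, degree


def interpolate_time(field: VelocityField4D, factor: int) -> VelocityField4D:
    """Refine the cardiac cycle by an integer ``factor`` (e.g. 25 -> 250 phases).

    Per-voxel periodic cubic spline over the cycle; the original phases are
    reproduced exactly and each inter-phase gap is subdivided uniformly into
    ``factor`` new frames (the wrap-around gap closes the cycle back to phase
    0 at cycle fraction 1).
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be an integer >= 1")
    if factor == 1:
        return field
    nt = field.nt
    if nt < 4:
        raise ValueError("periodic cubic refinement needs at least 4 phases")
    t = field.phase_times
    t_ext = np.concatenate([t, [t[0] + 1.0]])
    gaps = np.diff(t_ext)
    frac = np.arange(factor) / factor
    new_t = (t[:, None] + gaps[:, None] * frac[None, :]).ravel()
    comps = []
    for comp in (field.vx, field.vy, field.vz):
        y_ext = np.concatenate([comp, comp[:1]], axis=0)
        spl = CubicSpline(t_ext, y_ext, axis=0, bc_type="periodic")
        new = spl(new_t)
        new[::factor] = comp  # originals exact by construction; keep them bit-identical
        comps.append(new)
    mask = field.mask
    return VelocityField4D(*comps, spacing=field.spacing, origin=field.origin,
                           phase_times=new_t, mask=mask)
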
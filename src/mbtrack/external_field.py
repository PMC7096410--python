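"""Import of externally computed velocity-field time series.

Allows a real CFD/FSI solution (exported as a sequence of legacy-VTK ASCII
unstructured-grid snapshots with nodal velocities) to replace the analytic
lubrication field.  Interpolation is piecewise linear: barycentric within
the Delaunay triangulation of the nodes, linear between time frames; the
velocity gradient is the per-simplex linear reconstruction (piecewise
constant in space).

The node cloud is re-triangulated rather than trusting the file's own
connectivity, so strongly non-convex lumens are covered by their convex hull
-- acceptable for the near-convex geometries targeted here (see
docs/methods.md).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.spatial import Delaunay

from .io import read_field_vtk
from .rheology import RheologyParams, apparent_viscosity, shear_rate_magnitude, \
    strain_rate_tensor


class ExternalFlowField:
    """Time series of nodal velocities on a fixed unstructured point cloud."""

    def __init__(self, points: np.ndarray, velocities: np.ndarray,
                 times: np.ndarray, rheology: RheologyParams | None = None):
        points = np.asarray(points, dtype=float)
        velocities = np.asarray(velocities, dtype=float)
        times = np.asarray(times, dtype=float)
        if velocities.ndim != 3 or velocities.shape[1:] != (len(points), 3):
            raise ValueError(
                "velocities must have shape (n_frames, n_points, 3)")
        if len(times) != len(velocities):
            raise ValueError("one time stamp per frame required")
        if len(times) < 2:
            raise ValueError(
                "at least 2 time frames required for interpolation")
        if np.any(np.diff(times) <= 0.0):
            raise ValueError("frame times must be strictly increasing")
        self.points = points
        self.velocities = velocities
        self.times = times
        self.rheology = rheology
        self.tri = Delaunay(points)
        # per-simplex barycentric transform is precomputed by scipy (tri.transform)

    # -- interpolation helpers ---------------------------------------------
    def _frame_weights(self, t: float):
        times = self.times
        if t <= times[0]:
            return 0, 0, 0.0
        if t >= times[-1]:
            return len(times) - 1, len(times) - 1, 0.0
        k = int(np.searchsorted(times, t, side="right") - 1)
        w = (t - times[k]) / (times[k + 1] - times[k])
        return k, k + 1, float(w)

    def _nodal(self, t: float) -> np.ndarray:
        k0, k1, w = self._frame_weights(t)
        if k0 == k1:
            return self.velocities[k0]
        return (1.0 - w) * self.velocities[k0] + w * self.velocities[k1]

    def inside(self, x):
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        ok = self.tri.find_simplex(pts) >= 0
        return bool(ok[0]) if np.asarray(x).ndim == 1 else ok

    def velocity(self, x, t):
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        simplex = self.tri.find_simplex(pts)
        if np.any(simplex < 0):
            raise ValueError("velocity query outside the imported mesh")
        nodal = self._nodal(t)
        trans = self.tri.transform[simplex]
        bary = np.einsum("nij,nj->ni", trans[:, :3],
                         pts - trans[:, 3])
        weights = np.column_stack([bary, 1.0 - bary.sum(axis=1)])
        verts = self.tri.simplices[simplex]
        out = np.einsum("nk,nkd->nd", weights, nodal[verts])
        return out[0] if np.asarray(x).ndim == 1 else out

    def velocity_gradient(self, x, t):
        """Per-simplex constant gradient G[i,j] = du_i/dx_j from the linear
        reconstruction over each tetrahedron."""
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        simplex = self.tri.find_simplex(pts)
        if np.any(simplex < 0):
            raise ValueError("gradient query outside the imported mesh")
        nodal = self._nodal(t)
        trans = self.tri.transform[simplex]          # (n, 4, 3)
        verts = self.tri.simplices[simplex]          # (n, 4)
        v = nodal[verts]                              # (n, 4, 3)
        # d(bary_k)/dx_j: rows of the transform for k<3; last = -sum
        dbary = np.concatenate(
            [trans[:, :3], -trans[:, :3].sum(axis=1, keepdims=True)], axis=1)
        grad = np.einsum("nkd,nkj->ndj", v, dbary)
        return grad[0] if np.asarray(x).ndim == 1 else grad

    def pressure(self, x, t):
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.zeros(len(pts))
        return float(out[0]) if np.asarray(x).ndim == 1 else out

    def wall_shear_stress(self, point, t):
        """eta_app(gdot) * gdot from the local velocity gradient; requires a
        rheology to have been supplied."""
        if self.rheology is None:
            raise ValueError("wall_shear_stress needs rheology parameters")
        grad = self.velocity_gradient(point, t)
        gdot = shear_rate_magnitude(strain_rate_tensor(grad))
        return apparent_viscosity(gdot, self.rheology) * gdot


def load_external_field(paths, times, rheology: RheologyParams | None = None
                        ) -> ExternalFlowField:
    """Load a velocity-field time series from legacy-VTK ASCII snapshots.

    ``paths`` is a sequence of files (>= 2 frames) sharing node coordinates
    and connectivity; ``times`` are their time stamps.  Raises a format error
    naming the offending file/frame on topology mismatch.
    """
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise ValueError(
            "single-frame field: need >= 2 frames to interpolate in time")
    if len(paths) != len(times):
        raise ValueError("need exactly one time stamp per frame")
    ref_points = ref_cells = None
    vels = []
    for k, p in enumerate(paths):
        points, cells, vel = read_field_vtk(p)
        if ref_points is None:
            ref_points, ref_cells = points, cells
        else:
            if points.shape != ref_points.shape or not np.allclose(
                    points, ref_points):
                raise ValueError(
                    f"frame {k} ({p}): node coordinates do not match frame 0")
            if (cells is None) != (ref_cells is None) or (
                    cells is not None and not np.array_equal(cells, ref_cells)):
                raise ValueError(
                    f"frame {k} ({p}): connectivity does not match frame 0")
        vels.append(vel)
    return ExternalFlowField(ref_points, np.stack(vels), np.asarray(times),
                             rheology=rheology)
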
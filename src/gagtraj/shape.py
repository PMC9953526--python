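"""Minimum-volume enclosing ellipsoid (MVEE) and 2-D landscape histograms.

The MVEE of the solute atoms is used as a per-frame molecular volume
descriptor. It is computed by the Khachiyan barycentric-coordinate ascent
on the determinant-maximisation dual, accelerated with Wolfe-Atwood away
steps (linear convergence) and a convex-hull pre-reduction (only hull
vertices can support the ellipsoid). The returned shape matrix is rescaled
so that every input point lies inside; the volume is then within O(tol) of
the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .model import DescriptorSeries, Topology, Trajectory


class MveeError(ValueError):
    pass


@dataclass
class Ellipsoid:
    """Ellipsoid { x : (x - center)^T A (x - center) <= 1 }."""

    center: np.ndarray        # (3,), A
    shape_matrix: np.ndarray  # (3, 3) symmetric positive definite, A^-2 units
    volume: float             # A^3
    semi_axes: np.ndarray     # (3,), descending, A

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        d = np.asarray(points) - self.center
        return np.einsum("ij,jk,ik->i", d, self.shape_matrix, d) <= 1.0 + tol


def _mvee_dual(points: np.ndarray, tol: float, max_iter: int):
    """Wolfe-Atwood ascent; returns barycentric weights u over `points`."""
    n, d = points.shape
    q = np.column_stack([points, np.ones(n)])         # lifted points, (n, d+1)
    u = np.full(n, 1.0 / n)
    dp1 = d + 1
    x = q.T @ (q * u[:, None])
    for _ in range(max_iter):
        xin = np.linalg.inv(x)
        m = np.einsum("ij,jk,ik->i", q, xin, q)
        j_plus = int(np.argmax(m))
        eps_plus = m[j_plus] / dp1 - 1.0
        support = u > 0
        m_minus = np.where(support, m, np.inf)
        j_minus = int(np.argmin(m_minus))
        eps_minus = 1.0 - m_minus[j_minus] / dp1
        if eps_plus <= tol and eps_minus <= tol:
            return u
        if eps_plus >= eps_minus:                      # add step (Khachiyan)
            j, mj = j_plus, m[j_plus]
            step = (mj - dp1) / (dp1 * (mj - 1.0))
        else:                                          # away step
            j, mj = j_minus, m_minus[j_minus]
            step = max((mj - dp1) / (dp1 * (mj - 1.0)), -u[j] / (1.0 - u[j]))
        u *= 1.0 - step
        u[j] += step
        qj = q[j]
        x = (1.0 - step) * x + step * np.outer(qj, qj)
    raise MveeError(f"MVEE did not converge within {max_iter} iterations")


def mvee(points: np.ndarray, tol: float = 1e-4, max_iter: int = 100_000) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of a 3-D point set.

    Requires at least 4 affinely independent points; degenerate (coplanar or
    collinear) sets raise, with the advice to jitter or drop a dimension.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise MveeError(f"expected (n, 3) points, got {pts.shape}")
    n, d = pts.shape
    if n < 4:
        raise MveeError("need at least 4 points for a 3-D enclosing ellipsoid")
    if tol <= 0:
        raise MveeError("tol must be positive")
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(centred).max())) < 3:
        raise MveeError(
            "degenerate (coplanar/collinear) point set: jitter the points or "
            "use a lower-dimensional fit"
        )
    work = pts
    if n > 16:  # only hull vertices can carry weight
        try:
            work = pts[ConvexHull(pts).vertices]
        except QhullError:
            work = pts
    u = _mvee_dual(work, tol, max_iter)
    c = u @ work
    cov = (work * u[:, None]).T @ work - np.outer(c, c)
    a = np.linalg.inv(cov) / d
    # guarantee containment of *all* input points, then report the tight hull
    dev = pts - c
    scale = np.einsum("ij,jk,ik->i", dev, a, dev).max()
    if scale > 1.0:
        a = a / scale
    eigval = np.linalg.eigvalsh(a)
    semi = np.sort(1.0 / np.sqrt(eigval))[::-1]
    volume = 4.0 * np.pi / 3.0 / np.sqrt(np.linalg.det(a))
    return Ellipsoid(center=c, shape_matrix=a, volume=float(volume), semi_axes=semi)


def volume_series(traj: Trajectory, topology: Topology, tol: float = 1e-4) -> DescriptorSeries:
    """Per-frame MVEE volume (A^3) of the solute atoms."""
    sel = traj.solute_indices
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        try:
            values[f] = mvee(traj.coordinates[f, sel], tol=tol).volume
        except MveeError as e:
            raise MveeError(f"frame {f}: {e}") from None
    return DescriptorSeries("volume", values, units="A^3")


@dataclass
class Heatmap2D:
    """A 2-D probability histogram (cells sum to 1)."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    probability: np.ndarray    # (nx, ny)
    x_name: str = "x"
    y_name: str = "y"
    x_units: str = ""
    y_units: str = ""


def histogram2d(xs, ys, bins=50, range_=None, x_name="x", y_name="y",
                x_units="", y_units="") -> Heatmap2D:
    """Joint probability histogram of two equal-length per-frame series.

    `bins` may be counts or explicit edge arrays. Default conventions:
    50 x 50 over the data range for EED x volume landscapes; fixed 5-degree
    edges over [-180, 180) for phi/psi maps (pass those edges explicitly).
    """
    xs = np.asarray(xs, dtype=float).ravel()
    ys = np.asarray(ys, dtype=float).ravel()
    if xs.size == 0:
        raise ValueError("empty series")
    if xs.size != ys.size:
        raise ValueError(f"series lengths differ: {xs.size} vs {ys.size}")
    counts, xe, ye = np.histogram2d(xs, ys, bins=bins, range=range_)
    prob = counts / counts.sum()
    return Heatmap2D(xe, ye, prob, x_name, y_name, x_units, y_units)


def dihedral_edges(width_deg: float = 5.0) -> np.ndarray:
    """Fixed bin edges over [-180, 180) for torsion-angle heatmaps."""
    return np.arange(-180.0, 180.0 + width_deg / 2, width_deg)
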
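"""Elementary geometry and the flexibility/shape scalar descriptors.

Dihedral angles follow the IUPAC sign convention (looking along the central
bond from atom 2 to atom 3, a clockwise rotation of the far bond is
positive), with cis = 0 deg and trans reported as -180 deg so that every
angle lies in the half-open interval [-180, 180).

RMSD is computed after optimal rigid-body superposition (Kabsch), unweighted,
over all solute atoms, with the first frame as the reference — the common
default of MD analysis tools when a trajectory is compared to its initial
structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DescriptorSeries, Topology, Trajectory


class GeometryError(ValueError):
    pass


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, in [-180, 180)) of four points."""
    return float(dihedral_batch(np.asarray([p1]), np.asarray([p2]),
                                np.asarray([p3]), np.asarray([p4]))[0])


def dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised dihedral over leading axes; inputs (..., 3) in angstrom."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b, lbl in ((b1, "1-2"), (b2, "2-3"), (b3, "3-4")):
        if np.any(np.linalg.norm(b, axis=-1) < 1e-12):
            raise GeometryError(f"coincident points on bond {lbl}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-12) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-12
    ):
        raise GeometryError("three consecutive points are collinear")
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return wrap_angle(ang)


def wrap_angle(deg) -> np.ndarray:
    """Map angles into [-180, 180); +180 becomes -180."""
    return np.mod(np.asarray(deg, dtype=float) + 180.0, 360.0) - 180.0


def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns (rotation 3x3, translation 3, rmsd). The rotation is proper
    (det = +1); reflections are never returned. The fitted coordinates are
    mobile @ R.T + t and the returned RMSD is the global minimum over all
    rigid motions.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError(f"point sets must both be (n, 3); got {ref.shape} vs {mob.shape}")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError("need at least 3 points for superposition")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    h = mob_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(1.0, s[0]):
        raise GeometryError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    fitted = mob_c @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_c) ** 2, axis=1))))
    trans = ref.mean(axis=0) - mob.mean(axis=0) @ rot.T
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, topology: Topology) -> DescriptorSeries:
    """Best-fit all-solute-atom RMSD to the first frame, per frame."""
    sel = traj.solute_indices
    ref = traj.coordinates[0, sel]
    values = np.empty(traj.n_frames)
    values[0] = 0.0
    for f in range(1, traj.n_frames):
        values[f] = kabsch_superpose(ref, traj.coordinates[f, sel])[2]
    return DescriptorSeries("rmsd", values, units="A")


def rgyr_series(traj: Trajectory, topology: Topology) -> DescriptorSeries:
    """Unweighted (geometric) radius of gyration of the solute, per frame."""
    sel = traj.solute_indices
    if len(sel) == 0:
        raise GeometryError("empty solute selection")
    xyz = traj.coordinates[:, sel, :]
    centred = xyz - xyz.mean(axis=1, keepdims=True)
    values = np.sqrt(np.mean(np.sum(centred**2, axis=2), axis=1))
    return DescriptorSeries("rgyr", values, units="A")


def eed_series(traj: Trajectory, topology: Topology) -> DescriptorSeries:
    """End-to-end distance: reducing-end O1 to the glycosidic oxygen of the
    non-reducing-end linkage, per frame."""
    if topology.eed_atoms is None:
        raise GeometryError("topology has no resolved EED atoms")
    i, j = topology.eed_atoms
    d = np.linalg.norm(traj.coordinates[:, i, :] - traj.coordinates[:, j, :], axis=1)
    return DescriptorSeries("eed", d, units="A")


@dataclass
class LinkageAngles:
    """Per-frame (phi, psi) in degrees for one glycosidic linkage."""

    linkage_id: int
    linkage_type: int
    phi: np.ndarray
    psi: np.ndarray


def linkage_series(traj: Trajectory, topology: Topology) -> list:
    """One (phi, psi) series per linkage, in chain order."""
    out = []
    xyz = traj.coordinates
    for k, lk in enumerate(topology.linkages):
        phi = dihedral_batch(*(xyz[:, i, :] for i in lk.phi_atoms))
        psi = dihedral_batch(*(xyz[:, i, :] for i in lk.psi_atoms))
        out.append(LinkageAngles(k, lk.type, phi, psi))
    return out


def pool_linkages_by_type(series: list) -> dict:
    """Pool per-linkage angle series by linkage type (1 and 2), concatenating
    frames of all linkages of the same type — the convention used when one
    conformational map is drawn per linkage type per molecule."""
    pooled: dict = {}
    for s in series:
        phi, psi = pooled.get(s.linkage_type, (np.empty(0), np.empty(0)))
        pooled[s.linkage_type] = (np.concatenate([phi, s.phi]), np.concatenate([psi, s.psi]))
    return pooled
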
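"""Cremer-Pople puckering of six-membered rings and conformer populations.

Ring atoms are always ordered O5, C1, C2, C3, C4, C5. Under this ordering
and the standard Cremer-Pople mean-plane normal (R' x R''), the 4C1 chair of
a beta-D-pyranose sits at theta ~ 0 deg and 1C4 at theta ~ 180 deg. Named
skew (twist-boat) conformers live on the equator theta = 90 deg; with this
atom ordering the 2SO meridian is phi = 150 deg and the 1S3 meridian is
phi = 210 deg (derived by analysing idealised skew geometries: the named
atom above the plane displaced +z, the other below, remaining four in
plane).

The classification sector map (polar caps, equatorial band, meridian
half-widths) is configuration, not a constant of nature: different works
draw these boundaries differently, and the map here is the package default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Topology, Trajectory

#: Labels used for population reporting.
LABELS = ("4C1", "1C4", "2SO", "1S3", "other")

_J = np.arange(6)
_COS2 = np.cos(4.0 * np.pi * _J / 6.0)          # m=2 cosine basis
_SIN2 = np.sin(4.0 * np.pi * _J / 6.0)
_SIGN = (-1.0) ** _J                            # m=3 (alternating) basis
_COS1 = np.cos(2.0 * np.pi * _J / 6.0)
_SIN1 = np.sin(2.0 * np.pi * _J / 6.0)


class PuckerError(ValueError):
    pass


@dataclass(frozen=True)
class PuckerState:
    """Cremer-Pople parameters of one six-membered ring in one frame."""

    Q: float            # total puckering amplitude, A
    theta: float        # deg, [0, 180]
    phi: float          # deg, [0, 360)
    q2: float           # A
    q3: float           # A
    label: str
    degenerate_phi: bool = False


@dataclass(frozen=True)
class SectorMap:
    """Angular sectors assigning (theta, phi) to canonical conformer labels."""

    chair_cap_deg: float = 45.0          # theta < cap -> 4C1; theta > 180-cap -> 1C4
    meridian_halfwidth_deg: float = 15.0
    meridians: dict = field(default_factory=lambda: {"2SO": 150.0, "1S3": 210.0})
    amplitude_floor: float = 0.1         # A; below this phi/theta are meaningless

    def classify(self, theta: float, phi: float, Q: float) -> str:
        if Q < self.amplitude_floor:
            return "other"
        if theta < self.chair_cap_deg:
            return "4C1"
        if theta > 180.0 - self.chair_cap_deg:
            return "1C4"
        for name, mer in self.meridians.items():
            delta = (phi - mer + 180.0) % 360.0 - 180.0
            if abs(delta) <= self.meridian_halfwidth_deg:
                return name
        return "other"

    @classmethod
    def from_dict(cls, d: dict) -> "SectorMap":
        kw = {}
        if "chair_cap_deg" in d:
            kw["chair_cap_deg"] = float(d["chair_cap_deg"])
        if "meridian_halfwidth_deg" in d:
            kw["meridian_halfwidth_deg"] = float(d["meridian_halfwidth_deg"])
        if "meridians" in d:
            kw["meridians"] = {str(k): float(v) for k, v in d["meridians"].items()}
        if "amplitude_floor" in d:
            kw["amplitude_floor"] = float(d["amplitude_floor"])
        return cls(**kw)


DEFAULT_SECTOR_MAP = SectorMap()


def cremer_pople_batch(coords: np.ndarray):
    """Cremer-Pople (Q, theta, phi, q2, q3) for rings stacked along axis 0.

    coords: (..., 6, 3), atoms ordered O5, C1, C2, C3, C4, C5.
    Returns arrays Q, theta(deg), phi(deg in [0,360)), q2, q3.
    """
    r = np.asarray(coords, dtype=float)
    if r.shape[-2:] != (6, 3):
        raise PuckerError(f"expected (..., 6, 3) ring coordinates, got {r.shape}")
    r = r - r.mean(axis=-2, keepdims=True)
    rp = np.einsum("...jk,j->...k", r, _SIN1)    # R'
    rpp = np.einsum("...jk,j->...k", r, _COS1)   # R''
    n = np.cross(rp, rpp)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise PuckerError("degenerate ring: mean plane undefined")
    n = n / norm
    z = np.einsum("...jk,...k->...j", r, n)      # displacements from mean plane
    q2c = np.sqrt(1.0 / 3.0) * z @ _COS2
    q2s = -np.sqrt(1.0 / 3.0) * z @ _SIN2
    q2 = np.hypot(q2c, q2s)
    q3 = np.sqrt(1.0 / 6.0) * z @ _SIGN
    Q = np.hypot(q2, q3)
    theta = np.degrees(np.arctan2(q2, q3))       # q2 >= 0 -> theta in [0, 180]
    phi = np.degrees(np.arctan2(q2s, q2c)) % 360.0
    return Q, theta, phi, q2, q3


def cremer_pople(ring_coords, sector_map: SectorMap = DEFAULT_SECTOR_MAP) -> PuckerState:
    """Pucker state of a single ring given its 6 ordered atom positions."""
    r = np.asarray(ring_coords, dtype=float)
    if r.shape != (6, 3):
        raise PuckerError(f"expected 6 ring atoms with 3 coordinates, got {r.shape}")
    d = r[:, None, :] - r[None, :, :]
    if np.any(np.linalg.norm(d, axis=-1)[np.triu_indices(6, 1)] < 1e-9):
        raise PuckerError("coincident ring atoms")
    Q, theta, phi, q2, q3 = (float(x[0]) for x in cremer_pople_batch(r[None]))
    degenerate = Q < sector_map.amplitude_floor
    label = sector_map.classify(theta, phi, Q)
    return PuckerState(Q, theta, phi, q2, q3, label, degenerate_phi=degenerate)


def build_ring(Q: float, theta: float, phi: float, base_radius: float = 1.43) -> np.ndarray:
    """Construct an idealised six-membered ring with prescribed puckering.

    Atoms sit on a regular hexagon of the given radius in the xy plane, at
    polar angles 2*pi*j/6 (j = 0..5, atom order O5, C1..C5), displaced along
    z by the Cremer-Pople inverse formula. cremer_pople(build_ring(Q, t, p))
    recovers (Q, t, p) exactly for Q > 0: z built from the m=2 and m=3
    harmonics only leaves the mean plane equal to the hexagon plane.
    """
    if Q < 0:
        raise PuckerError("Q must be non-negative")
    if base_radius <= 0:
        raise PuckerError("base_radius must be positive")
    th = np.radians(theta)
    ph = np.radians(phi)
    q2 = Q * np.sin(th)
    q3 = Q * np.cos(th)
    z = np.sqrt(1.0 / 3.0) * q2 * np.cos(ph + 4.0 * np.pi * _J / 6.0) \
        + np.sqrt(1.0 / 6.0) * q3 * _SIGN
    # Clockwise traversal seen from +z: the Cremer-Pople normal (R' x R'')
    # of such a hexagon is +z, so the analysed z displacements equal the
    # built ones and the round trip is exact.
    ang = -2.0 * np.pi * _J / 6.0
    return np.column_stack([base_radius * np.cos(ang), base_radius * np.sin(ang), z])


def classify_pucker(state: PuckerState, sector_map: SectorMap = DEFAULT_SECTOR_MAP) -> str:
    return sector_map.classify(state.theta, state.phi, state.Q)


@dataclass
class PuckerPopulations:
    """Conformer fractions per ring residue and pooled by residue type."""

    per_residue: dict     # residue_index -> {label: fraction}
    per_type: dict        # residue role/name key -> {label: fraction}
    terminal: dict        # {label: fraction} over terminal sugar residues
    internal: dict        # {label: fraction} over internal sugar residues (may be empty)
    labels_per_frame: dict  # residue_index -> array of label strings (for audits)


def _fractions(labels: np.ndarray) -> dict:
    n = len(labels)
    return {lab: float(np.count_nonzero(labels == lab)) / n for lab in LABELS}


def _mix(label_arrays: list) -> dict:
    if not label_arrays:
        return {}
    return _fractions(np.concatenate(label_arrays))


def pucker_populations(
    traj: Trajectory,
    topology: Topology,
    sector_map: SectorMap = DEFAULT_SECTOR_MAP,
) -> PuckerPopulations:
    """Conformer population fractions over all frames.

    Pooled-by-type fractions are frame-weighted (every residue contributes
    every frame), so the pooled population equals the mean of per-residue
    populations when all residues share the frame count. Terminal (first and
    last sugar residue of the chain) and internal residues are also pooled
    separately, since chain ends typically pucker more freely.
    """
    sugar = topology.sugar_residue_indices()
    if not sugar:
        raise PuckerError("topology has no sugar rings")
    per_res_labels = {}
    for ri in sugar:
        ring = topology.rings[ri]
        coords = traj.coordinates[:, list(ring), :]
        Q, theta, phi, _, _ = cremer_pople_batch(coords)
        labels = np.array(
            [sector_map.classify(t, p, q) for q, t, p in zip(Q, theta, phi)]
        )
        per_res_labels[ri] = labels
    per_residue = {ri: _fractions(lab) for ri, lab in per_res_labels.items()}
    role_of = {}
    name_of = {}
    for res in topology.residues:
        if res.role in ("hexosamine", "uronic_acid"):
            ri = topology.atoms[res.atom_indices[0]].residue_index
            role_of[ri] = res.role
            name_of[ri] = res.name
    per_type: dict = {}
    for key_fn in (lambda ri: role_of[ri], lambda ri: name_of[ri]):
        groups: dict = {}
        for ri in sugar:
            groups.setdefault(key_fn(ri), []).append(per_res_labels[ri])
        for key, arrs in groups.items():
            per_type[key] = _mix(arrs)
    ends = {sugar[0], sugar[-1]}
    terminal = _mix([per_res_labels[ri] for ri in sugar if ri in ends])
    internal = _mix([per_res_labels[ri] for ri in sugar if ri not in ends])
    return PuckerPopulations(per_residue, per_type, terminal, internal, per_res_labels)
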
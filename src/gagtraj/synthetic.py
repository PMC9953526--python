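"""Synthetic GAG-like oligosaccharide trajectories with planted ground truth.

The generator builds chondroitin/dermatan-like chains (GalNAc with 4-O- or
6-O-sulfation alternating with GlcA or IdoA) from idealised internal
coordinates: each pyranose ring is constructed by the Cremer-Pople inverse
(`puckering.build_ring`) at a puckering state sampled from a planted
categorical distribution, rings are chained through glycosidic bonds whose
phi/psi torsions are sampled from planted Gaussian mixtures, substituents
(carboxyl, sulfate, N-acetyl, hydroxyls with polar hydrogens) are placed by
torsion templates, hydrogen bonds and counterion contacts are switched on
and off per frame by planted Bernoulli flags, and a small Cartesian jitter
is added last.

This is statistics, not physics: there is no force field, no sterics, no
solvent structure. The point is that every descriptor stage of the pipeline
can be validated against the recorded truth without running molecular
dynamics. Planted geometries keep wide safety margins to the detection
cutoffs (contact distance 0.85 x cutoff, H-bond distance 2.7 vs 3.0 A,
collinear D-H-A vs 135 deg) so that the default jitter (sd 0.03 A) cannot
flip any planted classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import DEFAULT as DEFAULT_CONVENTIONS
from .io import _build_topology, atom_class_indices
from .model import AtomRecord, ChargeMap, Topology, Trajectory
from .puckering import build_ring

GAG_TYPES = ("CS4", "CS6", "DS")
DEGREES = ("dp2", "dp4", "dp6")
SETS = ("Set1", "Set2")


class SyntheticSpecError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueKind:
    role: str                      # hexosamine | uronic_acid
    name: str                      # residue name written to files
    sulfation: Optional[int] = None  # 4 or 6 on hexosamines
    uronic_kind: Optional[str] = None  # GlcA | IdoA


@dataclass(frozen=True)
class LinkageComponent:
    weight: float
    phi_mean: float
    psi_mean: float
    phi_sd: float = 8.0
    psi_sd: float = 8.0


@dataclass(frozen=True)
class HBondPlant:
    """A planted donor->acceptor hydrogen bond with a target frame fraction.

    donor_oxygen names a hydroxyl oxygen of the donor residue (its hydrogen
    is repositioned); acceptor_atom is an O/N atom of the acceptor residue.
    """

    donor_residue: int
    donor_oxygen: str
    acceptor_residue: int
    acceptor_atom: str
    fraction: float


@dataclass(frozen=True)
class WaterPlant:
    count: int
    fraction: float


#: Idealised (Q / A, theta / deg, phi / deg) for the planted pucker states.
DEFAULT_STATE_GEOMETRY = {
    "4C1": (0.55, 5.0, 30.0),
    "1C4": (0.55, 175.0, 30.0),
    "2SO": (0.65, 90.0, 150.0),
    "1S3": (0.65, 90.0, 210.0),
}


@dataclass
class SyntheticSpec:
    """Full description of a synthetic trajectory, including all truths."""

    name: str
    chain: list                    # list[ResidueKind], non-reducing end first
    n_frames: int
    seed: int
    pucker_truth: dict             # residue_index -> {label: weight}
    linkage_truth: dict            # linkage position (0-based) -> [LinkageComponent]
    hbond_truth: list = field(default_factory=list)   # list[HBondPlant]
    ion_truth: dict = field(default_factory=dict)     # kind -> target fraction
    n_background_ions: int = 2
    #: when True, all linkages share one per-frame mixture component (a
    #: global two-state conformational switch rather than independent
    #: per-linkage flips)
    linkage_correlated: bool = False
    water_truth: Optional[WaterPlant] = None
    jitter_sd: float = 0.03        # A
    state_geometry: dict = field(default_factory=lambda: dict(DEFAULT_STATE_GEOMETRY))
    set_label: Optional[str] = None

    def validate(self):
        if self.n_frames < 1:
            raise SyntheticSpecError("n_frames must be >= 1")
        if self.jitter_sd < 0 or self.jitter_sd > 0.05:
            raise SyntheticSpecError("jitter sd must be in [0, 0.05] A")
        nres = len(self.chain)
        for ri, dist in self.pucker_truth.items():
            if not (1 <= ri <= nres):
                raise SyntheticSpecError(f"pucker truth for unknown residue {ri}")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SyntheticSpecError(f"pucker weights of residue {ri} must sum to 1")
        for k, comps in self.linkage_truth.items():
            if not (0 <= k < nres - 1):
                raise SyntheticSpecError(f"linkage truth for unknown linkage {k}")
            if abs(sum(c.weight for c in comps) - 1.0) > 1e-9:
                raise SyntheticSpecError(f"linkage {k} component weights must sum to 1")
        for hb in self.hbond_truth:
            if abs(hb.donor_residue - hb.acceptor_residue) > 1 and \
                    hb.donor_residue != hb.acceptor_residue:
                raise SyntheticSpecError(
                    "planted H-bonds must be within one residue or between "
                    "adjacent residues (no shared template geometry otherwise)"
                )
            if not (0.0 <= hb.fraction <= 1.0):
                raise SyntheticSpecError("H-bond fraction must be in [0, 1]")
        for kind, frac in self.ion_truth.items():
            if kind not in ("carboxyl", "sulfate"):
                raise SyntheticSpecError(f"unknown charged-group kind {kind!r}")
            if not (0.0 <= frac <= 1.0):
                raise SyntheticSpecError("ion contact fraction must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Realised (not just targeted) per-frame states of a generated run."""

    spec: SyntheticSpec
    pucker_labels: dict            # residue_index -> (F,) array of labels
    linkage_components: dict       # linkage pos -> (F,) int component index
    linkage_angles: dict           # linkage pos -> (F, 2) planted (phi, psi)
    hbond_flags: list              # parallel to spec.hbond_truth: (F,) bool
    ion_flags: dict                # (kind, residue_index) -> (F,) bool
    water_flags: Optional[np.ndarray] = None   # (count, F) bool

    def realized_pucker_fractions(self, residue_index: int) -> dict:
        lab = self.pucker_labels[residue_index]
        return {l: float(np.mean(lab == l)) for l in set(lab)}

    def to_json(self, path) -> None:
        payload = {
            "name": self.spec.name,
            "n_frames": self.spec.n_frames,
            "seed": self.spec.seed,
            "pucker_labels": {str(k): v.tolist() for k, v in self.pucker_labels.items()},
            "linkage_components": {str(k): v.tolist() for k, v in self.linkage_components.items()},
            "hbond_flags": [f.tolist() for f in self.hbond_flags],
            "ion_flags": {f"{k[0]}:{k[1]}": v.tolist() for k, v in self.ion_flags.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# chain composition and presets


def _hexosamine(sulfation: int) -> ResidueKind:
    return ResidueKind("hexosamine", f"NG{sulfation}", sulfation=sulfation)


def _uronic(kind: str) -> ResidueKind:
    return ResidueKind("uronic_acid", "GCU" if kind == "GlcA" else "IDR",
                       uronic_kind=kind)


def chain_composition(gag_type: str, dp: str, set_label: str) -> list:
    """Residue sequence (non-reducing end first) of one of the 18 oligomers."""
    sulf = 6 if gag_type == "CS6" else 4
    uronic = "IdoA" if gag_type == "DS" else "GlcA"
    n = int(dp[2:])
    unit = [_hexosamine(sulf), _uronic(uronic)]
    if set_label == "Set2":
        unit = unit[::-1]
    return [unit[i % 2] for i in range(n)]


def preset_specs(name, n_frames: int = 2000, seed: int = 0) -> SyntheticSpec:
    """Planted-truth spec for one of the 18 study oligomers.

    `name` is "CS4 dp2 Set1" style (space, dash or underscore separated) or a
    (gag_type, dp, set) tuple. Planted conformational tendencies follow the
    qualitative study picture: CS chains keep a single dominant uronic
    pucker and unimodal linkages, the DS chain has a strongly bimodal IdoA
    pucker and a two-state linkage ensemble (hence a two-state global shape);
    terminal residues pucker more freely than internal ones. Planted ion
    contact rates are the study's per-type contact fractions.
    """
    if isinstance(name, str):
        parts = name.replace("-", " ").replace("_", " ").split()
    else:
        parts = list(name)
    if len(parts) != 3 or parts[0] not in GAG_TYPES or parts[1] not in DEGREES \
            or parts[2] not in SETS:
        raise SyntheticSpecError(
            f"unknown oligomer {name!r}: expected <CS4|CS6|DS> <dp2|dp4|dp6> <Set1|Set2>"
        )
    gag_type, dp, set_label = parts
    chain = chain_composition(gag_type, dp, set_label)
    nres = len(chain)

    uronic_pucker = {
        "CS4": {"1C4": 0.85, "4C1": 0.10, "2SO": 0.05},
        "CS6": {"1C4": 0.75, "4C1": 0.125, "2SO": 0.078, "1S3": 0.047},
        "DS": {"1C4": 0.60, "4C1": 0.40},
    }[gag_type]
    pucker_truth = {}
    for i, rk in enumerate(chain, start=1):
        terminal = i in (1, nres)
        if rk.role == "hexosamine":
            pucker_truth[i] = {"4C1": 0.90, "1C4": 0.10} if terminal else {"4C1": 0.97, "1C4": 0.03}
        else:
            pucker_truth[i] = dict(uronic_pucker)

    correlated = gag_type == "DS"
    if correlated:
        # a global bent <-> extended two-state switch, slow exchange emulated
        # by switching every linkage together
        comps = [LinkageComponent(0.55, -75.0, -110.0), LinkageComponent(0.45, -75.0, 170.0)]
    else:
        spread = 12.0 if gag_type == "CS6" else 9.0
        comps = [LinkageComponent(0.92, -75.0, -110.0, spread, spread),
                 LinkageComponent(0.08, -75.0, -150.0, spread, spread)]
    linkage_truth = {k: list(comps) for k in range(nres - 1)}

    hb_fraction = {"CS4": 0.70, "CS6": 0.75, "DS": 0.50}[gag_type]
    hbond_truth = []
    for i, rk in enumerate(chain, start=1):
        if rk.role == "uronic_acid" and i > 1:
            # uronic O3-H donates to the carbonyl oxygen of the preceding
            # hexosamine's N-acetyl group (a protruding, uncrowded acceptor)
            hbond_truth.append(HBondPlant(i, "O3", i - 1, "O7", hb_fraction))
        elif rk.role == "hexosamine" and i > 1:
            # hexosamine amide donates to the preceding uronic 2-hydroxyl
            hbond_truth.append(HBondPlant(i, "N2", i - 1, "O2", hb_fraction))

    ion_truth = {
        "CS4": {"carboxyl": 0.0186, "sulfate": 0.0137},
        "CS6": {"carboxyl": 0.0189, "sulfate": 0.0145},
        "DS": {"carboxyl": 0.0231, "sulfate": 0.0139},
    }[gag_type]

    return SyntheticSpec(
        name=f"{gag_type} {dp} {set_label}",
        chain=chain,
        n_frames=n_frames,
        seed=seed,
        pucker_truth=pucker_truth,
        linkage_truth=linkage_truth,
        hbond_truth=hbond_truth,
        ion_truth=dict(ion_truth),
        linkage_correlated=correlated,
        set_label=set_label,
    )


def all_preset_names() -> list:
    return [f"{g} {d} {s}" for g in GAG_TYPES for d in DEGREES for s in SETS]


# ---------------------------------------------------------------------------
# vectorised internal-coordinate machinery


def _place(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement, vectorised over frames: all inputs (F, 3) / (F,)."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    bond = np.asarray(bond)[..., None] if np.ndim(bond) else bond
    d2x = -np.cos(ang)
    d2y = np.sin(ang) * np.cos(tor)
    d2z = np.sin(ang) * np.sin(tor)
    return c + bond * (d2x[..., None] * bc + d2y[..., None] * m + d2z[..., None] * n)


def build_ring_batch(Q, theta, phi, base_radius: float = 1.43) -> np.ndarray:
    """(F,) pucker parameters -> (F, 6, 3) rings (same convention as build_ring)."""
    Q = np.asarray(Q, float)
    th = np.radians(np.asarray(theta, float))
    ph = np.radians(np.asarray(phi, float))
    j = np.arange(6)
    q2 = Q * np.sin(th)
    q3 = Q * np.cos(th)
    z = (np.sqrt(1.0 / 3.0) * q2[:, None] * np.cos(ph[:, None] + 4.0 * np.pi * j / 6.0)
         + np.sqrt(1.0 / 6.0) * q3[:, None] * (-1.0) ** j)
    ang = -2.0 * np.pi * j / 6.0
    out = np.empty((len(Q), 6, 3))
    out[:, :, 0] = base_radius * np.cos(ang)
    out[:, :, 1] = base_radius * np.sin(ang)
    out[:, :, 2] = z
    return out


def _rigid_from_triples(p, t):
    """Per-frame rigid maps sending point triples p -> t; both (F, 3, 3).

    The triples are assumed congruent (equal pairwise distances); returns
    (R, shift) with x -> x @ R.T + shift.
    """
    def frame(x):
        e1 = x[:, 1] - x[:, 0]
        e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
        v = x[:, 2] - x[:, 0]
        v = v - np.sum(v * e1, axis=-1, keepdims=True) * e1
        e2 = v / np.linalg.norm(v, axis=-1, keepdims=True)
        e3 = np.cross(e1, e2)
        return np.stack([e1, e2, e3], axis=-1)   # (F, 3, 3) columns

    fp = frame(p)
    ft = frame(t)
    rot = ft @ np.transpose(fp, (0, 2, 1))
    shift = t[:, 0] - np.einsum("fij,fj->fi", rot, p[:, 0])
    return rot, shift


# substituent templates: (atom_name, element, (ref_a, ref_b, ref_c), bond, angle, torsion)
# refs are atom names within the same residue; placement order matters.

_RING = ["O5", "C1", "C2", "C3", "C4", "C5"]

_CO, _CC, _OH, _NH = 1.41, 1.52, 0.96, 1.01


def _substituent_templates(rk: ResidueKind, position: str, linked_in: bool):
    """Substituents for one residue.

    position: 'nre' | 'internal' | 're' (a dp2 NRE residue is still 'nre').
    linked_in: whether an upstream residue occupies this residue's acceptor
    position (C4 for uronic acids, C3 for hexosamines).
    """
    t = []
    if rk.role == "hexosamine":
        t += [("N2", "N", ("O5", "C1", "C2"), 1.47, 110.0, -120.0),
              ("HN2", "H", ("C1", "C2", "N2"), _NH, 112.0, 60.0),
              ("C7", "C", ("C1", "C2", "N2"), 1.34, 122.0, -160.0),
              ("O7", "O", ("C2", "N2", "C7"), 1.23, 123.0, 0.0)]
        if not linked_in:
            t += [("O3", "O", ("C1", "C2", "C3"), _CO, 110.0, 120.0),
                  ("HO3", "H", ("C2", "C3", "O3"), _OH, 108.0, 180.0)]
        if rk.sulfation == 4:
            t += [("O4", "O", ("C2", "C3", "C4"), _CO, 110.0, -120.0),
                  ("S", "S", ("C3", "C4", "O4"), 1.58, 119.0, 120.0),
                  ("O1S", "O", ("C4", "O4", "S"), 1.45, 105.0, 60.0),
                  ("O2S", "O", ("C4", "O4", "S"), 1.45, 105.0, 180.0),
                  ("O3S", "O", ("C4", "O4", "S"), 1.45, 105.0, -60.0)]
        else:
            t += [("O4", "O", ("C2", "C3", "C4"), _CO, 110.0, -120.0),
                  ("HO4", "H", ("C3", "C4", "O4"), _OH, 108.0, 180.0)]
        t += [("C6", "C", ("C3", "C4", "C5"), _CC, 112.0, 120.0),
              ("O6", "O", ("C4", "C5", "C6"), _CO, 111.0, 180.0)]
        if rk.sulfation == 6:
            t += [("S", "S", ("C5", "C6", "O6"), 1.58, 119.0, 180.0),
                  ("O1S", "O", ("C6", "O6", "S"), 1.45, 105.0, 60.0),
                  ("O2S", "O", ("C6", "O6", "S"), 1.45, 105.0, 180.0),
                  ("O3S", "O", ("C6", "O6", "S"), 1.45, 105.0, -60.0)]
        else:
            t += [("HO6", "H", ("C5", "C6", "O6"), _OH, 108.0, 180.0)]
    else:  # uronic acid
        t += [("O2", "O", ("O5", "C1", "C2"), _CO, 110.0, 120.0),
              ("HO2", "H", ("C1", "C2", "O2"), _OH, 108.0, 180.0),
              ("O3", "O", ("C1", "C2", "C3"), _CO, 110.0, -120.0),
              ("HO3", "H", ("C2", "C3", "O3"), _OH, 108.0, 180.0),
              ("C6", "C", ("C3", "C4", "C5"), _CC, 112.0, 120.0),
              ("O6A", "O", ("C4", "C5", "C6"), 1.25, 117.0, -30.0),
              ("O6B", "O", ("C4", "C5", "C6"), 1.25, 117.0, 150.0)]
        if not linked_in:
            t += [("O4", "O", ("C2", "C3", "C4"), _CO, 110.0, -120.0),
                  ("HO4", "H", ("C3", "C4", "O4"), _OH, 108.0, 180.0)]
    if position == "re":
        t += [("HO1", "H", ("O5", "C1", "O1"), _OH, 108.0, 180.0)]
    return t


# ---------------------------------------------------------------------------
# the generator


def generate(spec: SyntheticSpec):
    """Build (Topology, Trajectory, ChargeMap, PlantedTruth) from a spec.

    The output is a deterministic function of the spec (including its seed):
    identical inputs give bit-identical coordinates.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nres = len(spec.chain)
    F = spec.n_frames

    # ---- sample all planted truths first
    pucker_labels, pucker_params = {}, {}
    for i, rk in enumerate(spec.chain, start=1):
        dist = spec.pucker_truth.get(i, {"4C1": 1.0})
        labels = np.array(sorted(dist))
        weights = np.array([dist[l] for l in labels])
        choice = rng.choice(len(labels), size=F, p=weights)
        lab = labels[choice]
        geo = np.array([spec.state_geometry[l] for l in labels])
        pucker_labels[i] = lab
        pucker_params[i] = geo[choice]    # (F, 3): Q, theta, phi

    linkage_components, linkage_angles = {}, {}
    shared_idx = None
    for k in range(nres - 1):
        comps = spec.linkage_truth.get(
            k, [LinkageComponent(1.0, -75.0, -110.0)]
        )
        w = np.array([c.weight for c in comps])
        if spec.linkage_correlated:
            if shared_idx is None:
                shared_idx = rng.choice(len(comps), size=F, p=w)
            idx = shared_idx
        else:
            idx = rng.choice(len(comps), size=F, p=w)
        phim = np.array([c.phi_mean for c in comps])[idx]
        psim = np.array([c.psi_mean for c in comps])[idx]
        phis = np.array([c.phi_sd for c in comps])[idx]
        psis = np.array([c.psi_sd for c in comps])[idx]
        ang = np.column_stack([
            phim + rng.standard_normal(F) * phis,
            psim + rng.standard_normal(F) * psis,
        ])
        linkage_components[k] = idx
        linkage_angles[k] = ang

    hbond_flags = [rng.random(F) < hb.fraction for hb in spec.hbond_truth]
    water_flags = None
    if spec.water_truth is not None:
        water_flags = rng.random((spec.water_truth.count, F)) < spec.water_truth.fraction

    # ---- atom bookkeeping
    atoms = []          # list[AtomRecord]
    index_of = {}       # (residue_index, atom_name) -> 0-based atom index

    def add_atom(res_i, res_name, name, element, charge=None):
        index_of[(res_i, name)] = len(atoms)
        atoms.append(AtomRecord(len(atoms) + 1, name, element, res_i, res_name, charge))

    coords_parts = []   # list of (F, 3) in atom order

    def coord_of(res_i, name):
        return coords_parts[index_of[(res_i, name)]]

    # ---- rings and chain assembly
    ring_templates = {}
    for i in range(1, nres + 1):
        p = pucker_params[i]
        ring_templates[i] = build_ring_batch(p[:, 0], p[:, 1], p[:, 2])

    placed_rings = {}
    placed_rings[1] = ring_templates[1]                      # residue 1 in local frame
    bridge_xyz = {}                                          # linkage k -> (F,3) of O1
    for k in range(nres - 1):
        donor = k + 1
        acceptor = k + 2
        acc_role = spec.chain[acceptor - 1].role
        ltype = 1 if acc_role == "uronic_acid" else 2
        ring_d = placed_rings[donor]
        o5, c1, c5 = ring_d[:, 0], ring_d[:, 1], ring_d[:, 5]
        o1 = _place(c5, o5, c1, _CO, 108.0, np.full(F, 180.0))
        bridge_xyz[k] = o1
        phi = linkage_angles[k][:, 0]
        psi = linkage_angles[k][:, 1]
        tmpl = ring_templates[acceptor]
        if ltype == 1:
            ai, bi, ci = 4, 5, 0        # C4', C5', O5'
        else:
            ai, bi, ci = 3, 4, 5        # C3', C4', C5'
        cx = _place(o5, c1, o1, _CO, 116.0, phi)
        d_ab = np.linalg.norm(tmpl[:, bi] - tmpl[:, ai], axis=-1)
        cnext = _place(c1, o1, cx, d_ab, 110.0, psi)
        # third anchor with template-internal bond/angle => congruent triple
        v1 = tmpl[:, ai] - tmpl[:, bi]
        v2 = tmpl[:, ci] - tmpl[:, bi]
        d_bc = np.linalg.norm(v2, axis=-1)
        ang_abc = np.degrees(np.arccos(np.clip(
            np.sum(v1 * v2, axis=-1)
            / (np.linalg.norm(v1, axis=-1) * d_bc), -1.0, 1.0)))
        third = _place(o1, cx, cnext, d_bc, ang_abc, np.full(F, -60.0))
        rot, shift = _rigid_from_triples(
            np.stack([tmpl[:, ai], tmpl[:, bi], tmpl[:, ci]], axis=1),
            np.stack([cx, cnext, third], axis=1),
        )
        placed_rings[acceptor] = np.einsum("fij,fkj->fki", rot, tmpl) + shift[:, None, :]

    # reducing-end free anomeric oxygen
    ring_re = placed_rings[nres]
    re_o1 = _place(ring_re[:, 5], ring_re[:, 0], ring_re[:, 1], _CO, 108.0,
                   np.full(F, 180.0))

    # ---- emit atoms residue by residue
    for i, rk in enumerate(spec.chain, start=1):
        rname = rk.name
        ring = placed_rings[i]
        for j, nm in enumerate(_RING):
            add_atom(i, rname, nm, nm[0])
            coords_parts.append(ring[:, j])
        # glycosidic / anomeric oxygen O1
        add_atom(i, rname, "O1", "O")
        coords_parts.append(bridge_xyz[i - 1] if i < nres else re_o1)
        position = "re" if i == nres else ("nre" if i == 1 else "internal")
        linked_in = i > 1
        for nm, el, (ra, rb, rc), bond, angle, torsion in _substituent_templates(
            rk, position, linked_in
        ):
            add_atom(i, rname, nm, el)
            coords_parts.append(
                _place(coord_of(i, ra), coord_of(i, rb), coord_of(i, rc),
                       bond, angle, np.full(F, torsion))
            )

    # ---- reposition planted H-bond pairs into per-frame probe pockets
    #
    # Each planted donor-acceptor pair is moved into empty space ~7 A off
    # the midpoint of the two residues' ring centroids, in the direction
    # (chosen per frame from a fixed candidate sphere) with the largest
    # clearance from every heavy atom placed so far. Inside the pocket the
    # pair is collinear: acceptor, then (2.7 A when flagged / 3.6 A when
    # not) the donor oxygen with its hydrogen pointing at the acceptor
    # (flagged) or away from it (unflagged). Both criteria of the detector
    # therefore hold exactly when flagged and both fail when not, with
    # margins (0.3 A / 0.9 A / 135 deg) far beyond the coordinate jitter.
    planted_donors = {(hb.donor_residue, hb.donor_oxygen) for hb in spec.hbond_truth}
    heavy_obstacles = [
        coords_parts[j] for j, a in enumerate(atoms) if a.element != "H"
    ]
    ring_centroid = {i: placed_rings[i].mean(axis=1) for i in range(1, nres + 1)}
    for hb, flags in zip(spec.hbond_truth, hbond_flags):
        for res_i, nm in ((hb.donor_residue, hb.donor_oxygen),
                          (hb.acceptor_residue, hb.acceptor_atom)):
            if nm in _RING or nm == "O1" or nm in ("C6", "O6A", "O6B", "S",
                                                   "O1S", "O2S", "O3S"):
                raise SyntheticSpecError(
                    f"cannot plant an H-bond on {nm!r}: ring, linkage and "
                    "charged-group atoms must stay in place"
                )
        o_idx = index_of[(hb.donor_residue, hb.donor_oxygen)]
        h_name = "H" + hb.donor_oxygen if not hb.donor_oxygen.startswith("N") \
            else "HN" + hb.donor_oxygen[1:]
        h_idx = index_of[(hb.donor_residue, h_name)]
        a_idx = index_of[(hb.acceptor_residue, hb.acceptor_atom)]
        mid = 0.5 * (ring_centroid[hb.donor_residue]
                     + ring_centroid[hb.acceptor_residue])
        u = _clearest_direction(mid, heavy_obstacles, offset=7.0)
        acc = mid + 7.0 * u
        on_o = acc + 2.7 * u                    # inside the 3.0 A cutoff
        on_h = on_o - _OH * u                   # collinear D-H...A, 180 deg
        off_o = acc + 3.6 * u                   # outside the cutoff
        off_h = off_o + _OH * u                 # and H points away (angle ~0)
        sel = flags[:, None]
        coords_parts[a_idx] = acc
        coords_parts[o_idx] = np.where(sel, on_o, off_o)
        coords_parts[h_idx] = np.where(sel, on_h, off_h)
        heavy_obstacles.extend([acc, coords_parts[o_idx]])

    # ---- waters (minimal 3-atom template, planted as donors to the solute)
    #
    # Each water donates to a free hexosamine hydroxyl oxygen (O6 on
    # 4-sulfated, O4 on 6-sulfated residues) that is moved into its own
    # probe pocket, exactly like the intramolecular planted pairs, so the
    # planted solute-water bond is the only bond the pair can form.
    if spec.water_truth is not None:
        next_res_w = nres + 1
        hex_residues = [i for i, rk in enumerate(spec.chain, start=1)
                        if rk.role == "hexosamine"]
        if spec.water_truth.count > len(hex_residues):
            raise SyntheticSpecError(
                f"at most {len(hex_residues)} waters can be planted on this "
                "chain (one free hexosamine hydroxyl each)"
            )
        for w in range(spec.water_truth.count):
            acc_res = hex_residues[w]
            acc_name = "O6" if spec.chain[acc_res - 1].sulfation == 4 else "O4"
            acc_idx = index_of[(acc_res, acc_name)]
            u = _clearest_direction(ring_centroid[acc_res], heavy_obstacles,
                                    offset=7.0)
            acc = ring_centroid[acc_res] + 7.0 * u
            coords_parts[acc_idx] = acc
            ow_near = acc + 2.7 * u
            ow_far = acc + (40.0 + 5.0 * w) * u
            sel = water_flags[w][:, None]
            ow = np.where(sel, ow_near, ow_far)
            h1 = ow - _OH * u                    # donor H toward the acceptor
            h2 = ow + _OH * u                    # second H points outward
            add_atom(next_res_w, "WAT", "O", "O")
            coords_parts.append(ow)
            add_atom(next_res_w, "WAT", "H1", "H")
            coords_parts.append(h1)
            add_atom(next_res_w, "WAT", "H2", "H")
            coords_parts.append(h2)
            heavy_obstacles.extend([acc, ow])
            next_res_w += 1

    _point_unplanted_hydrogens_away(atoms, coords_parts, index_of, planted_donors)

    # ---- counterions
    topo_probe = _build_topology(list(atoms), DEFAULT_CONVENTIONS,
                                 set_label=spec.set_label)
    ion_flags = {}
    ion_coords = []
    next_res = max(a.residue_index for a in atoms) + 1
    groups = topo_probe.charged_groups
    coms = {}
    for grp in groups:
        idx = list(grp.atom_indices)
        m = topo_probe.masses(idx)
        xyz = np.stack([coords_parts[j] for j in idx], axis=1)
        coms[(grp.kind, grp.residue_index)] = np.einsum("fak,a->fk", xyz, m) / m.sum()
    all_com = np.mean(list(coms.values()), axis=0)
    from .interactions import DEFAULT_ION_CUTOFFS

    for g, grp in enumerate(groups):
        kind = grp.kind
        if kind not in spec.ion_truth:
            continue
        flags = rng.random(F) < spec.ion_truth[kind]
        ion_flags[(kind, grp.residue_index)] = flags
        com = coms[(kind, grp.residue_index)]
        away = com - all_com
        norm = np.linalg.norm(away, axis=-1, keepdims=True)
        away = np.where(norm > 1e-9, away / np.maximum(norm, 1e-9), [[1.0, 0.0, 0.0]])
        near = com + 0.85 * DEFAULT_ION_CUTOFFS[kind] * away
        far = com + (60.0 + 7.0 * g) * away
        ion_coords.append(np.where(flags[:, None], near, far))
    if spec.ion_truth and not ion_coords:
        raise SyntheticSpecError("ion truth given but topology has no matching groups")
    for k in range(len(ion_coords)):
        add_atom(next_res, "NA+", "NA", "NA")
        coords_parts.append(ion_coords[k])
        next_res += 1
    for k in range(spec.n_background_ions if ion_coords else 0):
        add_atom(next_res, "NA+", "NA", "NA")
        coords_parts.append(np.tile([[120.0 + 8.0 * k, 0.0, 0.0]], (F, 1)))
        next_res += 1

    # ---- final assembly, jitter last
    coords = np.stack(coords_parts, axis=1)      # (F, N, 3)
    if spec.jitter_sd > 0:
        coords = coords + rng.standard_normal(coords.shape) * spec.jitter_sd

    topology = _build_topology(list(atoms), DEFAULT_CONVENTIONS,
                               set_label=spec.set_label)
    sol, ion, wat = atom_class_indices(topology)
    traj = Trajectory(coords, sol, ion, wat)
    charge_map = synthetic_charge_map(topology)
    truth = PlantedTruth(
        spec=spec,
        pucker_labels=pucker_labels,
        linkage_components=linkage_components,
        linkage_angles=linkage_angles,
        hbond_flags=hbond_flags,
        ion_flags=ion_flags,
        water_flags=water_flags,
    )
    return topology, traj, charge_map, truth


def _candidate_sphere() -> np.ndarray:
    """A fixed, deterministic set of unit directions covering the sphere."""
    g = np.array([x for x in np.ndindex(3, 3, 3)], dtype=float) - 1.0
    g = g[np.any(g != 0, axis=1)]
    g = g / np.linalg.norm(g, axis=1, keepdims=True)
    # densify with a golden-spiral layer for finer angular resolution
    k = np.arange(38)
    z = 1.0 - 2.0 * (k + 0.5) / 38
    r = np.sqrt(1.0 - z**2)
    th = np.pi * (1.0 + 5.0**0.5) * k
    spiral = np.column_stack([r * np.cos(th), r * np.sin(th), z])
    return np.vstack([g, spiral])


_CAND = _candidate_sphere()


def _clearest_direction(origin: np.ndarray, obstacles: list, offset: float) -> np.ndarray:
    """Per-frame unit direction from `origin` (F, 3) whose point at
    origin + offset*u has the largest minimum distance to all obstacle
    trajectories ((F, 3) each)."""
    obs = np.stack(obstacles, axis=1)                     # (F, M, 3)
    # obstacles that never come near the search sphere cannot decide the
    # argmax when any safe direction exists; drop them for speed
    do = np.linalg.norm(obs - origin[:, None, :], axis=-1).min(axis=0)
    keep = do < offset + 5.0
    if keep.any():
        obs = obs[:, keep]
    F = origin.shape[0]
    best = np.empty(F, dtype=int)
    step = max(1, 2_000_000 // (len(_CAND) * max(1, obs.shape[1])))
    for s in range(0, F, step):
        e = min(F, s + step)
        probe = origin[s:e, None, None, :] + offset * _CAND[None, :, None, :]
        d = np.linalg.norm(probe - obs[s:e, None, :, :], axis=-1)   # (f, C, M)
        best[s:e] = np.argmax(d.min(axis=2), axis=1)
    return _CAND[best]


def _point_unplanted_hydrogens_away(atoms, coords_parts, index_of, planted_donors):
    """Re-aim every non-planted polar hydrogen so no acceptor falls in its
    bonding cone.

    A geometric hydrogen bond needs the acceptor inside the ~45-degree cone
    around the direction the hydrogen points (angle at H > 135 deg) and
    within 3.0 A of the donor heavy atom. For each hydrogen, each frame,
    the direction from a fixed candidate sphere that maximises the smallest
    angle to every nearby acceptor is selected; with at most a handful of
    acceptors near any donor a clear cone always exists, so template
    geometry cannot create incidental hydrogen bonds."""
    near_cut = 3.3   # A; acceptors beyond this cannot pass the 3.0 A cutoff
    polar = [i for i, a in enumerate(atoms) if a.element in ("O", "N")]
    if not polar:
        return
    polar_xyz = np.stack([coords_parts[i] for i in polar], axis=1)   # (F, P, 3)
    for i, a in enumerate(atoms):
        if a.element != "H":
            continue
        parent_name = "O" + a.name[2:] if a.name.startswith("HO") else "N" + a.name[2:]
        key = (a.residue_index, parent_name)
        if key not in index_of or key in planted_donors:
            continue
        o_xyz = coords_parts[index_of[key]]
        rel = polar_xyz - o_xyz[:, None, :]                # (F, P, 3)
        d = np.linalg.norm(rel, axis=-1)
        near = (d > 1e-6) & (d < near_cut)
        if not near.any():
            continue
        ever = near.any(axis=0)                            # prune distant acceptors
        rel, d, near = rel[:, ever], d[:, ever], near[:, ever]
        dirs = rel / np.maximum(d, 1e-9)[:, :, None]
        cosm = np.einsum("fpk,ck->fpc", dirs, _CAND)
        cosm = np.where(near[:, :, None], cosm, -1.0)
        worst = cosm.max(axis=1)                           # (F, C)
        v = _CAND[np.argmin(worst, axis=1)]
        coords_parts[i] = np.where(
            near.any(axis=1)[:, None], o_xyz + _OH * v, coords_parts[i]
        )


def synthetic_charge_map(topology: Topology) -> ChargeMap:
    """Formal synthetic charges: -0.5 e on each carboxylate oxygen and the
    sulfate formal -1 e split over its three terminal oxygens; all other
    atoms neutral. These are deliberately simple bookkeeping charges for
    testing electrostatics, not force-field charges."""
    entries = {}
    for a in topology.atoms:
        key = (a.residue_name, a.name)
        if a.name in ("O6A", "O6B"):
            entries[key] = -0.5
        elif a.name in ("O1S", "O2S", "O3S"):
            entries[key] = -1.0 / 3.0
        else:
            entries.setdefault(key, 0.0)
    return ChargeMap(entries)
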
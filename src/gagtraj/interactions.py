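"""Hydrogen bonds, counterion contacts and inter-group electrostatic repulsion.

Hydrogen bonds are geometric: donor and acceptor are O or N heavy atoms,
the donor carries a covalent hydrogen (inferred by an H within 1.2 A of the
O/N), and a bond is counted when the heavy-atom distance is below the
distance cutoff (default 3.0 A) AND the D-H-A angle measured at the
hydrogen exceeds the angle cutoff (default 135 deg) — the usual defaults of
MD H-bond analysis tools.

Counterion contacts: a charged group (carboxyl or sulfate) is "in contact"
in a frame when at least one counterion lies within the kind-specific
cutoff (defaults 4.0 A for carboxyl, 4.2 A for sulfate) of the group's
mass-weighted centre of mass.

Electrostatic repulsion: the pairwise Coulomb energy summed over all atom
pairs belonging to two *different* charged groups (intra-group pairs
excluded), vacuum dielectric, no distance cutoff, in kcal/mol with the
AMBER electrostatic constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ChargeMap, DescriptorSeries, Topology, Trajectory

#: AMBER Coulomb constant, kcal A mol^-1 e^-2.
COULOMB_CONSTANT = 332.0522

#: Covalent donor-hydrogen bond inference distance, A.
DONOR_H_BOND_CUTOFF = 1.2

DEFAULT_ION_CUTOFFS = {"carboxyl": 4.0, "sulfate": 4.2}


class InteractionError(ValueError):
    pass


@dataclass(frozen=True)
class HBondCriteria:
    distance_cutoff: float = 3.0      # donor-acceptor heavy-atom distance, A
    angle_cutoff: float = 135.0       # D-H-A angle at the hydrogen, deg

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise InteractionError("H-bond cutoffs must be positive")
        if self.angle_cutoff > 180:
            raise InteractionError("angle cutoff cannot exceed 180 deg")


def _polar_atoms(topology: Topology, indices) -> np.ndarray:
    return np.array(
        [i for i in indices if topology.atoms[i].element.upper() in ("O", "N")],
        dtype=int,
    )


def _hydrogens(topology: Topology, indices) -> np.ndarray:
    return np.array(
        [i for i in indices if topology.atoms[i].element.upper() == "H"], dtype=int
    )


def _donor_h_pairs(coords: np.ndarray, heavy: np.ndarray, hydrogens: np.ndarray):
    """(donor, hydrogen) pairs by covalent-distance inference on one frame."""
    if len(heavy) == 0 or len(hydrogens) == 0:
        return []
    d = np.linalg.norm(coords[heavy][:, None, :] - coords[hydrogens][None, :, :], axis=2)
    pairs = []
    for hi, col in enumerate(d.T):
        j = int(np.argmin(col))
        if col[j] < DONOR_H_BOND_CUTOFF:
            pairs.append((int(heavy[j]), int(hydrogens[hi])))
    return pairs


def detect_hbonds(
    coords: np.ndarray,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
    scope: str = "intra",
    solute_indices=None,
    water_indices=None,
) -> list:
    """Hydrogen bonds in one frame as (donor, hydrogen, acceptor) triples.

    scope "intra": donors and acceptors both within the solute.
    scope "solute-water": bonds between the solute and water, both directions.
    """
    coords = np.asarray(coords, dtype=float)
    if solute_indices is None:
        solute_indices = [
            i for i, a in enumerate(topology.atoms)
            if _role_of(topology, a.residue_index) in ("hexosamine", "uronic_acid")
        ]
    solute_indices = np.asarray(solute_indices, dtype=int)
    sol_h = _hydrogens(topology, solute_indices)
    sol_polar = _polar_atoms(topology, solute_indices)
    if scope == "intra":
        donors = _donor_h_pairs(coords, sol_polar, sol_h)
        if not donors:
            raise InteractionError(
                "no donor hydrogens found: H-bond analysis needs explicit hydrogens"
            )
        acceptors = sol_polar
    elif scope == "solute-water":
        if water_indices is None or len(water_indices) == 0:
            raise InteractionError("solute-water scope requires water atoms")
        water_indices = np.asarray(water_indices, dtype=int)
        wat_polar = _polar_atoms(topology, water_indices)
        wat_h = _hydrogens(topology, water_indices)
        donors = _donor_h_pairs(coords, sol_polar, sol_h) + _donor_h_pairs(
            coords, wat_polar, wat_h
        )
        if not donors:
            raise InteractionError(
                "no donor hydrogens found: H-bond analysis needs explicit hydrogens"
            )
        sol_set = set(int(i) for i in sol_polar)
        acceptors = None  # resolved per donor below
    else:
        raise InteractionError(f"unknown scope {scope!r}")
    out = []
    for d_idx, h_idx in donors:
        if scope == "intra":
            acc = acceptors
        else:
            # cross bonds only: solute donor -> water acceptor and vice versa
            acc = (
                _polar_atoms(topology, water_indices)
                if int(d_idx) in sol_set
                else sol_polar
            )
        acc = acc[acc != d_idx]
        if len(acc) == 0:
            continue
        da = np.linalg.norm(coords[acc] - coords[d_idx], axis=1)
        ok = da < criteria.distance_cutoff
        if not ok.any():
            continue
        hv_d = coords[d_idx] - coords[h_idx]
        hv_a = coords[acc[ok]] - coords[h_idx]
        cosang = (hv_a @ hv_d) / (
            np.linalg.norm(hv_a, axis=1) * np.linalg.norm(hv_d) + 1e-300
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        for a_idx, angle in zip(acc[ok][ang > criteria.angle_cutoff], ang[ang > criteria.angle_cutoff]):
            out.append((int(d_idx), int(h_idx), int(a_idx)))
    return out


def _role_of(topology: Topology, residue_index: int) -> str:
    for res in topology.residues:
        if res.atom_indices and topology.atoms[res.atom_indices[0]].residue_index == residue_index:
            return res.role
    return "unknown"


@dataclass
class HBondMatrix:
    """Residue-pair summed H-bond fractions plus the mean water H-bond count.

    Cell (i, j), i != j: sum over all donor-acceptor pairs between residues
    i and j (both directions folded together) of the fraction of frames in
    which that pair is bonded; can exceed 1 when several simultaneous bonds
    exist. Diagonal: within-residue fraction.
    """

    residue_indices: np.ndarray
    matrix: np.ndarray
    water_hbonds_per_frame: float = field(default=float("nan"))

    @property
    def total_intramolecular(self) -> float:
        iu = np.triu_indices(len(self.residue_indices))
        return float(self.matrix[iu].sum())


def hbond_matrix(
    traj: Trajectory,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondMatrix:
    """Aggregate per-frame H-bond detections into residue-pair fractions."""
    coords = traj.coordinates
    sel = traj.solute_indices
    sol_h = _hydrogens(topology, sel)
    sol_polar = _polar_atoms(topology, sel)
    donors = _donor_h_pairs(coords[0], sol_polar, sol_h)
    if not donors:
        raise InteractionError(
            "no donor hydrogens found: H-bond analysis needs explicit hydrogens"
        )
    sugar = topology.sugar_residue_indices()
    res_pos = {ri: k for k, ri in enumerate(sugar)}
    nres = len(sugar)
    asym = np.zeros((nres, nres))
    nf = traj.n_frames
    for d_idx, h_idx in donors:
        acc = sol_polar[sol_polar != d_idx]
        da = np.linalg.norm(coords[:, acc, :] - coords[:, d_idx, None, :], axis=2)
        hv_d = coords[:, d_idx, :] - coords[:, h_idx, :]
        hv_a = coords[:, acc, :] - coords[:, h_idx, None, :]
        cosang = np.einsum("fak,fk->fa", hv_a, hv_d) / (
            np.linalg.norm(hv_a, axis=2) * np.linalg.norm(hv_d, axis=1)[:, None] + 1e-300
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        bonded = (da < criteria.distance_cutoff) & (ang > criteria.angle_cutoff)
        frac = bonded.mean(axis=0)   # per acceptor
        rd = res_pos[topology.atoms[d_idx].residue_index]
        for a_idx, f in zip(acc, frac):
            if f == 0.0:
                continue
            ra = res_pos[topology.atoms[a_idx].residue_index]
            asym[rd, ra] += f
    sym = asym + asym.T - np.diag(np.diag(asym))
    water_mean = float("nan")
    if len(traj.water_indices) > 0:
        counts = np.zeros(nf)
        stride = max(1, nf // 2000) if nf > 4000 else 1
        frames = range(0, nf, stride)
        for f in frames:
            counts[f] = len(
                detect_hbonds(
                    coords[f], topology, criteria, scope="solute-water",
                    solute_indices=sel, water_indices=traj.water_indices,
                )
            )
        water_mean = float(np.mean([counts[f] for f in frames]))
    return HBondMatrix(np.asarray(sugar), sym, water_mean)


@dataclass
class ContactStats:
    """Counterion contact fractions per charged group and per group kind."""

    per_group: list      # (kind, residue_index, fraction)
    per_kind: dict       # kind -> {"mean": float, "sd": float, "n_groups": int}
    cutoffs: dict


def ion_contact_fractions(
    traj: Trajectory,
    topology: Topology,
    cutoffs: dict = None,
) -> ContactStats:
    """Fraction of frames with >= 1 counterion within the kind cutoff of each
    charged group's mass-weighted centre of mass."""
    cutoffs = dict(DEFAULT_ION_CUTOFFS if cutoffs is None else cutoffs)
    if len(traj.ion_indices) == 0:
        raise InteractionError(
            "topology contains no counterions: contact fractions are undefined "
            "(this is distinct from ions never being in contact)"
        )
    if not topology.charged_groups:
        raise InteractionError("topology has no charged groups")
    ions = traj.coordinates[:, traj.ion_indices, :]
    per_group = []
    by_kind: dict = {}
    for grp in topology.charged_groups:
        idx = list(grp.atom_indices)
        masses = topology.masses(idx)
        com = np.einsum(
            "fak,a->fk", traj.coordinates[:, idx, :], masses
        ) / masses.sum()
        dmin = np.linalg.norm(ions - com[:, None, :], axis=2).min(axis=1)
        frac = float(np.mean(dmin < cutoffs[grp.kind]))
        per_group.append((grp.kind, grp.residue_index, frac))
        by_kind.setdefault(grp.kind, []).append(frac)
    per_kind = {
        kind: {
            "mean": float(np.mean(fr)),
            "sd": float(np.std(fr, ddof=0)),
            "n_groups": len(fr),
        }
        for kind, fr in by_kind.items()
    }
    return ContactStats(per_group, per_kind, cutoffs)


def electrostatic_repulsion_series(
    traj: Trajectory,
    topology: Topology,
    charges: ChargeMap,
) -> DescriptorSeries:
    """Per-frame Coulomb energy over inter-group atom pairs, kcal/mol."""
    groups = topology.charged_groups
    if len(groups) < 2:
        raise InteractionError("need at least two charged groups for repulsion energy")
    atom_idx = []
    group_id = []
    for g, grp in enumerate(groups):
        atom_idx.extend(grp.atom_indices)
        group_id.extend([g] * len(grp.atom_indices))
    atom_idx = np.asarray(atom_idx)
    group_id = np.asarray(group_id)
    q = charges.resolve(topology, atom_idx)
    ii, jj = np.triu_indices(len(atom_idx), k=1)
    inter = group_id[ii] != group_id[jj]
    ii, jj = ii[inter], jj[inter]
    xyz = traj.coordinates[:, atom_idx, :]
    r = np.linalg.norm(xyz[:, ii, :] - xyz[:, jj, :], axis=2)
    bad = r < 1e-6
    if bad.any():
        f = int(np.argwhere(bad)[0][0])
        raise InteractionError(f"zero inter-atom distance in frame {f}")
    energy = COULOMB_CONSTANT * ((q[ii] * q[jj])[None, :] / r).sum(axis=1)
    return DescriptorSeries("electrostatic_repulsion", energy, units="kcal/mol")
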
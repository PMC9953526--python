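"""Core in-memory model: atoms, topology, trajectory, charge maps, series.

Coordinates are Cartesian and in angstrom throughout. Residue indices are
1-based along the chain counted from the non-reducing end, matching the
usual PDB presentation of oligosaccharides. Trajectories are assumed to be
pre-imaged (solute whole, counterions wrapped near the solute); no periodic
boundary arithmetic is performed anywhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Standard atomic masses (u) for center-of-mass computations.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "NA": 22.990,
    "K": 39.098,
    "CL": 35.45,
    "MG": 24.305,
    "CA": 40.078,
}


class TopologyError(ValueError):
    """Raised when a structure cannot be resolved into the GAG model."""


class TrajectoryError(ValueError):
    """Raised for malformed or mismatched trajectory input."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of the topology (coordinates live in Trajectory)."""

    serial: int                # 1-based, unique
    name: str                  # e.g. "O5", "C1", "O6A", "S"
    element: str               # upper-case element symbol
    residue_index: int         # 1-based along the chain from the non-reducing end
    residue_name: str
    charge: Optional[float] = None   # elementary charges; absent unless supplied

    @property
    def mass(self) -> float:
        try:
            return ELEMENT_MASSES[self.element.upper()]
        except KeyError:
            raise TopologyError(
                f"no standard mass for element {self.element!r} (atom {self.name})"
            ) from None


@dataclass(frozen=True)
class Residue:
    name: str
    role: str                  # hexosamine | uronic_acid | ion | water
    atom_indices: tuple        # 0-based indices into Topology.atoms


@dataclass(frozen=True)
class Linkage:
    """A glycosidic linkage with its phi/psi dihedral atom quadruples.

    type 1: hexosamine(beta1->4)uronic acid, phi = O5-C1-O1-C4', psi = C1-O1-C4'-C5'
    type 2: uronic acid(beta1->3)hexosamine, phi = O5-C1-O1-C3', psi = C1-O1-C3'-C4'

    The bridging oxygen is a single atom (named O1, owned by the residue
    contributing the anomeric carbon); the quadruples are completed with the
    carbon of the next residue at the linked position.
    """

    type: int                  # 1 or 2
    phi_atoms: tuple           # four distinct 0-based atom indices
    psi_atoms: tuple
    donor_residue: int         # 1-based residue contributing C1
    acceptor_residue: int


@dataclass(frozen=True)
class ChargedGroup:
    kind: str                  # carboxyl | sulfate
    atom_indices: tuple        # 0-based
    residue_index: int

    def __post_init__(self):
        n = len(self.atom_indices)
        want = {"carboxyl": 3, "sulfate": 4}[self.kind]
        if n != want:
            raise TopologyError(f"{self.kind} group must have {want} atoms, got {n}")


@dataclass
class Topology:
    atoms: list                        # list[AtomRecord]
    residues: list                     # list[Residue], chain order, then ions/waters
    rings: dict                        # residue_index -> (O5,C1,C2,C3,C4,C5) 0-based
    linkages: list                     # list[Linkage]
    charged_groups: list               # list[ChargedGroup]
    eed_atoms: Optional[tuple] = None  # (reducing-end O1, NRE glycosidic oxygen)
    set_label: Optional[str] = None    # "Set1" | "Set2" when known

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("atom serials are not unique")
        for ri, ring in self.rings.items():
            if len(ring) != 6 or len(set(ring)) != 6:
                raise TopologyError(f"residue {ri}: ring must be 6 distinct atoms")
        for lk in self.linkages:
            for quad in (lk.phi_atoms, lk.psi_atoms):
                if len(quad) != 4 or len(set(quad)) != 4:
                    raise TopologyError("linkage quadruple must be 4 distinct atoms")
        if self.eed_atoms is not None and self.eed_atoms[0] == self.eed_atoms[1]:
            raise TopologyError("EED atoms must be two distinct atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom_index(self, residue_index: int, name: str) -> int:
        """0-based index of a named atom in a 1-based residue."""
        for i in self._residue_atoms(residue_index):
            if self.atoms[i].name == name:
                return i
        raise TopologyError(f"residue {residue_index} has no atom {name!r}")

    def _residue_atoms(self, residue_index: int) -> Sequence[int]:
        for res in self.residues:
            if res.atom_indices and self.atoms[res.atom_indices[0]].residue_index == residue_index:
                return res.atom_indices
        raise TopologyError(f"no residue with index {residue_index}")

    def sugar_residue_indices(self) -> list:
        out = []
        for res in self.residues:
            if res.role in ("hexosamine", "uronic_acid"):
                out.append(self.atoms[res.atom_indices[0]].residue_index)
        return out

    def masses(self, indices) -> np.ndarray:
        return np.array([self.atoms[i].mass for i in indices], dtype=float)


@dataclass
class Trajectory:
    """Frames x atoms x 3 coordinates (angstrom) plus atom-class index sets."""

    coordinates: np.ndarray
    solute_indices: np.ndarray
    ion_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    water_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    frame_stride_ps: float = 1.0       # metadata only

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[0] < 1:
            raise TrajectoryError("trajectory has zero frames")
        if not np.isfinite(self.coordinates).all():
            raise TrajectoryError("non-finite coordinates")
        self.solute_indices = np.asarray(self.solute_indices, dtype=int)
        self.ion_indices = np.asarray(self.ion_indices, dtype=int)
        self.water_indices = np.asarray(self.water_indices, dtype=int)
        n = self.coordinates.shape[1]
        sets = [set(self.solute_indices), set(self.ion_indices), set(self.water_indices)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise TrajectoryError("solute/ion/water index sets overlap")
        for s in sets:
            if s and (min(s) < 0 or max(s) >= n):
                raise TrajectoryError("atom index set out of range")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


class ChargeMap:
    """(residue_name, atom_name) -> partial charge in elementary charges."""

    def __init__(self, entries: dict):
        self.entries = {(str(r), str(a)): float(q) for (r, a), q in entries.items()}

    def charge(self, residue_name: str, atom_name: str) -> float:
        try:
            return self.entries[(residue_name, atom_name)]
        except KeyError:
            raise KeyError(
                f"no charge for atom {atom_name!r} in residue {residue_name!r}"
            ) from None

    def resolve(self, topology: Topology, indices) -> np.ndarray:
        """Charges for the given atoms; AtomRecord.charge wins if present."""
        out = np.empty(len(indices), dtype=float)
        for k, i in enumerate(indices):
            a = topology.atoms[i]
            out[k] = a.charge if a.charge is not None else self.charge(a.residue_name, a.name)
        return out

    def to_dict(self) -> dict:
        return {f"{r}:{a}": q for (r, a), q in sorted(self.entries.items())}

    @classmethod
    def from_dict(cls, d: dict) -> "ChargeMap":
        entries = {}
        for key, q in d.items():
            r, a = key.split(":")
            entries[(r, a)] = q
        return cls(entries)


@dataclass
class DescriptorSeries:
    """A named per-frame scalar series with summary statistics.

    Units: angstrom for RMSD/Rgyr/EED, cubic angstrom for volume,
    kcal/mol for electrostatic repulsion energy.
    """

    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return len(self.values)

    @property
    def summary(self) -> dict:
        v = self.values
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=0)),
            "variance": float(np.var(v, ddof=0)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "n": int(v.size),
        }
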
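"""File input/output: topology and trajectory parsing, report writing.

Structures come in as multi-model PDB or PQR (PQR also supplies per-atom
charges); trajectories as multi-model PDB, DCD or XTC. Parsing of the
standard formats is delegated to MDAnalysis; this module resolves the
parsed atoms into the GAG-specific model (rings, linkages, charged groups,
chain ends) using an editable residue-naming convention table, because
deposited GAG structures use several naming dialects.

The glycosidic bridge is one oxygen atom. Internally it is named O1 and
owned by the residue contributing the anomeric carbon (the residue nearer
the non-reducing end); files that instead name it O4/O3 on the acceptor
residue are also resolved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    AtomRecord,
    ChargedGroup,
    Linkage,
    Residue,
    Topology,
    Trajectory,
    TopologyError,
    TrajectoryError,
)

ION_NAMES = {"NA", "NA+", "SOD", "K", "K+", "POT", "CL", "CL-", "CLA", "MG", "CA"}
WATER_NAMES = {"WAT", "HOH", "TIP3", "SOL", "T3P"}

#: Default residue-name conventions. Keys are residue names as found in the
#: file; values give the biochemical role and, where applicable, the uronic
#: acid kind or the hexosamine sulfation position. User tables loaded from
#: JSON are merged over these defaults.
DEFAULT_CONVENTIONS = {
    # glucuronic / iduronic acid
    "GCU": {"role": "uronic_acid", "kind": "GlcA"},
    "BDP": {"role": "uronic_acid", "kind": "GlcA"},
    "GLA": {"role": "uronic_acid", "kind": "GlcA"},
    "IDR": {"role": "uronic_acid", "kind": "IdoA"},
    "IDO": {"role": "uronic_acid", "kind": "IdoA"},
    # N-acetylgalactosamine, unsulfated and 4-/6-O-sulfated
    "NGA": {"role": "hexosamine", "sulfation": None},
    "ASG": {"role": "hexosamine", "sulfation": 4},
    "NG4": {"role": "hexosamine", "sulfation": 4},
    "NG6": {"role": "hexosamine", "sulfation": 6},
    # GLYCAM-style names (0/4/6 = substitution code)
    "0YB": {"role": "hexosamine", "sulfation": None},
    "4YB": {"role": "hexosamine", "sulfation": 4},
    "6YB": {"role": "hexosamine", "sulfation": 6},
    "0GB": {"role": "uronic_acid", "kind": "GlcA"},
    "0ID": {"role": "uronic_acid", "kind": "IdoA"},
}

RING_ATOMS = ("O5", "C1", "C2", "C3", "C4", "C5")


@dataclass
class Conventions:
    """Residue-name resolution table (user-editable, JSON-serialisable)."""

    residues: dict = field(default_factory=lambda: dict(DEFAULT_CONVENTIONS))
    ions: set = field(default_factory=lambda: set(ION_NAMES))
    waters: set = field(default_factory=lambda: set(WATER_NAMES))

    def role(self, residue_name: str) -> str:
        rn = residue_name.upper()
        if rn in self.ions:
            return "ion"
        if rn in self.waters:
            return "water"
        if rn in self.residues:
            return self.residues[rn]["role"]
        known = sorted(self.residues) + sorted(self.ions) + sorted(self.waters)
        raise TopologyError(
            f"unknown residue name {residue_name!r}; known conventions: {known}"
        )

    @classmethod
    def from_json(cls, path) -> "Conventions":
        with open(path) as fh:
            data = json.load(fh)
        conv = cls()
        conv.residues.update({k.upper(): v for k, v in data.get("residues", {}).items()})
        conv.ions |= {s.upper() for s in data.get("ions", [])}
        conv.waters |= {s.upper() for s in data.get("waters", [])}
        return conv


DEFAULT = Conventions()


def _element_of(name: str, residue_name: str, conventions: Conventions) -> str:
    rn = residue_name.upper()
    if rn in conventions.ions:
        return rn.rstrip("+-")
    n = name.upper()
    if n.startswith("H") or (n and n[0].isdigit() and "H" in n):
        return "H"
    if n.startswith("S"):
        return "S"
    for el in ("C", "N", "O"):
        if n.startswith(el):
            return el
    raise TopologyError(f"cannot infer element of atom {name!r} in {residue_name!r}")


def _build_topology(atoms: list, conventions: Conventions, set_label=None) -> Topology:
    """Resolve an ordered atom list into the full GAG model."""
    residues = []
    by_res: dict = {}
    order = []
    for i, a in enumerate(atoms):
        key = a.residue_index
        if key not in by_res:
            by_res[key] = []
            order.append(key)
        by_res[key].append(i)
    for key in order:
        idx = by_res[key]
        rname = atoms[idx[0]].residue_name
        residues.append(Residue(rname, conventions.role(rname), tuple(idx)))

    def find(idx_list, name):
        for i in idx_list:
            if atoms[i].name.upper() == name:
                return i
        return None

    sugar_keys = [k for k, r in zip(order, residues) if r.role in ("hexosamine", "uronic_acid")]
    rings = {}
    for k in sugar_keys:
        ring = []
        for nm in RING_ATOMS:
            i = find(by_res[k], nm)
            if i is None:
                rname = atoms[by_res[k][0]].residue_name
                raise TopologyError(f"residue {k} ({rname}): missing ring atom {nm!r}")
            ring.append(i)
        rings[k] = tuple(ring)

    role_by_key = {k: r.role for k, r in zip(order, residues)}
    linkages = []
    for a_key, b_key in zip(sugar_keys[:-1], sugar_keys[1:]):
        donor, acceptor = a_key, b_key
        bridge = find(by_res[donor], "O1")
        acc_role = role_by_key[acceptor]
        ltype = 1 if acc_role == "uronic_acid" else 2
        pos = "C4" if ltype == 1 else "C3"
        if bridge is None:  # acceptor-side naming dialect
            bridge = find(by_res[acceptor], "O4" if ltype == 1 else "O3")
        if bridge is None:
            raise TopologyError(
                f"no glycosidic oxygen between residues {donor} and {acceptor}"
            )
        o5, c1 = rings[donor][0], rings[donor][1]
        cx = find(by_res[acceptor], pos)
        cnext = find(by_res[acceptor], "C5" if ltype == 1 else "C4")
        linkages.append(
            Linkage(
                type=ltype,
                phi_atoms=(o5, c1, bridge, cx),
                psi_atoms=(c1, bridge, cx, cnext),
                donor_residue=donor,
                acceptor_residue=acceptor,
            )
        )

    charged = []
    for k in sugar_keys:
        if role_by_key[k] == "uronic_acid":
            grp = [find(by_res[k], nm) for nm in ("C6", "O6A", "O6B")]
            if None in grp:
                missing = [nm for nm, i in zip(("C6", "O6A", "O6B"), grp) if i is None]
                raise TopologyError(f"residue {k}: incomplete carboxyl group, missing {missing}")
            charged.append(ChargedGroup("carboxyl", tuple(grp), k))
        sgrp = [find(by_res[k], nm) for nm in ("S", "O1S", "O2S", "O3S")]
        if all(i is not None for i in sgrp):
            charged.append(ChargedGroup("sulfate", tuple(sgrp), k))

    eed = None
    if len(sugar_keys) >= 2:
        re_o1 = find(by_res[sugar_keys[-1]], "O1")
        if re_o1 is None:
            raise TopologyError(
                f"residue {sugar_keys[-1]}: missing O1 at the reducing end"
            )
        nre_glyc = linkages[0].phi_atoms[2]
        eed = (re_o1, nre_glyc)

    return Topology(
        atoms=atoms,
        residues=residues,
        rings=rings,
        linkages=linkages,
        charged_groups=charged,
        eed_atoms=eed,
        set_label=set_label,
    )


def read_topology(path, conventions: Conventions = DEFAULT) -> Topology:
    """Parse a PDB (first model) or PQR file into a Topology."""
    import MDAnalysis as mda

    path = Path(path)
    u = mda.Universe(str(path))
    has_charges = path.suffix.lower() == ".pqr"
    atoms = []
    for serial, a in enumerate(u.atoms, start=1):
        rname = a.resname.strip()
        atoms.append(
            AtomRecord(
                serial=serial,
                name=a.name.strip(),
                element=_element_of(a.name.strip(), rname, conventions),
                residue_index=int(a.resid),
                residue_name=rname,
                charge=float(a.charge) if has_charges else None,
            )
        )
    return _build_topology(atoms, conventions)


def atom_class_indices(topology: Topology):
    """(solute, ion, water) 0-based atom index arrays from residue roles."""
    solute, ion, water = [], [], []
    for res in topology.residues:
        tgt = {"hexosamine": solute, "uronic_acid": solute, "ion": ion, "water": water}[res.role]
        tgt.extend(res.atom_indices)
    return (np.array(solute, dtype=int), np.array(ion, dtype=int), np.array(water, dtype=int))


def read_trajectory(paths, topology: Topology, frame_stride_ps: float = 1.0) -> Trajectory:
    """Read one or more coordinate files (multi-model PDB, DCD, XTC).

    Frames are concatenated in file order; coordinates are in angstrom.
    No periodic re-imaging is performed: the trajectory is assumed to be
    post-processed (solute whole, ions wrapped near the solute).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        frames.extend(_read_coordinate_file(Path(p), topology.n_atoms))
    if not frames:
        raise TrajectoryError("zero frames read")
    coords = np.stack(frames)
    sol, ion, wat = atom_class_indices(topology)
    return Trajectory(coords, sol, ion, wat, frame_stride_ps=frame_stride_ps)


def _read_coordinate_file(path: Path, n_atoms: int):
    import MDAnalysis as mda

    suffix = path.suffix.lower()
    if suffix in (".pdb", ".pqr", ".ent"):
        u = mda.Universe(str(path))
        if len(u.atoms) != n_atoms:
            raise TrajectoryError(
                f"{path}: atom count {len(u.atoms)} != topology {n_atoms}"
            )
        return [u.atoms.positions.astype(float).copy() for _ in u.trajectory]
    if suffix == ".dcd":
        from MDAnalysis.coordinates.DCD import DCDReader

        reader = DCDReader(str(path))
    elif suffix == ".xtc":
        from MDAnalysis.coordinates.XTC import XTCReader

        reader = XTCReader(str(path))
    else:
        raise TrajectoryError(f"unsupported trajectory format {suffix!r}")
    if reader.n_atoms != n_atoms:
        raise TrajectoryError(
            f"{path}: atom count {reader.n_atoms} != topology {n_atoms}"
        )
    out = [ts.positions.astype(float).copy() for ts in reader]
    reader.close()
    return out


def _as_universe(topology: Topology, coordinates: np.ndarray):
    import MDAnalysis as mda

    n = topology.n_atoms
    res_ids = [a.residue_index for a in topology.atoms]
    uniq = sorted(set(res_ids), key=res_ids.index)
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=[uniq.index(r) for r in res_ids],
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in topology.atoms])
    u.add_TopologyAttr("elements", [a.element for a in topology.atoms])
    u.add_TopologyAttr(
        "resnames",
        [topology.atoms[[res_ids.index(r) for r in uniq][k]].residue_name for k in range(len(uniq))],
    )
    u.add_TopologyAttr("resids", uniq)
    charges = [a.charge if a.charge is not None else 0.0 for a in topology.atoms]
    u.add_TopologyAttr("charges", charges)
    u.load_new(np.asarray(coordinates, dtype=np.float32), order="fac")
    return u


def write_trajectory_pdb(topology: Topology, traj: Trajectory, path) -> None:
    """Write all frames as a multi-model PDB."""
    import warnings

    import MDAnalysis as mda

    u = _as_universe(topology, traj.coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_pqr(topology: Topology, coordinates: np.ndarray, path) -> None:
    """Write a single frame as PQR (charges in the occupancy-style column)."""
    import warnings

    import MDAnalysis as mda

    u = _as_universe(topology, np.asarray(coordinates)[None, :, :])
    u.add_TopologyAttr("radii", [1.5] * topology.n_atoms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path)) as w:
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# report writing


def write_report(results: dict, out_dir) -> list:
    """Write a descriptor result bundle: one CSV per series/heatmap/matrix
    and one JSON summary. Returns the list of written paths."""
    import pandas as pd

    from .interactions import ContactStats, HBondMatrix
    from .model import DescriptorSeries
    from .puckering import LABELS, PuckerPopulations
    from .shape import Heatmap2D

    if not results:
        raise ValueError("empty results bundle: nothing to write")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    written = []
    summary: dict = {}
    for key in sorted(results):
        obj = results[key]
        if isinstance(obj, DescriptorSeries):
            p = out_dir / f"{key}.csv"
            pd.DataFrame({"frame": np.arange(len(obj)), "value": obj.values}).to_csv(
                p, index=False
            )
            summary[key] = {"units": obj.units, **obj.summary}
            written.append(p)
        elif isinstance(obj, Heatmap2D):
            p = out_dir / f"{key}.csv"
            _write_heatmap_csv(obj, p)
            summary[key] = {
                "x": obj.x_name, "y": obj.y_name,
                "total_probability": float(obj.probability.sum()),
            }
            written.append(p)
        elif isinstance(obj, PuckerPopulations):
            summary[key] = {
                "per_residue": {str(k): v for k, v in obj.per_residue.items()},
                "per_type": obj.per_type,
                "terminal": obj.terminal,
                "internal": obj.internal,
            }
            rows = [
                {"residue": ri, **{lab: fr[lab] for lab in LABELS}}
                for ri, fr in sorted(obj.per_residue.items())
            ]
            p = out_dir / f"{key}.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)
        elif isinstance(obj, HBondMatrix):
            p = out_dir / f"{key}.csv"
            pd.DataFrame(
                obj.matrix,
                index=obj.residue_indices,
                columns=obj.residue_indices,
            ).to_csv(p)
            summary[key] = {
                "total_intramolecular": obj.total_intramolecular,
                "water_hbonds_per_frame": None
                if np.isnan(obj.water_hbonds_per_frame)
                else obj.water_hbonds_per_frame,
            }
            written.append(p)
        elif isinstance(obj, ContactStats):
            summary[key] = {
                "per_group": [
                    {"kind": k, "residue": r, "fraction": f} for k, r, f in obj.per_group
                ],
                "per_kind": obj.per_kind,
                "cutoffs": obj.cutoffs,
            }
        elif isinstance(obj, dict):
            summary[key] = obj
        else:
            raise TypeError(f"cannot serialise result {key!r} of type {type(obj)!r}")
    p = out_dir / "summary.json"
    with open(p, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append(p)
    return written


def _write_heatmap_csv(hm, path) -> None:
    def fmt(values):
        return ",".join(format(float(v), ".17g") for v in values)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x_edges," + fmt(hm.x_edges) + "\n")
        fh.write("y_edges," + fmt(hm.y_edges) + "\n")
        for i, row in enumerate(hm.probability):
            fh.write(f"p{i}," + fmt(row) + "\n")
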
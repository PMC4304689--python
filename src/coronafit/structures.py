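"""Reading, orienting and writing protein structures.

The corona generator assumes a fixed frame: membrane normal along +z,
transmembrane mid-plane at z = 0, coordinates in Angstrom, right-handed
axes.  This module provides the PDB plumbing (via gemmi) and the rigid
alignment that puts an arbitrary input structure into that frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "GroupTable",
    "load_group_table",
    "read_structure",
    "align_to_z",
    "assign_scattering_groups",
    "write_complex",
]

TAIL_RESIDUE = "DTL"  # detergent tail bead (written as element C)
HEAD_RESIDUE = "DHD"  # detergent head bead (written as element N)


@dataclass(frozen=True)
class Atom:
    """One heavy atom (implicit hydrogens folded into ``n_e``/``v_vdw``)."""

    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    x: float
    y: float
    z: float
    element: str = ""
    n_e: float = float("nan")
    v_vdw: float = float("nan")


@dataclass
class Provenance:
    source: str = "<memory>"
    transforms: list = field(default_factory=list)  # list of (R 3x3, shift 3)


class Structure:
    """Ordered collection of atoms with per-atom scattering-group data.

    Stored column-wise (numpy arrays for numbers, lists for labels) so the
    geometry-heavy downstream code can use vectorised operations; ``atoms()``
    yields :class:`Atom` records for row-wise access.
    """

    def __init__(self, atoms: Sequence[Atom] | None = None,
                 provenance: Provenance | None = None):
        atoms = list(atoms) if atoms else []
        self.serial = np.array([a.serial for a in atoms], dtype=int)
        self.name = [a.name for a in atoms]
        self.residue_name = [a.residue_name for a in atoms]
        self.chain = [a.chain for a in atoms]
        self.residue_number = np.array([a.residue_number for a in atoms], dtype=int)
        self.coords = np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)
        if not atoms:
            self.coords = np.empty((0, 3))
        self.element = [a.element for a in atoms]
        self.n_e = np.array([a.n_e for a in atoms], dtype=float)
        self.v_vdw = np.array([a.v_vdw for a in atoms], dtype=float)
        self.provenance = provenance or Provenance()
        if len(atoms) and not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")

    def __len__(self) -> int:
        return len(self.name)

    def atoms(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield Atom(int(self.serial[i]), self.name[i], self.residue_name[i],
                       self.chain[i], int(self.residue_number[i]),
                       *map(float, self.coords[i]), self.element[i],
                       float(self.n_e[i]), float(self.v_vdw[i]))

    def copy(self) -> "Structure":
        new = Structure.__new__(Structure)
        new.serial = self.serial.copy()
        new.name = list(self.name)
        new.residue_name = list(self.residue_name)
        new.chain = list(self.chain)
        new.residue_number = self.residue_number.copy()
        new.coords = self.coords.copy()
        new.element = list(self.element)
        new.n_e = self.n_e.copy()
        new.v_vdw = self.v_vdw.copy()
        new.provenance = Provenance(self.provenance.source,
                                    list(self.provenance.transforms))
        return new

    def transformed(self, rotation: np.ndarray, shift: np.ndarray) -> "Structure":
        """Apply the rigid map x -> R x + shift; the map is recorded."""
        rotation = np.asarray(rotation, dtype=float)
        shift = np.asarray(shift, dtype=float)
        new = self.copy()
        new.coords = self.coords @ rotation.T + shift
        new.provenance.transforms.append((rotation, shift))
        return new

    def groups_assigned(self) -> bool:
        return len(self) > 0 and bool(np.all(np.isfinite(self.n_e))
                                      and np.all(self.n_e > 0)
                                      and np.all(self.v_vdw > 0))


# ---------------------------------------------------------------------------
# group lookup table

@dataclass(frozen=True)
class GroupTable:
    """Scattering-group lookup shipped as editable plain-text data files."""

    groups: dict[str, tuple[str, int, float, float]]  # label -> (element, n_h, n_e, v_vdw)
    residue_map: dict[tuple[str, str], str]           # (residue, atom) -> label

    def lookup(self, residue: str, atom: str) -> tuple[str, int, float, float]:
        label = self.residue_map[(residue.upper(), atom.upper())]
        return self.groups[label]


def load_group_table(groups_path: str | Path | None = None,
                     residues_path: str | Path | None = None) -> GroupTable:
    def _read(path, default_name):
        if path is None:
            return (resources.files("coronafit") / "data" / default_name).read_text()
        return Path(path).read_text()

    groups: dict[str, tuple[str, int, float, float]] = {}
    for line in _read(groups_path, "pseudo_atom_groups.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, elem, n_h, n_e, v = line.split("\t")
        groups[label] = (elem, int(n_h), float(n_e), float(v))

    residue_map: dict[tuple[str, str], str] = {}
    for line in _read(residues_path, "residue_groups.tsv").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, label = line.split("\t")
        residue_map[(res, atom)] = label
    return GroupTable(groups, residue_map)


# ---------------------------------------------------------------------------
# operations

def read_structure(path: str | Path, *, exclude_waters: bool = True,
                   exclude_hetero: bool = False) -> Structure:
    """Read a fixed-column PDB file.

    Alternate locations are resolved to the highest-occupancy conformer
    (first wins on ties).  Waters (and, optionally, all HETATM ligands)
    can be dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                if exclude_waters and res.is_water():
                    continue
                if exclude_hetero and res.het_flag == "H":
                    continue
                best: dict[str, gemmi.Atom] = {}
                for at in res:
                    prev = best.get(at.name)
                    if prev is None or at.occ > prev.occ:
                        best[at.name] = at
                for at in best.values():
                    atoms.append(Atom(at.serial, at.name, res.name, chain.name,
                                      res.seqid.num, at.pos.x, at.pos.y, at.pos.z,
                                      at.element.name))
        break  # first model only
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records parsed from {path}")
    return Structure(atoms, Provenance(source=str(path)))


def _inertia_axis(coords: np.ndarray) -> np.ndarray:
    """Unit axis whose covariance eigenvalue is most separated from the rest."""
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    spread = evals[2] - evals[0]
    if spread <= 0:
        raise ValueError("degenerate geometry: atoms are coincident")
    if evals[1] <= 1e-9 * evals[2]:
        raise ValueError("degenerate geometry: all atoms are collinear")
    gap_low = evals[1] - evals[0]
    gap_high = evals[2] - evals[1]
    if max(gap_low, gap_high) < 0.05 * spread:
        raise ValueError(
            "inertia eigenvalues are nearly degenerate (< 5% separation); "
            "use the two-point axis mode")
    axis = evecs[:, 2] if gap_high >= gap_low else evecs[:, 0]
    return axis / np.linalg.norm(axis)


def _rotation_to_z(axis: np.ndarray) -> np.ndarray:
    """Minimal rotation taking ``axis`` (sign-adjusted to +z hemisphere) to z."""
    axis = axis / np.linalg.norm(axis)
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s = np.linalg.norm(v)
    c = float(axis @ z)
    if s < 1e-12:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def align_to_z(s: Structure, mode: str = "auto", z_offset: float = 0.0,
               axis_points: tuple[Sequence[float], Sequence[float]] | None = None,
               slab_selection: np.ndarray | None = None) -> Structure:
    """Orient the transmembrane axis along z and centre the mid-plane at z = 0.

    Parameters
    ----------
    mode : "auto" | "two-point"
        "auto" takes the principal inertia axis (of C-alpha atoms when at
        least three are present, otherwise of all atoms) whose eigenvalue
        is most separated from the other two as the membrane normal.
        "two-point" uses the direction ``axis_points[1] - axis_points[0]``.
    z_offset : float
        Extra elevation applied after centring, to fine-tune the mid-plane
        when the hydrophobic belt is off-centre.
    slab_selection : bool array over atoms, optional
        Subset defining the transmembrane slab; its axial centroid is
        brought to z = 0 (default: all atoms).
    """
    if len(s) < 3:
        raise ValueError("need at least 3 atoms to orient a structure")
    if mode == "auto":
        ca = [i for i, n in enumerate(s.name) if n.strip().upper() == "CA"]
        pts = s.coords[ca] if len(ca) >= 3 else s.coords
        axis = _inertia_axis(pts)
    elif mode == "two-point":
        if axis_points is None:
            raise ValueError("two-point mode needs axis_points=(p1, p2)")
        p1, p2 = (np.asarray(p, dtype=float) for p in axis_points)
        if np.linalg.norm(p2 - p1) < 1e-9:
            raise ValueError("axis points are coincident")
        axis = (p2 - p1) / np.linalg.norm(p2 - p1)
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")

    rot = _rotation_to_z(axis)
    rotated = s.coords @ rot.T
    sel = slab_selection if slab_selection is not None else slice(None)
    z_mid = rotated[sel][:, 2].mean()
    shift = np.array([0.0, 0.0, z_offset - z_mid])
    # also centre laterally on the axis through the slab centroid
    xy_mid = rotated[sel][:, :2].mean(axis=0)
    shift[:2] = -xy_mid
    return s.transformed(rot, shift)


def assign_scattering_groups(s: Structure, table: GroupTable | None = None, *,
                             on_missing: str = "error") -> Structure:
    """Attach ``n_e`` and ``v_vdw`` to every atom from the lookup table.

    on_missing : "error" raises listing every offender; "skip" drops the
    unmatched atoms with a warning.
    """
    table = table or load_group_table()
    new = s.copy()
    missing: list[str] = []
    keep = np.ones(len(s), dtype=bool)
    for i in range(len(s)):
        try:
            elem, n_h, n_e, v = table.lookup(s.residue_name[i], s.name[i])
        except KeyError:
            missing.append(f"record {int(s.serial[i])}: "
                           f"{s.residue_name[i]} {s.name[i]}")
            keep[i] = False
            continue
        new.n_e[i] = n_e
        new.v_vdw[i] = v
        new.element[i] = elem
    if missing:
        msg = f"{len(missing)} atom(s) without a scattering group: " \
              + "; ".join(missing[:20]) + ("; ..." if len(missing) > 20 else "")
        if on_missing == "error":
            raise KeyError(msg)
        if on_missing != "skip":
            raise ValueError(f"on_missing must be 'error' or 'skip', got {on_missing!r}")
        warnings.warn(msg)
        return _subset(new, keep)
    return new


def _subset(s: Structure, mask: np.ndarray) -> Structure:
    new = Structure.__new__(Structure)
    idx = np.flatnonzero(mask)
    new.serial = s.serial[idx]
    new.name = [s.name[i] for i in idx]
    new.residue_name = [s.residue_name[i] for i in idx]
    new.chain = [s.chain[i] for i in idx]
    new.residue_number = s.residue_number[idx]
    new.coords = s.coords[idx]
    new.element = [s.element[i] for i in idx]
    new.n_e = s.n_e[idx]
    new.v_vdw = s.v_vdw[idx]
    new.provenance = Provenance(s.provenance.source, list(s.provenance.transforms))
    return new


def write_complex(s: Structure, corona, path: str | Path) -> None:
    """Write protein + corona beads as a single PDB file.

    Protein atoms keep their records; tail beads become HETATM residues
    ``DTL`` (element C) and head beads ``DHD`` (element N), on their own
    chains.  gemmi renumbers serials sequentially and switches to
    hybrid-36 encoding beyond 99,999 records, so large models round-trip
    without truncation.
    """
    st = gemmi.Structure()
    model = gemmi.Model("1")
    used = set(s.chain)
    for cname in dict.fromkeys(s.chain):  # preserve chain order
        chain = gemmi.Chain(cname)
        runs: list[tuple[tuple[int, str], list[int]]] = []
        for i in range(len(s)):
            if s.chain[i] != cname:
                continue
            key = (int(s.residue_number[i]), s.residue_name[i])
            if not runs or runs[-1][0] != key:
                runs.append((key, []))
            runs[-1][1].append(i)
        for (num, rname), idx in runs:
            res = gemmi.Residue()
            res.name = rname
            res.seqid = gemmi.SeqId(num, " ")
            for i in idx:
                at = gemmi.Atom()
                at.name = s.name[i]
                at.element = gemmi.Element(s.element[i] or "X")
                at.pos = gemmi.Position(*s.coords[i])
                at.occ = 1.0
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)

    def bead_chain(beads: np.ndarray, res_name: str, elem: str) -> gemmi.Chain:
        cid = next(c for c in "WVUTSRQPONMLKJIHGFEDCBAZYX0123456789"
                   if c not in used)
        used.add(cid)
        chain = gemmi.Chain(cid)
        for j, xyz in enumerate(beads, start=1):
            res = gemmi.Residue()
            res.name = res_name
            res.seqid = gemmi.SeqId(j, " ")
            res.het_flag = "H"
            at = gemmi.Atom()
            at.name = elem
            at.element = gemmi.Element(elem)
            at.pos = gemmi.Position(*xyz)
            at.occ = 1.0
            res.add_atom(at)
            chain.add_residue(res)
        return chain

    if corona is not None:
        if len(corona.tail_beads):
            model.add_chain(bead_chain(corona.tail_beads, TAIL_RESIDUE, "C"))
        if len(corona.head_beads):
            model.add_chain(bead_chain(corona.head_beads, HEAD_RESIDUE, "N"))
    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.write_text(st.make_pdb_string())
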
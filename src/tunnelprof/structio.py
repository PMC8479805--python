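"""Structure and ligand I/O, SYBYL atom typing, and Gasteiger (PEOE) charges.

Structures are held as a :class:`StructureEnsemble` — a fixed atom topology
shared by one or more coordinate snapshots (e.g. frames of a trajectory read
from a multi-model PDB file).  Ligands are held as a :class:`TypedMolecule`
carrying explicit bonds, SYBYL atom types and, once assigned, PEOE partial
charges.

PDB reading is backed by :mod:`gemmi`; mol2 reading by :mod:`MDAnalysis`
(which preserves native SYBYL types and charges).  Parameter tables (PEOE
a/b/c coefficients, scoring radii) ship as plain-text data files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError, ParseError, TopologyError, TypingError

__all__ = [
    "Atom",
    "StructureEnsemble",
    "TypedMolecule",
    "parse_pdb",
    "write_pdb",
    "read_mol2",
    "write_mol2",
    "perceive_bonds",
    "assign_sybyl_types",
    "assign_gasteiger_charges",
    "scoring_parameters",
    "covalent_radius",
]

# Covalent radii (A) used by the distance-based bond perception rule
# d < r_cov(i) + r_cov(j) + 0.45.
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_BOND_TOLERANCE = 0.45


def covalent_radius(element: str) -> float:
    try:
        return _COVALENT_RADII[element.capitalize()]
    except KeyError:
        raise TypingError(f"no covalent radius for element {element!r}") from None


@dataclass(frozen=True)
class Atom:
    """One atom of a structure or ligand.

    ``position`` is the snapshot-0 coordinate; ensembles keep per-snapshot
    coordinates separately.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    is_hetero: bool = False

    def __post_init__(self):
        if not self.element:
            raise ValueError("element must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


class StructureEnsemble:
    """Snapshots of one structure sharing an atom topology.

    Parameters
    ----------
    atoms : sequence of Atom
        The shared topology (names, residues, elements).
    coords : (n_snapshots, n_atoms, 3) array
        Coordinates per snapshot, Angstrom.
    snapshot_ids : sequence of int, optional
        Strictly increasing identifiers; defaults to 0..n-1.
    """

    def __init__(self, atoms: Sequence[Atom], coords: np.ndarray,
                 snapshot_ids: Sequence[int] | None = None):
        self.atoms = list(atoms)
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_snapshots, n_atoms, 3)")
        if coords.shape[1] != len(self.atoms):
            raise TopologyError(
                f"coords carry {coords.shape[1]} atoms but topology has {len(self.atoms)}")
        self.coords = coords
        if snapshot_ids is None:
            snapshot_ids = list(range(coords.shape[0]))
        self.snapshot_ids = [int(s) for s in snapshot_ids]
        if len(self.snapshot_ids) != coords.shape[0]:
            raise ValueError("one snapshot_id per snapshot required")
        if any(b <= a for a, b in zip(self.snapshot_ids, self.snapshot_ids[1:])):
            raise ValueError("snapshot_ids must be strictly increasing")

    @property
    def n_snapshots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def snapshot(self, snapshot_id: int) -> list[Atom]:
        """Atom list with the coordinates of the given snapshot."""
        i = self.snapshot_ids.index(snapshot_id)
        return [replace(a, position=self.coords[i, j])
                for j, a in enumerate(self.atoms)]

    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def subset(self, index: np.ndarray) -> "StructureEnsemble":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return StructureEnsemble([self.atoms[i] for i in index],
                                 self.coords[:, index], self.snapshot_ids)


@dataclass
class TypedMolecule:
    """A small molecule with explicit bonds and (optionally) types/charges."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    sybyl_types: list[str] | None = None
    charges: np.ndarray | None = None
    formal_charge: float = 0.0
    formal_charges: np.ndarray | None = None  # per-atom seed for PEOE

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atom indices")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]


# ---------------------------------------------------------------------------
# PDB read / write
# ---------------------------------------------------------------------------

def _validate_pdb_coordinates(text: str) -> None:
    # gemmi silently zero-fills unparseable coordinate columns, so malformed
    # fields are caught here, naming the offending line.
    for ln, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi]
                try:
                    float(fieldtxt)
                except ValueError:
                    raise ParseError(
                        f"line {ln}: malformed coordinate field {fieldtxt!r}") from None


def parse_pdb(text: str, hydrogen_policy: str = "keep") -> StructureEnsemble:
    """Parse (multi-model) PDB content into a :class:`StructureEnsemble`.

    One snapshot per MODEL record (a single snapshot if none).  Atom order is
    preserved.  ``hydrogen_policy`` is ``"keep"`` or ``"strip"``; heavy atoms
    are always kept.
    """
    if hydrogen_policy not in ("keep", "strip"):
        raise ValueError("hydrogen_policy must be 'keep' or 'strip'")
    _validate_pdb_coordinates(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ParseError("no models / atom records found")

    per_model: list[list[Atom]] = []
    for model in st:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for a in res:
                    atom = Atom(
                        serial=a.serial, name=a.name, element=a.element.name,
                        residue_name=res.name, residue_id=res.seqid.num,
                        chain_id=chain.name, position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        is_hetero=het)
                    if hydrogen_policy == "strip" and atom.is_hydrogen:
                        continue
                    atoms.append(atom)
        per_model.append(atoms)

    ref = per_model[0]
    for k, snap in enumerate(per_model[1:], start=2):
        if len(snap) != len(ref):
            raise TopologyError(
                f"MODEL {k} has {len(snap)} atoms, MODEL 1 has {len(ref)}")
        for a, b in zip(ref, snap):
            if (a.name, a.residue_id, a.chain_id) != (b.name, b.residue_id, b.chain_id):
                raise TopologyError(
                    f"MODEL {k}: atom ordering differs at serial {b.serial}")
    coords = np.array([[a.position for a in snap] for snap in per_model])
    return StructureEnsemble(ref, coords)


def _pdb_atom_name_field(name: str, element: str) -> str:
    if len(name) > 4:
        raise FormatError(f"atom name {name!r} exceeds the 4-character PDB field")
    # one-letter elements start in column 14 by convention
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(ensemble: StructureEnsemble) -> str:
    """Serialize an ensemble as fixed-width (multi-model) PDB text."""
    if ensemble.n_snapshots == 0 or ensemble.n_atoms == 0:
        raise ValueError("cannot write an empty ensemble")
    out = io.StringIO()
    multi = ensemble.n_snapshots > 1
    for i in range(ensemble.n_snapshots):
        if multi:
            out.write(f"MODEL     {ensemble.snapshot_ids[i] + 1:>4}\n")
        for j, a in enumerate(ensemble.atoms):
            x, y, z = ensemble.coords[i, j]
            rec = "HETATM" if a.is_hetero else "ATOM  "
            out.write(
                f"{rec}{min(a.serial, 99999):>5} {_pdb_atom_name_field(a.name, a.element)}"
                f" {a.residue_name:<3} {a.chain_id[:1] or 'A'}{a.residue_id:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{a.element:>2}\n")
        if multi:
            out.write("ENDMDL\n")
    out.write("END\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# mol2 read / write
# ---------------------------------------------------------------------------

def read_mol2(path: str) -> TypedMolecule:
    """Read a TRIPOS mol2 file (native SYBYL types and charges preserved)."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path, format="MOL2")
    atoms = []
    for i, a in enumerate(u.atoms):
        stype = str(a.type)
        element = stype.split(".")[0].capitalize()
        atoms.append(Atom(
            serial=i + 1, name=str(a.name), element=element,
            residue_name=str(a.resname)[:3], residue_id=int(a.resid),
            chain_id="A", position=np.asarray(a.position, dtype=float),
            is_hetero=True))
    bonds = []
    for b in u.bonds:
        order_txt = getattr(b, "order", "1") or "1"
        order = {"1": 1, "2": 2, "3": 3, "am": 1, "ar": 1}.get(str(order_txt), 1)
        bonds.append((int(b.atoms[0].ix), int(b.atoms[1].ix), order))
    charges = None
    if hasattr(u.atoms, "charges") and np.any(u.atoms.charges):
        charges = np.asarray(u.atoms.charges, dtype=float)
    types = [str(t) for t in u.atoms.types]
    formal = float(np.round(charges.sum())) if charges is not None else 0.0
    return TypedMolecule(atoms=atoms, bonds=bonds, sybyl_types=types,
                         charges=charges, formal_charge=formal)


def write_mol2(mol: TypedMolecule, name: str = "LIG") -> str:
    """Serialize a typed molecule as TRIPOS mol2 text."""
    if mol.sybyl_types is None:
        raise TypingError("assign SYBYL types before writing mol2")
    q = mol.charges if mol.charges is not None else np.zeros(len(mol.atoms))
    lines = ["@<TRIPOS>MOLECULE", name,
             f"{len(mol.atoms)} {len(mol.bonds)} 1", "SMALL",
             "USER_CHARGES" if mol.charges is not None else "NO_CHARGES",
             "@<TRIPOS>ATOM"]
    for i, a in enumerate(mol.atoms):
        x, y, z = a.position
        lines.append(f"{i + 1:>4} {a.name:<4} {x:>9.4f} {y:>9.4f} {z:>9.4f} "
                     f"{mol.sybyl_types[i]:<5} {a.residue_id} {a.residue_name} "
                     f"{q[i]:>8.4f}")
    lines.append("@<TRIPOS>BOND")
    for k, (i, j, order) in enumerate(mol.bonds):
        lines.append(f"{k + 1:>4} {i + 1:>4} {j + 1:>4} {order}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bond perception and SYBYL typing
# ---------------------------------------------------------------------------

def perceive_bonds(atoms: Sequence[Atom]) -> list[tuple[int, int, int]]:
    """Distance-rule bond perception: d < r_cov(i) + r_cov(j) + 0.45 A."""
    pos = np.array([a.position for a in atoms])
    if len(atoms) < 2:
        return []
    rcov = np.array([covalent_radius(a.element) for a in atoms])
    tree = cKDTree(pos)
    maxr = 2 * rcov.max() + _BOND_TOLERANCE
    bonds = []
    for i, j in sorted(tree.query_pairs(maxr)):
        d = np.linalg.norm(pos[i] - pos[j])
        if d < rcov[i] + rcov[j] + _BOND_TOLERANCE:
            bonds.append((i, j, 1))
    return bonds


def _ring_members(mol: TypedMolecule) -> set[int]:
    """Atoms in 5- or 6-membered rings (via networkx cycle basis)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from([(i, j) for i, j, _ in mol.bonds])
    members: set[int] = set()
    for cycle in nx.cycle_basis(g):
        if len(cycle) in (5, 6):
            members.update(cycle)
    return members


def assign_sybyl_types(mol: TypedMolecule) -> TypedMolecule:
    """Assign a SYBYL atom type to every atom from element + bond environment.

    Bonds are perceived from interatomic distances when absent.  The rules
    cover the organic elements that occur in lipase substrates (C, H, N, O,
    S, P, halogens); aromaticity is recognized for carbons/nitrogens in 5- or
    6-membered rings whose ring bonds are all shorter than 1.45 A.
    """
    bonds = mol.bonds if mol.bonds else perceive_bonds(mol.atoms)
    mol = replace(mol, bonds=bonds)
    n = len(mol.atoms)
    nbrs = [[] for _ in range(n)]
    order_of = {}
    for i, j, order in bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
        order_of[(i, j)] = order_of[(j, i)] = order
    pos = mol.positions
    elements = mol.elements

    ring = _ring_members(mol)

    def dist(i, j):
        return float(np.linalg.norm(pos[i] - pos[j]))

    def aromatic_carbon(i):
        if i not in ring:
            return False
        ring_nb = [j for j in nbrs[i] if j in ring and elements[j] in ("C", "N")]
        return len(ring_nb) >= 2 and all(dist(i, j) < 1.45 for j in ring_nb)

    def has_double(i):
        # explicit order, else short-bond heuristic
        for j in nbrs[i]:
            if order_of[(i, j)] == 2:
                return True
            pair = {elements[i], elements[j]}
            d = dist(i, j)
            if pair == {"C", "O"} and d < 1.30:
                return True
            if pair == {"C"} and d < 1.40 and i not in ring:
                return True
            if pair == {"C", "N"} and d < 1.32:
                return True
        return False

    types: list[str] = []
    for i, a in enumerate(mol.atoms):
        el = a.element
        deg = len(nbrs[i])
        heavy_deg = sum(1 for j in nbrs[i] if elements[j] not in ("H", "D"))
        if el in ("H", "D"):
            t = "H"
        elif el == "C":
            if aromatic_carbon(i):
                t = "C.ar"
            elif deg >= 4:
                t = "C.3"
            elif deg == 3:
                t = "C.2" if has_double(i) else "C.3"
            elif deg == 2:
                t = "C.1" if not has_double(i) and heavy_deg == 2 else "C.2"
            else:
                t = "C.3"
        elif el == "O":
            if deg <= 1:
                carb = nbrs[i][0] if nbrs[i] else None
                if carb is not None and elements[carb] == "C":
                    o1 = [j for j in nbrs[carb]
                          if elements[j] == "O" and len(nbrs[j]) == 1]
                    t = "O.co2" if len(o1) >= 2 else "O.2"
                else:
                    t = "O.3"
            else:
                t = "O.3"
        elif el == "N":
            if deg >= 4:
                t = "N.4"
            elif i in ring and any(
                    elements[j] == "C" and j in ring and dist(i, j) < 1.40
                    for j in nbrs[i]):
                t = "N.ar"
            elif deg == 3:
                carbonyl = any(
                    elements[j] == "C" and any(
                        elements[k] == "O" and len(nbrs[k]) == 1 and dist(j, k) < 1.30
                        for k in nbrs[j])
                    for j in nbrs[i])
                t = "N.am" if carbonyl else "N.3"
            elif deg == 2:
                t = "N.2"
            else:
                t = "N.1"
        elif el == "S":
            o_nb = sum(1 for j in nbrs[i] if elements[j] == "O" and len(nbrs[j]) == 1)
            t = {0: "S.3", 1: "S.o"}.get(o_nb, "S.o2") if deg > 2 else \
                ("S.2" if deg == 1 else "S.3")
        elif el == "P":
            t = "P.3"
        elif el in ("F", "Cl", "Br", "I"):
            t = el
        else:
            raise TypingError(
                f"no SYBYL mapping for element {el!r} (atom {a.serial} {a.name})")
        types.append(t)
    return replace(mol, sybyl_types=types)


# ---------------------------------------------------------------------------
# Gasteiger PEOE charges
# ---------------------------------------------------------------------------

def _load_table(fname: str) -> dict:
    out = {}
    text = resources.files("tunnelprof.data").joinpath(fname).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out[parts[0]] = tuple(float(x) for x in parts[1:])
    return out


_PEOE_PARAMS = _load_table("peoe.tsv")
# cation electronegativity of hydrogen uses the method's special value
_CHI_PLUS_H = 20.02


def assign_gasteiger_charges(mol: TypedMolecule, n_iter: int = 6) -> TypedMolecule:
    """Iterative PEOE partial charges with damping (1/2)^n.

    Electronegativity per atom is chi(q) = a + b q + c q^2; each iteration n
    transfers (chi_j - chi_i)/chi_plus * (1/2)^n across every bond, where
    chi_plus is the cation electronegativity of the less electronegative
    partner (20.02 for hydrogen).  Total charge is conserved exactly.

    The per-iteration maximum charge transfer is recorded on the returned
    molecule as ``peoe_convergence_``.
    """
    if mol.sybyl_types is None:
        raise TypingError("assign SYBYL types before computing PEOE charges")
    for t in mol.sybyl_types:
        if t not in _PEOE_PARAMS:
            raise TypingError(f"no PEOE parameters for SYBYL type {t!r}")
    abc = np.array([_PEOE_PARAMS[t] for t in mol.sybyl_types])
    a, b, c = abc[:, 0], abc[:, 1], abc[:, 2]
    chi_plus = a + b + c
    chi_plus = np.where([t == "H" for t in mol.sybyl_types], _CHI_PLUS_H, chi_plus)

    if mol.formal_charges is not None:
        q = np.asarray(mol.formal_charges, dtype=float).copy()
    else:
        q = np.zeros(len(mol.atoms))
        q += mol.formal_charge / len(mol.atoms)

    bonds = [(i, j) for i, j, _ in mol.bonds]
    convergence = []
    for it in range(1, n_iter + 1):
        damp = 0.5 ** it
        chi = a + b * q + c * q * q
        dq = np.zeros_like(q)
        max_step = 0.0
        for i, j in bonds:
            if chi[i] == chi[j]:
                continue
            lo = i if chi[i] < chi[j] else j
            step = abs(chi[j] - chi[i]) / chi_plus[lo] * damp
            # the less electronegative atom donates electron density
            if lo == i:
                dq[i] += step
                dq[j] -= step
            else:
                dq[j] += step
                dq[i] -= step
            max_step = max(max_step, step)
        q += dq
        convergence.append(max_step)

    out = replace(mol, charges=q)
    out.peoe_convergence_ = convergence
    return out


# ---------------------------------------------------------------------------
# Scoring atom classes
# ---------------------------------------------------------------------------

_VINA_RADII = {k: v[0] for k, v in _load_table("vina_atoms.tsv").items()}
_ACCEPTOR_TYPES = {"O.3", "O.2", "O.co2", "N.1", "N.2", "N.ar"}
_HALOGENS = {"F", "Cl", "Br", "I"}


def scoring_parameters(sybyl_type: str, bonded_elements: Iterable[str] = ()):
    """Scoring class (vdW radius, hydrophobic/donor/acceptor flags) for an atom.

    Carbon is hydrophobic iff bonded only to carbon/hydrogen; halogens are
    hydrophobic; N/O are donors iff bearing a polar hydrogen, acceptors per
    SYBYL type.
    """
    from .vinascore import ScoringAtomClass

    element = sybyl_type.split(".")[0].capitalize()
    bonded = [e.capitalize() for e in bonded_elements]
    if element not in _VINA_RADII:
        raise TypingError(f"no scoring parameters for type {sybyl_type!r}")
    radius = _VINA_RADII[element]
    if element == "C":
        hydrophobic = all(e in ("C", "H", "D") for e in bonded)
    else:
        hydrophobic = element in _HALOGENS
    donor = element in ("N", "O") and any(e in ("H", "D") for e in bonded)
    acceptor = element == "O" or (element == "N" and sybyl_type in _ACCEPTOR_TYPES)
    return ScoringAtomClass(vdw_radius=radius, hydrophobic=hydrophobic,
                            donor=donor, acceptor=acceptor)


def molecule_scoring_classes(mol: TypedMolecule):
    """Scoring classes for the heavy atoms of a typed molecule.

    Returns (heavy_indices, [ScoringAtomClass]); charges are attached when
    the molecule has them.
    """
    if mol.sybyl_types is None:
        raise TypingError("assign SYBYL types first")
    elements = mol.elements
    classes = []
    heavy = mol.heavy_indices()
    for i in heavy:
        bonded = [elements[j] for j in mol.neighbors(i)]
        cls = scoring_parameters(mol.sybyl_types[i], bonded)
        if mol.charges is not None:
            cls = replace(cls, charge=float(mol.charges[i]))
        classes.append(cls)
    return heavy, classes
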
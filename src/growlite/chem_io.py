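"""Molecular data model and readers/writers for PDB and SDF/MOL files.

The in-memory model is deliberately small: atoms with coordinates, elements
and vdW radii, plus an explicit bond list.  Receptors are read from PDB via
gemmi (first model, altloc A, waters split off into their own list); ligands
and fragment libraries are read from SDF via RDKit.  All frames are treated
as already aligned -- no superposition is ever performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .config import COVALENT_RADII, GrowConfig, vdw_radius
from .errors import FormatError, InputError, ValenceError

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: Standard single-bonded valences used for open-valence detection.
STANDARD_VALENCE = {
    "H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class Atom:
    """One atom: element, position (Angstrom) and bookkeeping flags."""

    index: int
    element: str
    position: np.ndarray
    is_water: bool = False
    vdw_radius: float = 1.70
    formal_charge: int = 0
    attached_hydrogens: int = 0
    residue: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates for atom {self.index}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class Molecule:
    """A molecule as an atom list plus (i, j, order) bonds."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if i == j:
                raise ValueError("self-bond")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond index out of range")

    # -- geometry ----------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> "Molecule":
        atoms = [replace(a, position=np.array(p)) for a, p in zip(self.atoms, xyz)]
        return Molecule(atoms, list(self.bonds), self.name)

    def translated(self, shift: np.ndarray) -> "Molecule":
        return self.set_coords(self.coords + np.asarray(shift, dtype=float))

    # -- topology ----------------------------------------------------------
    @property
    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def explicit_hydrogens(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.atoms[j].element == "H"]

    def bond_order_sum(self, i: int) -> float:
        return sum(o for a, b, o in self.bonds if i in (a, b))

    def open_valence(self, i: int) -> int:
        """Number of free bonding slots at atom ``i`` (implicit H count or
        missing valence)."""
        atom = self.atoms[i]
        if atom.attached_hydrogens > 0:
            return atom.attached_hydrogens
        std = STANDARD_VALENCE.get(atom.element)
        if std is None:
            return 0
        used = self.bond_order_sum(i) + atom.attached_hydrogens
        return max(0, int(round(std + atom.formal_charge - used)))

    def graph(self, heavy_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            if heavy_only and a.element == "H":
                continue
            g.add_node(a.index, element=a.element)
        for i, j, o in self.bonds:
            if heavy_only and (self.atoms[i].element == "H" or self.atoms[j].element == "H"):
                continue
            g.add_edge(i, j, order=o)
        return g

    def remove_atoms(self, indices: set[int]) -> tuple["Molecule", dict[int, int]]:
        """Return a copy without ``indices`` plus the old->new index map."""
        keep = [a for a in self.atoms if a.index not in indices]
        idx_map = {a.index: k for k, a in enumerate(keep)}
        atoms = [replace(a, index=k) for k, a in enumerate(keep)]
        bonds = [
            (idx_map[i], idx_map[j], o)
            for i, j, o in self.bonds
            if i in idx_map and j in idx_map
        ]
        return Molecule(atoms, bonds, self.name), idx_map

    def n_components(self) -> int:
        g = self.graph()
        return nx.number_connected_components(g) if g.number_of_nodes() else 0


@dataclass
class BindingSite:
    """A receptor (waters split off) in one alignment frame."""

    receptor: Molecule
    waters: list[Atom] = field(default_factory=list)
    frame_id: str = ""

    def __post_init__(self) -> None:
        for w in self.waters:
            if not w.is_water:
                raise ValueError("waters must be flagged is_water")
        if any(a.is_water for a in self.receptor.atoms):
            raise ValueError("receptor must not contain water atoms")

    def without_waters(self, indices: set[int]) -> "BindingSite":
        kept = [w for k, w in enumerate(self.waters) if k not in indices]
        return BindingSite(self.receptor, kept, self.frame_id)


@dataclass
class CoreAnchor:
    """The frozen core with one attachment atom and a growth direction."""

    core: Molecule
    attachment_atom: int
    growth_vector: np.ndarray
    frozen: bool = True

    def __post_init__(self) -> None:
        self.growth_vector = np.asarray(self.growth_vector, dtype=float)
        norm = np.linalg.norm(self.growth_vector)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("growth_vector must be unit norm")

    @property
    def attachment_point(self) -> np.ndarray:
        return self.core.atoms[self.attachment_atom].position


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str, config: GrowConfig | None = None) -> BindingSite:
    """Read a binding site from a PDB file.

    Keeps the first model and altloc A only.  HOH/WAT residues go to the
    ``waters`` list (oxygen atoms); other HETATM residues are dropped unless
    named in ``config.receptor_hetnames``.  Hydrogens are kept if present.
    """
    config = config or GrowConfig()
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"no model found in {path}")
    model = structure[0]

    receptor_atoms: list[Atom] = []
    water_atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            is_water = resname in WATER_RESNAMES
            is_het = residue.het_flag == "H"
            if is_het and not is_water and resname not in config.receptor_hetnames:
                continue
            for atom in residue:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                element = atom.element.name
                if element not in STANDARD_VALENCE and element not in ("",):
                    log.warning("unknown element %r, using fallback vdW radius", element)
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if is_water:
                    if element != "O":
                        continue
                    water_atoms.append(
                        Atom(len(water_atoms), element, pos, is_water=True,
                             vdw_radius=vdw_radius(element), residue=resname)
                    )
                else:
                    receptor_atoms.append(
                        Atom(len(receptor_atoms), element, pos,
                             vdw_radius=vdw_radius(element), residue=resname)
                    )
    if not receptor_atoms and not water_atoms:
        raise FormatError(f"no atoms read from {path}")
    receptor = Molecule(receptor_atoms, [], name=str(path))
    frame_id = _stem(path)
    return BindingSite(receptor, water_atoms, frame_id=frame_id)


def write_pdb(site: BindingSite, path: str) -> None:
    """Write a binding site (receptor + waters) to a PDB file."""
    structure = gemmi.Structure()
    structure.name = site.frame_id or "site"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for k, atom in enumerate(site.receptor.atoms):
        res = gemmi.Residue()
        res.name = atom.residue or "UNK"
        res.het_flag = "A"  # write as ATOM so readers keep wall/receptor atoms
        res.seqid = gemmi.SeqId(k + 1, " ")
        ga = gemmi.Atom()
        ga.name = f"{atom.element}{k % 100}"
        ga.element = gemmi.Element(atom.element)
        ga.pos = gemmi.Position(*atom.position)
        res.add_atom(ga)
        chain.add_residue(res)
    model.add_chain(chain)
    wchain = gemmi.Chain("W")
    offset = len(site.receptor.atoms)
    for k, atom in enumerate(site.waters):
        res = gemmi.Residue()
        res.name = "HOH"
        res.seqid = gemmi.SeqId(offset + k + 1, " ")
        res.het_flag = "H"
        ga = gemmi.Atom()
        ga.name = "O"
        ga.element = gemmi.Element("O")
        ga.pos = gemmi.Position(*atom.position)
        res.add_atom(ga)
        wchain.add_residue(res)
    model.add_chain(wchain)
    structure.add_model(model)
    structure.write_pdb(str(path))


def _stem(path: str) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# ---------------------------------------------------------------------------
# SDF / MOL via RDKit
# ---------------------------------------------------------------------------

_BOND_ORDER_TO_RDKIT = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    1.5: Chem.BondType.AROMATIC,
}


def from_rdkit(mol: Chem.Mol, name: str = "") -> Molecule:
    """Convert an RDKit molecule (with one conformer) to a :class:`Molecule`."""
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Chem.KekulizeException:
        pass
    conf = mol.GetConformer()
    atoms = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        pos = np.array(conf.GetAtomPosition(i))
        element = atom.GetSymbol()
        atoms.append(
            Atom(i, element, pos, vdw_radius=vdw_radius(element),
                 formal_charge=atom.GetFormalCharge(),
                 attached_hydrogens=atom.GetTotalNumHs(includeNeighbors=False))
        )
    bonds = []
    for bond in mol.GetBonds():
        order = bond.GetBondTypeAsDouble()
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), float(order)))
    label = name or (mol.GetProp("_Name") if mol.HasProp("_Name") else "")
    return Molecule(atoms, bonds, label)


def to_rdkit(mol: Molecule, sanitize: bool = True) -> Chem.Mol:
    """Convert a :class:`Molecule` to an RDKit molecule with a 3D conformer."""
    rw = Chem.RWMol()
    for atom in mol.atoms:
        ra = Chem.Atom(atom.element)
        ra.SetFormalCharge(atom.formal_charge)
        ra.SetNumExplicitHs(atom.attached_hydrogens)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, _BOND_ORDER_TO_RDKIT.get(float(order), Chem.BondType.SINGLE))
    out = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(out)
    conf = Chem.Conformer(len(mol.atoms))
    for atom in mol.atoms:
        conf.SetAtomPosition(atom.index, atom.position.tolist())
    out.AddConformer(conf)
    if mol.name:
        out.SetProp("_Name", mol.name)
    return out


def read_sdf(path: str) -> list[Molecule]:
    """Read all records of an SDF (or single-record MOL) file.

    Records that fail RDKit sanitization are retried unsanitized; records
    that cannot be read at all are skipped with a logged warning.  Zero
    readable records raise :class:`InputError`.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    mols: list[Molecule] = []
    for k in range(len(supplier)):
        try:
            raw = supplier[k]
        except (RuntimeError, ValueError):
            raw = None
        if raw is None:
            # retry without sanitization before giving up on the record
            try:
                text = supplier.GetItemText(k)
                raw = Chem.MolFromMolBlock(text, removeHs=False, sanitize=False)
            except (RuntimeError, ValueError):
                raw = None
        if raw is None:
            log.warning("skipping unreadable record %d of %s", k, path)
            continue
        try:
            mols.append(from_rdkit(raw))
        except (ValueError, RuntimeError) as exc:
            log.warning("skipping record %d of %s: %s", k, path, exc)
    if not mols:
        raise InputError(f"no readable records in {path}")
    for m in mols:
        if not m.name:
            m.name = f"{_stem(path)}_{mols.index(m)}"
    return mols


def write_sdf(mols: list[Molecule], path: str,
              tags: list[dict[str, object]] | None = None) -> None:
    """Write molecules to SDF; per-record SD tags carry score metadata."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for k, mol in enumerate(mols):
        rd = to_rdkit(mol, sanitize=False)
        rd.UpdatePropertyCache(strict=False)
        if tags and k < len(tags):
            for key, value in tags[k].items():
                rd.SetProp(str(key), str(value))
        writer.write(rd)
    writer.close()


# ---------------------------------------------------------------------------
# Core marking
# ---------------------------------------------------------------------------

def mark_core(mol: Molecule, attachment_atom: int) -> CoreAnchor:
    """Mark ``attachment_atom`` of ``mol`` as the growth position.

    If the atom carries explicit hydrogens the lowest-index one is removed
    and the growth vector points along the former bond.  Otherwise an
    idealized open-valence direction (opposite the mean of the remaining
    bond vectors) is used.  A saturated atom raises :class:`ValenceError`.
    """
    if not (0 <= attachment_atom < len(mol.atoms)):
        raise InputError(f"attachment atom {attachment_atom} out of range")
    explicit_h = mol.explicit_hydrogens(attachment_atom)
    pos = mol.atoms[attachment_atom].position
    if explicit_h:
        h_idx = explicit_h[0]
        direction = mol.atoms[h_idx].position - pos
        norm = np.linalg.norm(direction)
        if norm < 1e-8:
            raise ValenceError("degenerate H position at attachment atom")
        core, idx_map = mol.remove_atoms({h_idx})
        return CoreAnchor(core, idx_map[attachment_atom], direction / norm)
    if mol.open_valence(attachment_atom) < 1:
        raise ValenceError(
            f"atom {attachment_atom} ({mol.atoms[attachment_atom].element}) is saturated"
        )
    neighbors = mol.neighbors(attachment_atom)
    if not neighbors:
        direction = np.array([1.0, 0.0, 0.0])
    else:
        vecs = []
        for j in neighbors:
            v = mol.atoms[j].position - pos
            n = np.linalg.norm(v)
            if n > 1e-8:
                vecs.append(v / n)
        mean = -np.sum(vecs, axis=0)
        norm = np.linalg.norm(mean)
        if norm < 1e-8:
            # neighbors are symmetric around the atom; pick any perpendicular
            ref = np.array([1.0, 0.0, 0.0])
            v0 = vecs[0]
            perp = ref - np.dot(ref, v0) * v0
            if np.linalg.norm(perp) < 1e-8:
                perp = np.array([0.0, 1.0, 0.0])
            mean, norm = perp, np.linalg.norm(perp)
        direction = mean / norm
    core = Molecule([replace(a) for a in mol.atoms], list(mol.bonds), mol.name)
    if core.atoms[attachment_atom].attached_hydrogens > 0:
        core.atoms[attachment_atom].attached_hydrogens -= 1
    return CoreAnchor(core, attachment_atom, direction)


def new_bond_length(elem_a: str, elem_b: str) -> float:
    """Idealized single-bond length as the covalent-radii sum."""
    return COVALENT_RADII.get(elem_a, 0.76) + COVALENT_RADII.get(elem_b, 0.76)
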
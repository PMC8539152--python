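"""Molecular-graph model and structure readers.

The model deliberately stores the structural conventions the group grammar is
written against, which differ from the usual toolkit defaults in three ways:

* only six-membered rings carry aromatic bonds (benzene, pyridine,
  pyridinium, ...); five-membered heteroaromatics such as pyrrole, furan and
  thiophene are stored in a Kekule (alternating single/double) form,
* the positive charge of amidinium, guanidinium and imidazolium fragments
  sits on the carbon between the nitrogen atoms, and the C-N bonds of that
  fragment are aromatic,
* hydrogens are always explicit, and amino acids / guanidines bearing a
  carboxylic acid may be converted to their zwitterion.

Hybridization is derived from the bond pattern (one double bond -> sp2, a
triple bond or two cumulated double bonds -> sp, aromatic bond -> aromatic),
not taken from a perception model, because the group grammar is defined in
those terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .errors import ParseError, UnsupportedElement

RDLogger.DisableLog("rdApp.*")

SUPPORTED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "P", "S", "Si", "F", "Cl", "Br", "I"]
)

#: bond order codes; AROMATIC follows the MDL ctab convention
SINGLE, DOUBLE, TRIPLE, AROMATIC = 1, 2, 3, 4

_HYBRIDIZATIONS = ("sp3", "sp2", "sp", "aromatic", "none")


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    hybridization: str = "none"
    is_aromatic: bool = False
    coords: Optional[np.ndarray] = None
    index: int = -1


@dataclass
class Bond:
    i: int
    j: int
    order: int = SINGLE

    def other(self, idx: int) -> int:
        return self.j if idx == self.i else self.i


class Molecule:
    """Explicit-hydrogen molecular graph (possibly multi-component)."""

    def __init__(self, atoms: Sequence[Atom], bonds: Sequence[Bond], name: str = "",
                 has_3d: bool = False):
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.name = name
        self.has_3d = has_3d
        for i, a in enumerate(self.atoms):
            a.index = i
        self._adj: Optional[list[list[Bond]]] = None
        self.refresh()

    # -- derived structure ------------------------------------------------

    def refresh(self) -> None:
        """Rebuild adjacency and re-derive hybridization from bond orders."""
        adj: list[list[Bond]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.i].append(b)
            adj[b.j].append(b)
        self._adj = adj
        for a in self.atoms:
            incident = adj[a.index]
            orders = [b.order for b in incident]
            if AROMATIC in orders:
                a.hybridization = "aromatic"
                a.is_aromatic = True
                continue
            a.is_aromatic = False
            if a.element in ("C", "N"):
                n_double = orders.count(DOUBLE)
                n_triple = orders.count(TRIPLE)
                if n_triple or n_double >= 2:
                    a.hybridization = "sp"
                elif n_double == 1:
                    a.hybridization = "sp2"
                else:
                    a.hybridization = "sp3"
            else:
                a.hybridization = "none"

    def bonds_of(self, idx: int) -> list[Bond]:
        return self._adj[idx]

    def neighbors(self, idx: int) -> list[int]:
        return [b.other(idx) for b in self._adj[idx]]

    def degree(self, idx: int) -> int:
        return len(self._adj[idx])

    def bond_between(self, i: int, j: int) -> Optional[Bond]:
        for b in self._adj[i]:
            if b.other(i) == j:
                return b
        return None

    @property
    def net_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    def formula(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.atoms:
            out[a.element] = out.get(a.element, 0) + 1
        return out

    def components(self) -> list[list[int]]:
        """Connected components as lists of atom indices."""
        seen = [False] * len(self.atoms)
        comps = []
        for start in range(len(self.atoms)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                i = stack.pop()
                comp.append(i)
                for j in self.neighbors(i):
                    if not seen[j]:
                        seen[j] = True
                        stack.append(j)
            comps.append(sorted(comp))
        return comps

    def valence(self, idx: int) -> int:
        """Sum of bond orders; aromatic bonds counted as 1.5 then rounded."""
        tot = 0.0
        for b in self._adj[idx]:
            tot += 1.5 if b.order == AROMATIC else b.order
        return int(round(tot))

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.atoms[i].coords - self.atoms[j].coords))

    def angle(self, i: int, j: int, k: int) -> float:
        """Angle at j in degrees (requires coordinates)."""
        u = self.atoms[i].coords - self.atoms[j].coords
        v = self.atoms[k].coords - self.atoms[j].coords
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    def rings(self) -> list[list[int]]:
        """Smallest set of smallest rings (atom-index lists, ring order)."""
        rd = _to_rdkit(self, sanitize=False)
        return [list(r) for r in Chem.GetSymmSSSR(rd)]

    def copy(self) -> "Molecule":
        atoms = [Atom(a.element, a.formal_charge, a.hybridization, a.is_aromatic,
                      None if a.coords is None else a.coords.copy(), a.index)
                 for a in self.atoms]
        bonds = [Bond(b.i, b.j, b.order) for b in self.bonds]
        return Molecule(atoms, bonds, self.name, self.has_3d)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Molecule({self.name!r}, n_atoms={len(self.atoms)}, n_bonds={len(self.bonds)})"


# -- RDKit conversion -----------------------------------------------------


def _check_elements(rdmol: Chem.Mol) -> None:
    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() not in SUPPORTED_ELEMENTS:
            raise UnsupportedElement(f"element {atom.GetSymbol()!r} is not supported")


def _aromatic_six_rings(rdmol: Chem.Mol) -> tuple[set[int], set[int]]:
    """Bond/atom indices belonging to fully aromatic six-membered rings."""
    ri = rdmol.GetRingInfo()
    arom_bonds: set[int] = set()
    arom_atoms: set[int] = set()
    for atoms, bonds in zip(ri.AtomRings(), ri.BondRings()):
        if len(atoms) != 6:
            continue
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in atoms) and all(
            rdmol.GetBondWithIdx(b).GetIsAromatic() for b in bonds
        ):
            arom_bonds.update(bonds)
            arom_atoms.update(atoms)
    return arom_bonds, arom_atoms


_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: SINGLE,
    Chem.BondType.DOUBLE: DOUBLE,
    Chem.BondType.TRIPLE: TRIPLE,
}


def from_rdkit(rdmol: Chem.Mol, name: str = "", keep_coords: bool = True) -> Molecule:
    """Convert a sanitized RDKit molecule, applying the aromaticity model."""
    _check_elements(rdmol)
    arom_bonds, _ = _aromatic_six_rings(rdmol)
    kek = Chem.Mol(rdmol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:  # pragma: no cover - exotic input
        raise ParseError(f"cannot kekulize structure: {exc}") from exc

    conf = None
    has_3d = False
    if keep_coords and rdmol.GetNumConformers():
        conf = rdmol.GetConformer()
        has_3d = bool(conf.Is3D()) or any(
            abs(conf.GetAtomPosition(i).z) > 1e-6 for i in range(rdmol.GetNumAtoms())
        )
        if not has_3d:
            conf = None

    atoms = []
    for atom in rdmol.GetAtoms():
        coords = None
        if conf is not None:
            p = conf.GetAtomPosition(atom.GetIdx())
            coords = np.array([p.x, p.y, p.z])
        atoms.append(Atom(atom.GetSymbol(), atom.GetFormalCharge(), coords=coords))
    bonds = []
    for bond in rdmol.GetBonds():
        if bond.GetIdx() in arom_bonds:
            order = AROMATIC
        else:
            ktype = kek.GetBondWithIdx(bond.GetIdx()).GetBondType()
            if ktype not in _ORDER_FROM_RDKIT:
                raise ParseError(f"unsupported bond type {ktype}")
            order = _ORDER_FROM_RDKIT[ktype]
        bonds.append(Bond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))
    return Molecule(atoms, bonds, name=name, has_3d=has_3d)


def _to_rdkit(mol: Molecule, sanitize: bool = True) -> Chem.Mol:
    """Back-conversion used for ring perception, depiction and embedding."""
    em = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        em.AddAtom(ra)
    order_map = {
        SINGLE: Chem.BondType.SINGLE,
        DOUBLE: Chem.BondType.DOUBLE,
        TRIPLE: Chem.BondType.TRIPLE,
        AROMATIC: Chem.BondType.AROMATIC,
    }
    for b in mol.bonds:
        em.AddBond(b.i, b.j, order_map[b.order])
        if b.order == AROMATIC:
            em.GetAtomWithIdx(b.i).SetIsAromatic(True)
            em.GetAtomWithIdx(b.j).SetIsAromatic(True)
            em.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    rd = em.GetMol()
    if sanitize:
        Chem.SanitizeMol(
            rd,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
            ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
        )
    else:
        rd.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(rd)
    return rd


# -- readers --------------------------------------------------------------


def parse_smiles(smiles: str, name: str = "") -> Molecule:
    """Parse a SMILES string into an explicit-hydrogen molecular graph."""
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    _check_elements(rdmol)
    rdmol = Chem.AddHs(rdmol)
    return from_rdkit(rdmol, name=name or smiles, keep_coords=False)


def parse_molfile(text: str, name: str = "") -> Molecule:
    """Parse one MDL MOL (V2000) block, keeping 3D coordinates when present."""
    if "V3000" in text.splitlines()[3] if len(text.splitlines()) > 3 else False:
        raise ParseError("V3000 connection tables are not supported")
    rdmol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=False)
    if rdmol is None:
        # retry without sanitization: tolerates the package's own aromatic
        # amidinium bonds which have no Kekule counterpart
        rdmol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
        if rdmol is None:
            raise ParseError("malformed MOL block")
        rdmol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(rdmol)
        _check_elements(rdmol)
        return _from_unsanitized(rdmol, name or rdmol.GetProp("_Name"))
    _check_elements(rdmol)
    rdmol = Chem.AddHs(rdmol, addCoords=rdmol.GetNumConformers() > 0)
    return from_rdkit(rdmol, name=name or rdmol.GetProp("_Name"))


def _from_unsanitized(rdmol: Chem.Mol, name: str) -> Molecule:
    conf = rdmol.GetConformer() if rdmol.GetNumConformers() else None
    has_3d = bool(conf is not None and (conf.Is3D() or any(
        abs(conf.GetAtomPosition(i).z) > 1e-6 for i in range(rdmol.GetNumAtoms()))))
    atoms = []
    for atom in rdmol.GetAtoms():
        coords = None
        if conf is not None and has_3d:
            p = conf.GetAtomPosition(atom.GetIdx())
            coords = np.array([p.x, p.y, p.z])
        atoms.append(Atom(atom.GetSymbol(), atom.GetFormalCharge(), coords=coords))
    bond_map = {
        Chem.BondType.SINGLE: SINGLE,
        Chem.BondType.DOUBLE: DOUBLE,
        Chem.BondType.TRIPLE: TRIPLE,
        Chem.BondType.AROMATIC: AROMATIC,
    }
    bonds = [Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), bond_map[b.GetBondType()])
             for b in rdmol.GetBonds()]
    return Molecule(atoms, bonds, name=name, has_3d=has_3d)


def parse_sdf(text: str) -> list[Molecule]:
    """Parse a multi-record SDF (V2000) into graphs in file order."""
    mols = []
    for block in _split_sdf(text):
        mols.append(parse_molfile(block))
    return mols


def _split_sdf(text: str) -> Iterable[str]:
    record: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            if record:
                yield "\n".join(record) + "\n"
            record = []
        else:
            record.append(line)
    if any(ln.strip() for ln in record):
        yield "\n".join(record) + "\n"


# -- writer ---------------------------------------------------------------


def to_molblock(mol: Molecule, properties: Optional[dict] = None) -> str:
    """Serialize to an MDL MOL block (V2000, explicit H, aromatic bonds as 4)."""
    lines = [mol.name or "", "  hcomb", ""]
    dim = "3D" if mol.has_3d else "2D"
    lines[1] = "  hcomb           " + dim
    lines.append(f"{len(mol.atoms):3d}{len(mol.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in mol.atoms:
        x, y, z = (a.coords if a.coords is not None else (0.0, 0.0, 0.0))
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for b in mol.bonds:
        lines.append(f"{b.i + 1:3d}{b.j + 1:3d}{b.order:3d}  0")
    charged = [(a.index + 1, a.formal_charge) for a in mol.atoms if a.formal_charge]
    for start in range(0, len(charged), 8):
        chunk = charged[start:start + 8]
        lines.append("M  CHG" + f"{len(chunk):3d}" + "".join(f"{i:4d}{c:4d}" for i, c in chunk))
    lines.append("M  END")
    if properties:
        for key, value in properties.items():
            lines.append(f">  <{key}>")
            lines.append(str(value))
            lines.append("")
    return "\n".join(lines) + "\n"


def write_sdf(mols: Sequence[Molecule], properties: Optional[Sequence[dict]] = None) -> str:
    """Serialize molecules to an annotated SDF string."""
    blocks = []
    for k, mol in enumerate(mols):
        props = properties[k] if properties else None
        blocks.append(to_molblock(mol, props) + "$$$$\n")
    return "".join(blocks)


# -- normalization --------------------------------------------------------


def _relocate_amidinium_charge(mol: Molecule) -> bool:
    """Move amidinium/guanidinium/imidazolium N(+) charge onto the central C.

    The C-N bonds of the fragment become aromatic, matching the database
    convention for these delocalized cations.  Six-ring aromatics such as
    pyridinium are left untouched.
    """
    changed = False
    for a in mol.atoms:
        if a.element != "C" or a.is_aromatic:
            continue
        nbonds = [b for b in mol.bonds_of(a.index)
                  if mol.atoms[b.other(a.index)].element == "N"]
        if len(nbonds) < 2:
            continue
        double_to_nplus = [
            b for b in nbonds
            if b.order == DOUBLE and mol.atoms[b.other(a.index)].formal_charge == 1
        ]
        drawn_cation = (
            a.formal_charge == 1
            and all(b.order == SINGLE for b in nbonds)
            and not any(b.order in (DOUBLE, TRIPLE) for b in mol.bonds_of(a.index))
        )
        if len(double_to_nplus) == 1:
            nplus = mol.atoms[double_to_nplus[0].other(a.index)]
            nplus.formal_charge = 0
            a.formal_charge = 1
        elif not drawn_cation:
            continue
        for b in nbonds:
            b.order = AROMATIC
        changed = True
    if changed:
        mol.refresh()
    return changed


def _find_carboxylic_acids(mol: Molecule, component: set[int]) -> list[tuple[int, int]]:
    """(acid oxygen, its hydrogen) pairs of -C(=O)OH groups in a component."""
    acids = []
    for a in mol.atoms:
        if a.index not in component or a.element != "C":
            continue
        oxo = [b for b in mol.bonds_of(a.index) if b.order == DOUBLE
               and mol.atoms[b.other(a.index)].element == "O"]
        if not oxo:
            continue
        for b in mol.bonds_of(a.index):
            o = mol.atoms[b.other(a.index)]
            if b.order != SINGLE or o.element != "O" or o.formal_charge != 0:
                continue
            hs = [n for n in mol.neighbors(o.index) if mol.atoms[n].element == "H"]
            if hs:
                acids.append((o.index, hs[0]))
    return acids


def _find_basic_nitrogens(mol: Molecule, component: set[int]) -> list[int]:
    """Primary aliphatic amine N, or the imine N of a neutral guanidine."""
    basic = []
    for a in mol.atoms:
        if a.index not in component or a.element != "N" or a.formal_charge:
            continue
        if a.is_aromatic:
            continue
        heavy = [n for n in mol.neighbors(a.index) if mol.atoms[n].element != "H"]
        n_h = mol.degree(a.index) - len(heavy)
        if a.hybridization == "sp3" and n_h == 2 and len(heavy) == 1:
            c = mol.atoms[heavy[0]]
            # aliphatic only: anilines and amides are too weakly basic
            if c.element == "C" and c.hybridization == "sp3":
                basic.append(a.index)
        elif a.hybridization == "sp2" and len(heavy) == 1:
            c = mol.atoms[heavy[0]]
            if c.element == "C":
                other_n = [n for n in mol.neighbors(c.index)
                           if mol.atoms[n].element == "N" and n != a.index]
                if len(other_n) == 2:  # guanidine imine nitrogen
                    basic.append(a.index)
    return basic


def normalize_conventions(mol: Molecule, zwitterion_policy: str = "as_drawn") -> Molecule:
    """Apply the database structural conventions; returns a new graph.

    ``zwitterion_policy='auto'`` moves the acidic proton of a carboxylic acid
    onto a primary aliphatic amine or guanidine in the same component (the
    two cases treated as zwitterionic in the reference data); ``'as_drawn'``
    keeps the input protonation state.
    """
    if zwitterion_policy not in ("as_drawn", "auto"):
        raise ValueError(f"unknown zwitterion policy {zwitterion_policy!r}")
    out = mol.copy()
    _relocate_amidinium_charge(out)
    if zwitterion_policy == "auto":
        moved = False
        for comp in out.components():
            comp_set = set(comp)
            acids = _find_carboxylic_acids(out, comp_set)
            bases = _find_basic_nitrogens(out, comp_set)
            for (o_idx, h_idx), n_idx in zip(acids, bases):
                bond = out.bond_between(o_idx, h_idx)
                # move the proton: re-point its bond from O to N
                if bond.i == h_idx:
                    bond.j = n_idx
                else:
                    bond.i = n_idx
                out.atoms[o_idx].formal_charge = -1
                out.atoms[n_idx].formal_charge = 1
                moved = True
        if moved:
            out.refresh()
            _relocate_amidinium_charge(out)  # protonated guanidine -> guanidinium
    return out
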
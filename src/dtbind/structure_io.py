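"""Reading and writing protein structures, small molecules, and pockets.

Protein structures are parsed with gemmi (PDB and mmCIF), reduced to the
polymer residues that carry a resolvable α-carbon, and held in a plain
:class:`ProteinStructure` record that the featurizers consume. Small
molecules are parsed with RDKit from SMILES or SDF into a
:class:`MoleculeRecord`. Pockets are subsets of residues, either read
from a selection file (one ``<chain>:<resnum><icode?>`` per line) or
derived geometrically from a ligand pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "ProteinStructure",
    "MoleculeRecord",
    "PocketSelection",
    "StructureFormatError",
    "EmptyStructureError",
    "MoleculeParseError",
    "parse_protein_structure",
    "parse_small_molecule",
    "extract_pocket",
    "pocket_from_ligand",
    "read_pocket_selection",
    "write_pdb",
    "write_mmcif",
]


class StructureFormatError(ValueError):
    """File could not be parsed as PDB/mmCIF."""


class EmptyStructureError(ValueError):
    """No usable residues remained after filtering."""


class MoleculeParseError(ValueError):
    """Molecule input failed RDKit sanitization."""


@dataclass(frozen=True)
class AtomRecord:
    name: str
    element: str
    xyz: np.ndarray  # (3,) Å

    def __post_init__(self):
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=np.float64))


@dataclass(frozen=True)
class ResidueRecord:
    chain_id: str
    resnum: int
    icode: str      # "" when absent
    resname: str    # 3-letter type
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> np.ndarray:
        a = self.atom("CA")
        if a is None:
            raise KeyError(f"residue {self.key} has no CA atom")
        return a.xyz

    @property
    def one_letter(self) -> str:
        info = gemmi.find_tabulated_residue(self.resname)
        if info is not None and info.is_amino_acid():
            code = info.one_letter_code.upper()
            if code.isalpha():
                return code
        return "X"


@dataclass
class ProteinStructure:
    """Ordered polymer residues with coordinates; chains preserved."""

    residues: list[ResidueRecord]
    name: str = ""
    parent_indices: list[int] | None = None  # set for extracted pockets

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    @property
    def sequence(self) -> str:
        """One-letter sequence over all chains in residue order."""
        return "".join(r.one_letter for r in self.residues)

    def sequences_by_chain(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for r in self.residues:
            out[r.chain_id] = out.get(r.chain_id, "") + r.one_letter
        return out

    def ca_coordinates(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=np.float64)

    def heavy_atom_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """All non-hydrogen atom coordinates and their residue indices."""
        coords, owners = [], []
        for i, r in enumerate(self.residues):
            for a in r.atoms:
                if a.element.upper() != "H":
                    coords.append(a.xyz)
                    owners.append(i)
        return np.array(coords, dtype=np.float64), np.array(owners, dtype=np.intp)

    def residue_index(self) -> dict[tuple[str, int, str], int]:
        return {r.key: i for i, r in enumerate(self.residues)}


@dataclass(frozen=True)
class MoleculeRecord:
    """Atom/bond graph of a small molecule, optionally with 3D coordinates."""

    atoms: tuple[dict, ...]   # element, degree, explicit/implicit valence, ...
    bonds: tuple[dict, ...]   # i, j, order, conjugated, in_ring
    coords: np.ndarray | None = None  # (n_atoms, 3) Å
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def with_coords(self, coords: np.ndarray) -> "MoleculeRecord":
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        return MoleculeRecord(self.atoms, self.bonds, coords, self.smiles)


@dataclass(frozen=True)
class PocketSelection:
    """Member residues of a pocket as (chain id, resnum, insertion code)."""

    members: tuple[tuple[str, int, str], ...]

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# protein parsing

def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc id, '' then 'A' first
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or ""))[0]


def _residue_is_polymer(res: gemmi.Residue) -> bool:
    if res.is_water():
        return False
    info = gemmi.find_tabulated_residue(res.name)
    if info is not None and info.is_amino_acid():
        return True
    return res.het_flag == "A"


def parse_protein_structure(path: str | Path, model_index: int = 0) -> ProteinStructure:
    """Parse a PDB or mmCIF file into a :class:`ProteinStructure`.

    Waters and ligand/heteroatom records are excluded; residues lacking
    a resolvable α-carbon are dropped with a warning. ``model_index``
    selects one model of a multi-model file (default: first).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path} contains no models")
    if not 0 <= model_index < len(st):
        raise StructureFormatError(
            f"model_index {model_index} out of range for {len(st)} model(s)")
    model = st[model_index]

    residues: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            if not _residue_is_polymer(res):
                continue
            # collapse altlocs per atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, group in by_name.items():
                a = _pick_altloc(group)
                atoms.append(AtomRecord(
                    name=name, element=a.element.name,
                    xyz=np.array([a.pos.x, a.pos.y, a.pos.z])))
            ca = next((a for a in atoms
                       if a.name == "CA" and a.element.upper() == "C"), None)
            if ca is None:
                logger.warning("dropping residue %s %s%d%s: no alpha-carbon",
                               res.name, chain.name, res.seqid.num,
                               res.seqid.icode.strip())
                continue
            residues.append(ResidueRecord(
                chain_id=chain.name,
                resnum=res.seqid.num,
                icode=res.seqid.icode.strip(),
                resname=res.name,
                atoms=tuple(atoms)))
    if not residues:
        raise EmptyStructureError(f"{path}: no residues with alpha-carbons")
    return ProteinStructure(residues=residues, name=path.stem)


def _to_gemmi(structure: ProteinStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.name or "dtbind"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for r in structure.residues:
        if r.chain_id not in chains:
            chains[r.chain_id] = gemmi.Chain(r.chain_id)
        res = gemmi.Residue()
        res.name = r.resname
        res.seqid = gemmi.SeqId(r.resnum, r.icode or " ")
        res.het_flag = "A"
        for a in r.atoms:
            atom = gemmi.Atom()
            atom.name = a.name
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.xyz)
            atom.occ = 1.0
            res.add_atom(atom)
        chains[r.chain_id].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    _to_gemmi(structure).write_pdb(str(path))


def write_mmcif(structure: ProteinStructure, path: str | Path) -> None:
    st = _to_gemmi(structure)
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# molecule parsing

def _record_from_mol(mol: Chem.Mol, keep_coords: bool) -> MoleculeRecord:
    atoms = tuple(
        {
            "element": a.GetSymbol(),
            "degree": a.GetDegree(),
            "explicit_valence": a.GetExplicitValence(),
            "implicit_valence": a.GetImplicitValence(),
            "aromatic": a.GetIsAromatic(),
            "formal_charge": a.GetFormalCharge(),
        }
        for a in mol.GetAtoms())
    order_names = {
        Chem.BondType.SINGLE: "single",
        Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple",
        Chem.BondType.AROMATIC: "aromatic",
    }
    bonds = tuple(
        {
            "i": b.GetBeginAtomIdx(),
            "j": b.GetEndAtomIdx(),
            "order": order_names.get(b.GetBondType(), "single"),
            "conjugated": b.GetIsConjugated(),
            "in_ring": b.IsInRing(),
        }
        for b in mol.GetBonds())
    coords = None
    if keep_coords and mol.GetNumConformers() > 0:
        coords = np.array(mol.GetConformer().GetPositions(), dtype=np.float64)
    return MoleculeRecord(atoms=atoms, bonds=bonds, coords=coords,
                          smiles=Chem.MolToSmiles(Chem.RemoveHs(mol)))


def parse_small_molecule(source: str | Path) -> MoleculeRecord:
    """Parse a molecule from a SMILES string or an SDF file path.

    Aromaticity and valences are perceived by RDKit sanitization; for
    SDF input the 3D coordinates of the first record are retained.
    Sanitization failures raise :class:`MoleculeParseError`.
    """
    src = str(source)
    is_sdf = src.lower().endswith(".sdf") or isinstance(source, Path)
    if is_sdf:
        if not Path(src).exists():
            raise MoleculeParseError(f"SDF file not found: {src}")
        supplier = Chem.SDMolSupplier(src, removeHs=True, sanitize=True)
        mol = next((m for m in supplier if m is not None), None)
        if mol is None:
            raise MoleculeParseError(f"no parseable molecule in {src}")
        return _record_from_mol(mol, keep_coords=True)
    mol = Chem.MolFromSmiles(src, sanitize=True)
    if mol is None:
        raise MoleculeParseError(f"RDKit could not sanitize SMILES {src!r}")
    return _record_from_mol(mol, keep_coords=False)


# ---------------------------------------------------------------------------
# pockets

def extract_pocket(structure: ProteinStructure,
                   selection: PocketSelection) -> ProteinStructure:
    """Restrict a structure to the selected residues, preserving order.

    The returned structure records the parent indices of its residues so
    pocket-level features can be mapped back to the full protein.
    """
    if len(selection) == 0:
        raise ValueError("pocket selection is empty")
    index = structure.residue_index()
    missing = [m for m in selection.members if m not in index]
    if missing:
        raise KeyError(f"selection residues absent from structure: {missing}")
    wanted = {index[m] for m in selection.members}
    picked = sorted(wanted)
    return ProteinStructure(
        residues=[structure.residues[i] for i in picked],
        name=structure.name + "_pocket",
        parent_indices=picked)


def pocket_from_ligand(structure: ProteinStructure, ligand_coords: np.ndarray,
                       cutoff: float = 10.0) -> PocketSelection:
    """Residues with any heavy atom within ``cutoff`` Å of any ligand atom."""
    ligand_coords = np.asarray(ligand_coords, dtype=np.float64)
    members = []
    for r in structure.residues:
        heavy = np.array([a.xyz for a in r.atoms if a.element.upper() != "H"])
        if heavy.size == 0:
            continue
        d = np.linalg.norm(heavy[:, None, :] - ligand_coords[None, :, :], axis=-1)
        if d.min() <= cutoff:
            members.append(r.key)
    return PocketSelection(members=tuple(members))


def read_pocket_selection(path: str | Path) -> PocketSelection:
    """Read one residue per line as ``<chain>:<resnum><icode?>``."""
    members = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        chain, _, rest = line.partition(":")
        if not rest:
            raise ValueError(f"malformed pocket line: {raw!r}")
        num = rest
        icode = ""
        if rest and rest[-1].isalpha():
            num, icode = rest[:-1], rest[-1]
        members.append((chain, int(num), icode))
    return PocketSelection(members=tuple(members))
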
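"""Synthetic complexes with planted, recoverable ground truth.

Every stage of the pipeline is testable without downloads: an idealized
α-helical protein (N/Cα/C backbone on a standard helix: 1.5 Å rise,
100° twist, 2.3 Å radius), a small molecule posed against one face of
the helix, binding-site labels planted by a distance rule (any residue
atom within r_bind = 5 Å of any drug heavy atom), and a planted
affinity that is linear in the contact count plus seeded Gaussian
noise. Binding-occurrence labels follow a simple recoverable chemical
rule: a pair is a binder iff its drug is aromatic.

The fixtures emulate the data *shapes* and the statistical structure a
learning method must recover; they do not emulate binding physics.
A JSON manifest records every constant so runs are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .structure_io import (AtomRecord, MoleculeRecord, ProteinStructure,
                           ResidueRecord, parse_small_molecule, write_pdb)

__all__ = [
    "ToyComplex",
    "StubEmbedder",
    "stub_embedder",
    "make_toy_protein",
    "make_toy_drug",
    "make_toy_complex",
    "make_imbalanced_site_complex",
    "emit_fixtures",
    "FIXTURE_CONSTANTS",
]

# planted-truth constants (also written to the fixture manifest)
FIXTURE_CONSTANTS = {
    "helix_rise": 1.5,          # Å per residue
    "helix_twist_deg": 100.0,   # rotation per residue
    "helix_radius": 2.3,        # Å
    "r_bind": 5.0,              # Å, distance rule for planted sites
    "affinity_intercept": 4.0,  # p-affinity units
    "affinity_slope": 0.3,      # p-affinity units per contact residue
    "affinity_noise_sd": 0.1,   # p-affinity units
    "occurrence_rule": "binder iff drug contains an aromatic atom",
}

# aromatic (binder) and non-aromatic (non-binder) toy ligands, 5-20 atoms
_BINDER_SMILES = ["c1ccccc1", "c1ccncc1", "Cc1ccccc1O", "c1ccc2ccccc2c1",
                  "Cc1ccc(N)cc1"]
_NONBINDER_SMILES = ["CCO", "CC(=O)O", "C1CCCCC1", "CCN(CC)CC", "CC(C)CO"]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class ToyComplex:
    protein: ProteinStructure
    drug: MoleculeRecord           # with 3D pose
    rdkit_mol: Chem.Mol            # posed molecule, for SDF export
    site_labels: np.ndarray        # (N_residues,) binary
    contact_count: int
    affinity: float                # planted p-affinity
    occurrence_label: int          # 1 = binder (aromatic drug)
    seed: int
    smiles: str


class StubEmbedder:
    """Deterministic position-aware stand-in for a protein language model.

    Row i is a reproducible hash of (residue letter, position) expanded
    to 1024 values in [−1, 1]. Like a real language-model embedding, the
    row is dominated by residue identity with a smaller position-specific
    component, so two occurrences of the same letter get distinct but
    similar rows.
    """

    name = "stub-hash"
    dimension = 1024
    deterministic = True
    _identity_weight = 0.8

    @staticmethod
    @lru_cache(maxsize=256)
    def _letter_row(letter: str) -> tuple:
        rng = np.random.default_rng((ord(letter) * 100_003 + 17) % (2 ** 31))
        return tuple(rng.uniform(-1.0, 1.0, size=1024))

    @staticmethod
    @lru_cache(maxsize=16384)
    def _position_row(letter: str, position: int) -> tuple:
        key = (ord(letter) * 100_003 + position * 7919 + 29) % (2 ** 31 - 1)
        rng = np.random.default_rng(key)
        return tuple(rng.uniform(-1.0, 1.0, size=1024))

    def __call__(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValueError("empty sequence")
        w = self._identity_weight
        return np.array([
            w * np.array(self._letter_row(ch))
            + (1.0 - w) * np.array(self._position_row(ch, i))
            for i, ch in enumerate(sequence)])


def stub_embedder() -> StubEmbedder:
    return StubEmbedder()


def make_toy_protein(n_residues: int, seed: int) -> ProteinStructure:
    """Idealized α-helix with N/Cα/C backbone atoms and a random sequence."""
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(seed)
    # cysteine is reserved for planted binding-site marking, so random
    # backgrounds draw from the other 19 residue types
    pool = [ch for ch in _ONE_TO_THREE if ch != "C"]
    letters = rng.choice(pool, size=n_residues)
    rise = FIXTURE_CONSTANTS["helix_rise"]
    radius = FIXTURE_CONSTANTS["helix_radius"]
    twist = np.deg2rad(FIXTURE_CONSTANTS["helix_twist_deg"])

    residues = []
    for i in range(n_residues):
        theta = i * twist
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        ca = radius * radial + np.array([0.0, 0.0, i * rise])
        n_dir = -1.2 * tangent + 0.6 * radial + 0.5 * axial
        c_dir = 1.2 * tangent + 0.6 * radial + 0.5 * axial
        n_xyz = ca + 1.46 * n_dir / np.linalg.norm(n_dir)
        c_xyz = ca + 1.52 * c_dir / np.linalg.norm(c_dir)
        residues.append(ResidueRecord(
            chain_id="A", resnum=i + 1, icode="",
            resname=_ONE_TO_THREE[letters[i]],
            atoms=(AtomRecord("N", "N", n_xyz),
                   AtomRecord("CA", "C", ca),
                   AtomRecord("C", "C", c_xyz))))
    return ProteinStructure(residues=residues, name=f"toy{n_residues}_{seed}")


def make_toy_drug(smiles: str, seed: int) -> tuple[MoleculeRecord, Chem.Mol]:
    """Parse a SMILES and generate a deterministic 3D conformer."""
    record = parse_small_molecule(smiles)
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    AllChem.EmbedMolecule(mol, params)
    mol = Chem.RemoveHs(mol)
    coords = np.array(mol.GetConformer().GetPositions(), dtype=np.float64)
    return record.with_coords(coords), mol


def _pose_drug(coords: np.ndarray, protein: ProteinStructure,
               anchor: int, distance: float,
               rng: np.random.Generator) -> np.ndarray:
    """Rigidly place the ligand off the helix face at the anchor residue."""
    ca = protein.residues[anchor].ca
    theta = np.arctan2(ca[1], ca[0])
    outward = np.array([np.cos(theta), np.sin(theta), 0.0])
    # random rotation about the centroid
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2 ** 31 - 1))).as_matrix()
    centered = (coords - coords.mean(axis=0)) @ rot.T
    return centered + ca + outward * distance


def _planted_site(protein: ProteinStructure, drug_coords: np.ndarray,
                  r_bind: float) -> np.ndarray:
    labels = np.zeros(protein.n_residues, dtype=np.intp)
    for i, res in enumerate(protein.residues):
        atoms = np.array([a.xyz for a in res.atoms])
        d = np.linalg.norm(atoms[:, None, :] - drug_coords[None, :, :], axis=-1)
        if d.min() <= r_bind:
            labels[i] = 1
    return labels


def make_toy_complex(seed: int, n_residues: int | None = None,
                     required_contacts: int | None = None) -> ToyComplex:
    """A posed toy protein–ligand complex with planted labels.

    The pose is resampled until the planted site is nonempty (or matches
    ``required_contacts`` exactly when given).
    """
    rng = np.random.default_rng(seed)
    if n_residues is None:
        n_residues = int(rng.integers(20, 61))
    protein = make_toy_protein(n_residues, seed=int(rng.integers(2 ** 31 - 1)))
    pool = _BINDER_SMILES + _NONBINDER_SMILES
    smiles = pool[int(rng.integers(len(pool)))]
    record, mol = make_toy_drug(smiles, seed=int(rng.integers(2 ** 31 - 1)))
    r_bind = FIXTURE_CONSTANTS["r_bind"]

    for _ in range(200):
        anchor = int(rng.integers(2, n_residues - 2))
        distance = float(rng.uniform(2.5, 5.5))
        coords = _pose_drug(np.asarray(record.coords), protein, anchor,
                            distance, rng)
        labels = _planted_site(protein, coords, r_bind)
        count = int(labels.sum())
        if required_contacts is None and count > 0:
            break
        if required_contacts is not None and count == required_contacts:
            break
    else:
        raise RuntimeError("could not place ligand with the requested contacts")

    # Give contact residues a distinctive chemical microenvironment — a
    # cysteine-like SG atom — so sites are recoverable from residue
    # features on held-out complexes, as real sites are. Twice as many
    # isolated distractor residues get the same marking away from the
    # ligand, so chemistry alone cannot separate sites: the spatial
    # contiguity of the true site must be used too. The distance rule is
    # re-evaluated afterwards and defines the final labels.
    site_idx = np.flatnonzero(labels)
    away = [i for i in range(n_residues)
            if labels[i] == 0 and np.abs(site_idx - i).min() > 3]
    n_distract = min(4 * len(site_idx), len(away))
    distract = rng.choice(away, size=n_distract, replace=False)
    residues = list(protein.residues)
    for i in np.concatenate([site_idx, distract]):
        res = residues[i]
        ca = res.ca
        radial = np.array([ca[0], ca[1], 0.0])
        radial /= max(np.linalg.norm(radial), 1e-9)
        residues[i] = ResidueRecord(
            res.chain_id, res.resnum, res.icode, "CYS",
            atoms=res.atoms + (AtomRecord("SG", "S", ca + 1.8 * radial),))
    protein = ProteinStructure(residues, name=protein.name)
    labels = _planted_site(protein, coords, r_bind)
    count = int(labels.sum())

    conf = mol.GetConformer()
    for a in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(a, coords[a].tolist())
    affinity = (FIXTURE_CONSTANTS["affinity_intercept"]
                + FIXTURE_CONSTANTS["affinity_slope"] * count
                + rng.normal(0.0, FIXTURE_CONSTANTS["affinity_noise_sd"]))
    aromatic = any(a["aromatic"] for a in record.atoms)
    return ToyComplex(protein=protein, drug=record.with_coords(coords),
                      rdkit_mol=mol, site_labels=labels, contact_count=count,
                      affinity=float(affinity),
                      occurrence_label=int(aromatic), seed=seed,
                      smiles=smiles)


def make_imbalanced_site_complex(seed: int, ratio: int = 48) -> ToyComplex:
    """A long-helix complex whose planted site hits an exact class ratio.

    A ligand is posed against a long helix; the helix is then trimmed to
    a contiguous window of ``contacts * (ratio + 1)`` residues around
    the planted site, so positives:negatives is exactly 1:ratio.
    """
    n_long = 4 * (ratio + 1)
    for attempt in range(50):
        cx = make_toy_complex(seed * 100 + attempt, n_residues=n_long)
        m = cx.contact_count
        total = m * (ratio + 1)
        if not 1 <= m <= 4:
            continue
        site_idx = np.flatnonzero(cx.site_labels)
        center = int(site_idx.mean())
        start = min(max(center - total // 2, 0), n_long - total)
        if site_idx.min() < start or site_idx.max() >= start + total:
            continue
        trimmed = ProteinStructure(
            residues=cx.protein.residues[start:start + total],
            name=cx.protein.name + f"_w{start}")
        labels = cx.site_labels[start:start + total]
        assert labels.sum() == m and len(labels) == total
        return ToyComplex(
            protein=trimmed, drug=cx.drug, rdkit_mol=cx.rdkit_mol,
            site_labels=labels, contact_count=m, affinity=cx.affinity,
            occurrence_label=cx.occurrence_label, seed=seed,
            smiles=cx.smiles)
    raise RuntimeError("could not build an imbalanced complex")


def emit_fixtures(outdir: str | Path, seed: int = 0,
                  n_complexes: int = 8) -> dict:
    """Write a self-describing fixture directory.

    Emits one PDB and posed SDF per complex, per-complex binding-site
    label files, a ``pairs.tsv`` with all three task payloads, and a
    ``manifest.json`` with the planted-truth constants and seeds.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_complexes):
        cx = make_toy_complex(seed * 1000 + i)
        pdb = outdir / f"complex{i}.pdb"
        sdf = outdir / f"complex{i}.sdf"
        labels = outdir / f"complex{i}.site.txt"
        write_pdb(cx.protein, pdb)
        writer = Chem.SDWriter(str(sdf))
        writer.write(cx.rdkit_mol)
        writer.close()
        labels.write_text("".join(
            f"{r.chain_id}:{r.resnum}{r.icode}\n"
            for r, y in zip(cx.protein.residues, cx.site_labels) if y))
        rows.append({
            "pair_id": f"pair{i}", "protein_path": pdb.name,
            "drug": sdf.name, "occurrence": cx.occurrence_label,
            "affinity_molar": 10.0 ** (-cx.affinity),
            "measure": "Kd", "label_file": labels.name,
            "contact_count": cx.contact_count, "smiles": cx.smiles,
        })
    header = ["pair_id", "protein_path", "drug", "occurrence",
              "affinity_molar", "measure", "label_file"]
    with open(outdir / "pairs.tsv", "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[k]) for k in header) + "\n")
    manifest = {"seed": seed, "n_complexes": n_complexes,
                "constants": FIXTURE_CONSTANTS,
                "pairs": rows}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
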
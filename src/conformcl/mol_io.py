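"""Molecule data model, dataset I/O and synthetic fixture generation.

The package works from SMILES-only CSV datasets (MoleculeNet layout): 3D
coordinates are never read from disk but generated on demand with RDKit's
distance-geometry embedding followed by MMFF94 minimization. All-atom
geometries are the working representation — explicit hydrogens are added
before embedding and kept, since the 3D encoder operates on all-atom point
clouds.

The fixture generator builds small, guaranteed-embeddable organic molecules
(alkane/ether/amine chains and substituted rings) with synthetic targets that
are a smooth function of simple structural descriptors plus seeded Gaussian
noise, so that representation quality measurably affects downstream error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.Descriptors import NumRotatableBonds
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")

REGRESSION = "regression"
CLASSIFICATION = "classification"


class EmbeddingError(RuntimeError):
    """Distance-geometry embedding or MMFF94 setup failed for a molecule."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass
class Molecule3D:
    """One conformer of one molecule: atomic numbers + Cartesian coordinates (Å)."""

    atomic_numbers: np.ndarray  # (n_atoms,) int
    positions: np.ndarray  # (n_atoms, 3) float, Å
    energy: float | None = None  # MMFF94 potential energy, kcal/mol
    source_smiles: str = ""

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.shape != (len(self.atomic_numbers), 3):
            raise ValueError("positions must be (n_atoms, 3)")
        if len(self.atomic_numbers) < 1:
            raise ValueError("molecule needs at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)


@dataclass
class MoleculeRecord:
    """A dataset row: canonical SMILES plus task targets and presence mask."""

    smiles: str
    targets: np.ndarray  # (n_tasks,) float
    target_mask: np.ndarray  # (n_tasks,) bool; masked-out entries never enter loss/metrics

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.float64)
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        if self.targets.shape != self.target_mask.shape:
            raise ValueError("targets and target_mask must align")


@dataclass
class ReadReport:
    n_rows: int = 0
    n_dropped: int = 0
    dropped_indices: list[int] = field(default_factory=list)


@dataclass
class Dataset:
    records: list[MoleculeRecord]
    task_type: str  # REGRESSION | CLASSIFICATION
    n_tasks: int
    name: str = ""
    report: ReadReport | None = None

    def __post_init__(self):
        if self.task_type not in (REGRESSION, CLASSIFICATION):
            raise ValueError(f"unknown task_type {self.task_type!r}")
        for r in self.records:
            if len(r.targets) != self.n_tasks:
                raise ValueError("record target length inconsistent with n_tasks")

    def __len__(self) -> int:
        return len(self.records)

    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


def _etkdg_params(seed: int) -> AllChem.EmbedParameters:
    p = AllChem.ETKDGv3()
    p.randomSeed = int(seed) & 0x7FFFFFFF
    return p


def mol_from_smiles(smiles: str, add_hs: bool = True) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.AddHs(mol) if add_hs else mol


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _conformer_to_molecule3d(mol: Chem.Mol, conf_id: int, energy: float, smiles: str) -> Molecule3D:
    conf = mol.GetConformer(conf_id)
    return Molecule3D(
        atomic_numbers=np.array([a.GetAtomicNum() for a in mol.GetAtoms()]),
        positions=np.array(conf.GetPositions()),
        energy=float(energy),
        source_smiles=smiles,
    )


def embed_molecule(smiles: str, seed: int = 0) -> Molecule3D:
    """Embed one MMFF94-optimized conformer for a SMILES string.

    Deterministic for a fixed seed. Raises :class:`EmbeddingError` when
    distance-geometry embedding fails or MMFF94 lacks parameters, so callers
    can drop the molecule with a warning instead of aborting.
    """
    can = canonical_smiles(smiles)
    mol = mol_from_smiles(can)
    cid = AllChem.EmbedMolecule(mol, _etkdg_params(seed))
    if cid < 0:
        raise EmbeddingError(f"distance-geometry embedding failed for {can!r}")
    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        raise EmbeddingError(f"MMFF94 has no parameters for {can!r}")
    if AllChem.MMFFOptimizeMolecule(mol) < 0:
        raise EmbeddingError(f"MMFF94 minimization failed for {can!r}")
    ff = AllChem.MMFFGetMoleculeForceField(mol, props)
    return _conformer_to_molecule3d(mol, cid, ff.CalcEnergy(), can)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_csv_dataset(
    path: str | Path,
    smiles_column: str,
    target_columns: list[str],
    task_type: str,
    name: str = "",
) -> Dataset:
    """Read a MoleculeNet-style CSV into a Dataset.

    Rows with unparseable SMILES are dropped and counted in ``dataset.report``;
    blank target cells get ``target_mask`` False. SMILES are canonicalized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in [smiles_column, *target_columns] if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns in {path.name}: {missing}")
    records: list[MoleculeRecord] = []
    report = ReadReport(n_rows=len(df))
    for idx, row in df.iterrows():
        raw = row[smiles_column]
        mol = Chem.MolFromSmiles(raw) if isinstance(raw, str) else None
        if mol is None:
            report.n_dropped += 1
            report.dropped_indices.append(int(idx))
            continue
        vals = pd.to_numeric(row[target_columns], errors="coerce").to_numpy(dtype=np.float64)
        mask = np.isfinite(vals)
        records.append(
            MoleculeRecord(Chem.MolToSmiles(mol), np.where(mask, vals, 0.0), mask)
        )
    if not records:
        raise ValueError(f"no parseable rows in {path}")
    if report.n_dropped:
        logger.warning("dropped %d unparseable rows from %s", report.n_dropped, path.name)
    return Dataset(records, task_type, len(target_columns), name or path.stem, report)


def write_csv_dataset(dataset: Dataset, path: str | Path, smiles_column: str = "smiles") -> None:
    """Write a Dataset back to CSV; masked target cells are left blank."""
    cols: dict[str, list] = {smiles_column: dataset.smiles()}
    for t in range(dataset.n_tasks):
        cols[f"target_{t}"] = [
            r.targets[t] if r.target_mask[t] else np.nan for r in dataset.records
        ]
    pd.DataFrame(cols).to_csv(path, index=False)


def target_column_names(dataset: Dataset) -> list[str]:
    return [f"target_{t}" for t in range(dataset.n_tasks)]


# ---------------------------------------------------------------------------
# SDF output
# ---------------------------------------------------------------------------


def _rdkit_mol_with_coords(mol3d: Molecule3D) -> Chem.Mol:
    """Rebuild an RDKit mol carrying mol3d's coordinates.

    Uses the bond topology from source_smiles when the all-atom order matches;
    otherwise (e.g. after atom dropping) writes a bond-less atom cloud.
    """
    mol = None
    if mol3d.source_smiles:
        cand = mol_from_smiles(mol3d.source_smiles)
        z = [a.GetAtomicNum() for a in cand.GetAtoms()]
        if z == list(mol3d.atomic_numbers):
            mol = cand
    if mol is None:
        rw = Chem.RWMol()
        for z in mol3d.atomic_numbers:
            a = Chem.Atom(int(z))
            a.SetNoImplicit(True)
            rw.AddAtom(a)
        mol = rw.GetMol()
    conf = Chem.Conformer(mol3d.n_atoms)
    for i, xyz in enumerate(mol3d.positions):
        conf.SetAtomPosition(i, [float(v) for v in xyz])
    mol.RemoveAllConformers()
    mol.AddConformer(conf)
    return mol


def write_sdf(mols: list[Molecule3D], path: str | Path, properties: list[dict] | None = None) -> None:
    """Write Molecule3D records to a V2000 SDF, energy stored as a property."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for k, m in enumerate(mols):
        mol = _rdkit_mol_with_coords(m)
        mol.SetProp("_Name", m.source_smiles)
        if m.source_smiles:
            mol.SetProp("SMILES", m.source_smiles)
        if m.energy is not None:
            mol.SetProp("ENERGY_KCAL_MOL", f"{m.energy:.6f}")
        if properties is not None:
            for key, val in properties[k].items():
                mol.SetProp(key, str(val))
        writer.write(mol)
    writer.close()


# ---------------------------------------------------------------------------
# fixture generation
# ---------------------------------------------------------------------------

def _random_chain(rng: np.random.Generator) -> str:
    """Random flexible acyclic molecule: 4-9 heavy atoms, optional heteroatoms
    and one optional methyl branch; >=4-atom backbone guarantees a rotatable bond."""
    length = int(rng.integers(4, 10))
    atoms = ["C"] * length
    prev_het = False
    for pos in range(1, length - 1):  # interior substitutions, no O-O/N-N adjacency
        if not prev_het and rng.random() < 0.3:
            atoms[pos] = "O" if rng.random() < 0.5 else "N"
            prev_het = True
        else:
            prev_het = False
    if atoms[-2] == "C" and rng.random() < 0.25:
        atoms[-1] = "O"  # terminal alcohol
    if length >= 5 and rng.random() < 0.4:
        branch_pos = int(rng.integers(1, length - 1))
        if atoms[branch_pos] == "C":
            atoms[branch_pos] = "C(C)"
    return "".join(atoms)


def _ring_smiles(size: int, het: str | None, het_pos: int = -1) -> str:
    atoms = ["C"] * size
    if het is not None:
        atoms[het_pos] = het
    return atoms[0] + "1" + "".join(atoms[1:]) + "1"


def _ring_templates() -> list[str]:
    """Ring systems with an ethyl handle so every molecule stays flexible."""
    out = []
    for size in (4, 5, 6, 7, 8):
        for het in (None, "O", "N", "S"):
            if het == "S" and size < 5:
                continue
            out.append("CC" + _ring_smiles(size, het))
    for het_a in (None, "O", "N"):
        for size_a in (4, 5, 6, 7):
            for linker in (1, 2, 3):
                for size_b in (4, 5, 6, 7):
                    # heteroatom mid-ring: the last ring atom carries the linker
                    out.append(
                        _ring_smiles(size_a, het_a, het_pos=size_a // 2)
                        + "C" * linker
                        + _ring_smiles(size_b, None)
                    )
    return out


def scaffold_key(smiles: str, include_chirality: bool = False) -> str:
    """Canonical Bemis–Murcko scaffold string ('' for acyclic molecules)."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles, includeChirality=include_chirality)


def _unique_scaffold_templates() -> list[str]:
    seen: set[str] = set()
    out = []
    for smi in _ring_templates():
        key = scaffold_key(smi)
        if key and key not in seen:
            seen.add(key)
            out.append(canonical_smiles(smi))
    return out


def _descriptors(smiles: str) -> np.ndarray:
    mol = mol_from_smiles(smiles)
    n_atoms = mol.GetNumAtoms()
    n_rot = NumRotatableBonds(Chem.RemoveHs(mol))
    n_het = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return np.array([n_atoms, n_rot, n_het], dtype=np.float64)


# per-task weights on (all-atom count, rotatable bonds, heteroatoms); tasks
# cycle through these triples with a mild scale ramp
_TASK_WEIGHTS = [(0.30, 1.50, -1.00), (0.20, 1.00, 0.80), (0.40, 0.60, -0.50)]
_FIXTURE_NOISE_STD = 0.5
_FIXTURE_FLIP_PROB = 0.05


def fixture_target_matrix(smiles_list: list[str], n_tasks: int) -> np.ndarray:
    """Noise-free synthetic targets: a fixed linear map of structural descriptors."""
    desc = np.stack([_descriptors(s) for s in smiles_list])
    cols = []
    for t in range(n_tasks):
        w = np.array(_TASK_WEIGHTS[t % len(_TASK_WEIGHTS)]) * (1.0 + 0.25 * (t // len(_TASK_WEIGHTS)))
        cols.append(desc @ w)
    return np.stack(cols, axis=1)


def generate_fixture_dataset(
    n_molecules: int,
    task_type: str = REGRESSION,
    seed: int = 0,
    n_tasks: int = 1,
    unique_scaffolds: bool = False,
    name: str = "fixture",
) -> Dataset:
    """Deterministic synthetic dataset of small, embeddable, flexible molecules.

    Every molecule parses, embeds under MMFF94 and has at least one rotatable
    bond. Regression targets are a fixed linear function of (all-atom count,
    rotatable-bond count, heteroatom count) plus N(0, 0.5²) noise;
    classification thresholds the noise-free score at the median and flips 5%
    of labels. In ``unique_scaffolds`` mode each molecule carries a distinct
    Bemis–Murcko scaffold (ring-containing templates only).
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    if unique_scaffolds:
        templates = _unique_scaffold_templates()
        if n_molecules > len(templates):
            raise ValueError(
                f"unique-scaffold mode supports at most {len(templates)} molecules"
            )
        idx = rng.permutation(len(templates))[:n_molecules]
        smiles_list = [templates[i] for i in idx]
    else:
        rings = [t for t in _ring_templates() if t.startswith("CC")][:20]
        smiles_list, seen = [], set()
        attempts = 0
        while len(smiles_list) < n_molecules:
            if rng.random() < 0.7:
                smi = _random_chain(rng)
            else:
                # ring template with a random flexible side chain; the scaffold
                # stays that of the template, so scaffolds repeat across molecules
                smi = _random_chain(rng) + rings[rng.integers(len(rings))][2:]
            smi = canonical_smiles(smi)
            attempts += 1
            # prefer unique molecules (distinct contrastive negatives); allow
            # repeats only once the chemical space is exhausted
            if smi not in seen or attempts > 20 * n_molecules:
                seen.add(smi)
                smiles_list.append(smi)
    clean = fixture_target_matrix(smiles_list, n_tasks)
    if task_type == REGRESSION:
        targets = clean + rng.normal(0.0, _FIXTURE_NOISE_STD, size=clean.shape)
    else:
        med = np.median(clean, axis=0, keepdims=True)
        labels = (clean > med).astype(np.float64)
        flips = rng.random(clean.shape) < _FIXTURE_FLIP_PROB
        targets = np.where(flips, 1.0 - labels, labels)
    records = [
        MoleculeRecord(s, targets[i], np.ones(n_tasks, dtype=bool))
        for i, s in enumerate(smiles_list)
    ]
    return Dataset(records, task_type, n_tasks, name)
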
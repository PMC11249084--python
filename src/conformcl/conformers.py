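"""Per-molecule conformer pools and positive-pair sampling strategies.

A pool holds the ``pool_size`` lowest-MMFF94-energy conformers of a molecule,
obtained by oversampling distance-geometry embeddings, force-field minimizing
each candidate, and keeping the energy-sorted head. Two pairing strategies
draw the positive pair for contrastive learning:

* ``conformer_S`` — always the two most stable conformers (pool[0], pool[1]);
* ``conformer_R`` — two distinct conformers drawn uniformly at random,
  by default excluding the most stable one from the eligible set.

Molecules without rotatable bonds have a single conformation up to force-field
minimization, so they get a pool of one; both strategies then return that
conformer twice. Geometric deduplication of minimized candidates (symmetric
heavy-atom RMSD) is available but off by default: energy-degenerate duplicate
basins are a real feature of force-field conformer generation and keeping them
preserves the energy-rank semantics of the pool.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign
from rdkit.Chem.Descriptors import NumRotatableBonds

from .mol_io import (
    Dataset,
    EmbeddingError,
    Molecule3D,
    _conformer_to_molecule3d,
    _etkdg_params,
    canonical_smiles,
    mol_from_smiles,
    write_sdf,
)

logger = logging.getLogger(__name__)

DEFAULT_N_CANDIDATES = 30
DEFAULT_POOL_SIZE = 5

CONFORMER_R = "conformer_R"
CONFORMER_S = "conformer_S"


@dataclass
class PairSamplingMode:
    """How the two positive-pair conformers are chosen from a pool."""

    mode: str = CONFORMER_R
    exclude_most_stable: bool = True  # ignored by conformer_S

    def __post_init__(self):
        if self.mode not in (CONFORMER_R, CONFORMER_S):
            raise ValueError(f"unknown sampling mode {self.mode!r}")


@dataclass
class ConformerPool:
    """Energy-ranked conformers of a single molecule (index 0 = most stable)."""

    conformers: list[Molecule3D]
    energies: np.ndarray = field(default=None)  # kcal/mol, ascending

    def __post_init__(self):
        if not self.conformers:
            raise ValueError("empty conformer pool")
        if self.energies is None:
            self.energies = np.array([c.energy for c in self.conformers], dtype=np.float64)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if len(self.energies) != len(self.conformers):
            raise ValueError("energies must align with conformers")
        if np.any(np.diff(self.energies) < 0):
            raise ValueError("pool energies must be non-decreasing")
        z0 = self.conformers[0].atomic_numbers
        for c in self.conformers[1:]:
            if not np.array_equal(c.atomic_numbers, z0):
                raise ValueError("pool conformers must share atomic numbers")

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def smiles(self) -> str:
        return self.conformers[0].source_smiles


def generate_candidates(smiles: str, n_candidates: int, seed: int = 0) -> list[Molecule3D]:
    """Embed and MMFF94-minimize ``n_candidates`` conformers (unsorted)."""
    can = canonical_smiles(smiles)
    mol = mol_from_smiles(can)
    cids = AllChem.EmbedMultipleConfs(mol, numConfs=n_candidates, params=_etkdg_params(seed))
    if len(cids) == 0:
        raise EmbeddingError(f"distance-geometry embedding failed for {can!r}")
    if AllChem.MMFFGetMoleculeProperties(mol) is None:
        raise EmbeddingError(f"MMFF94 has no parameters for {can!r}")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol)
    out = []
    for cid, (converged, energy) in zip(cids, results):
        if converged < 0:
            continue
        out.append(_conformer_to_molecule3d(mol, cid, energy, can))
    if not out:
        raise EmbeddingError(f"MMFF94 minimization failed for all candidates of {can!r}")
    return out


def _dedup_by_rmsd(cands: list[Molecule3D], threshold: float) -> list[Molecule3D]:
    """Greedy energy-ordered dedup on symmetric heavy-atom RMSD."""
    order = np.argsort([c.energy for c in cands], kind="stable")
    ref = mol_from_smiles(cands[0].source_smiles)
    heavy_ids = [a.GetIdx() for a in ref.GetAtoms() if a.GetAtomicNum() > 1]
    probe = Chem.RemoveHs(ref)

    def with_conf(m3d: Molecule3D) -> Chem.Mol:
        mol = Chem.Mol(probe)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for k, i in enumerate(heavy_ids):
            conf.SetAtomPosition(k, [float(v) for v in m3d.positions[i]])
        mol.RemoveAllConformers()
        mol.AddConformer(conf)
        return mol

    kept: list[Molecule3D] = []
    kept_mols: list[Chem.Mol] = []
    for i in order:
        cand_mol = with_conf(cands[i])
        if all(rdMolAlign.GetBestRMS(cand_mol, km) > threshold for km in kept_mols):
            kept.append(cands[i])
            kept_mols.append(cand_mol)
    return kept


def build_pool(
    smiles: str,
    n_candidates: int = DEFAULT_N_CANDIDATES,
    pool_size: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    dedup_rmsd: float | None = None,
) -> ConformerPool:
    """Build the energy-ranked conformer pool for one molecule.

    Oversamples ``n_candidates`` embeddings, minimizes each with MMFF94, sorts
    by energy and truncates to ``pool_size``. Molecules with no rotatable bond
    are rigid and yield a pool of one. With ``dedup_rmsd`` set, minimized
    candidates closer than that symmetric heavy-atom RMSD (Å) are merged,
    keeping the lower-energy representative.
    """
    if not 1 <= pool_size <= n_candidates:
        raise ValueError("need n_candidates >= pool_size >= 1")
    mol2d = Chem.MolFromSmiles(smiles)
    if mol2d is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if NumRotatableBonds(mol2d) == 0:
        cands = generate_candidates(smiles, 1, seed)
    else:
        cands = generate_candidates(smiles, n_candidates, seed)
        if dedup_rmsd is not None:
            cands = _dedup_by_rmsd(cands, dedup_rmsd)
    order = np.argsort([c.energy for c in cands], kind="stable")[:pool_size]
    return ConformerPool([cands[i] for i in order])


def sample_pair(
    pool: ConformerPool, mode: PairSamplingMode, rng: np.random.Generator
) -> tuple[Molecule3D, Molecule3D]:
    """Draw the positive-pair conformers for one molecule.

    conformer_S returns the two most stable conformers. conformer_R draws two
    distinct indices uniformly without replacement from the eligible set —
    indices 1..end when ``exclude_most_stable`` and the pool has at least 3
    conformers, otherwise all indices. A singleton pool returns its conformer
    twice under either mode.
    """
    n = len(pool)
    if mode.mode == CONFORMER_S:
        i, j = (0, 1) if n >= 2 else (0, 0)
    else:
        if n == 1:
            i = j = 0
        else:
            eligible = np.arange(1, n) if (mode.exclude_most_stable and n >= 3) else np.arange(n)
            i, j = rng.choice(eligible, size=2, replace=False)
    return pool.conformers[int(i)], pool.conformers[int(j)]


# ---------------------------------------------------------------------------
# pool cache (SDF)
# ---------------------------------------------------------------------------


def write_pool_sdf(pools: dict[str, ConformerPool], path: str | Path) -> None:
    """Write pools to one SDF; conformers of a molecule are consecutive records."""
    mols: list[Molecule3D] = []
    props: list[dict] = []
    for smi, pool in pools.items():
        for k, conf in enumerate(pool.conformers):
            mols.append(conf)
            props.append({"POOL_SMILES": smi, "POOL_INDEX": k})
    write_sdf(mols, path, properties=props)


def read_pool_sdf(path: str | Path) -> dict[str, ConformerPool]:
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    grouped: dict[str, list[tuple[int, Molecule3D]]] = defaultdict(list)
    for mol in supplier:
        if mol is None:
            continue
        smi = mol.GetProp("POOL_SMILES")
        m3d = Molecule3D(
            atomic_numbers=np.array([a.GetAtomicNum() for a in mol.GetAtoms()]),
            positions=np.array(mol.GetConformer().GetPositions()),
            energy=float(mol.GetProp("ENERGY_KCAL_MOL")),
            source_smiles=smi,
        )
        grouped[smi].append((int(mol.GetProp("POOL_INDEX")), m3d))
    return {
        smi: ConformerPool([m for _, m in sorted(items)]) for smi, items in grouped.items()
    }


def build_pool_cache(
    dataset: Dataset,
    n_candidates: int = DEFAULT_N_CANDIDATES,
    pool_size: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    path: str | Path | None = None,
    dedup_rmsd: float | None = None,
) -> dict[str, ConformerPool]:
    """Build pools for every unique SMILES in a dataset.

    Molecules whose embedding fails are dropped with a warning; the returned
    dict simply lacks them. Optionally persists the cache to SDF.
    """
    pools: dict[str, ConformerPool] = {}
    for smi in dict.fromkeys(dataset.smiles()):
        try:
            pools[smi] = build_pool(smi, n_candidates, pool_size, seed, dedup_rmsd)
        except EmbeddingError as err:
            logger.warning("dropping molecule from pool cache: %s", err)
    if path is not None:
        write_pool_sdf(pools, path)
    return pools
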
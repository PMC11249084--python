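"""Perturbing graph/geometry augmentations used as contrastive baselines.

These operations deliberately break molecular semantics (removing atoms,
masking elements) or produce geometries off the force-field surface (noising
coordinates); they exist to compare conformer-pair pretraining against the
augmentation families common in graph contrastive learning:

* atom dropping — delete a fixed fraction of atoms uniformly at random;
* attribute masking — overwrite the atomic number of a fixed fraction of
  atoms with a reserved mask token outside the dataset's element range;
* position noising — add independent N(0,1) noise times a small scale
  (default 0.01) to every Cartesian coordinate.

The affected-atom count is round-half-to-even of ratio × n_atoms; dropping
always retains at least one atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mol_io import Molecule3D

ATOM_DROP = "atom_drop"
ATTR_MASK = "attr_mask"
POSITION_NOISE = "position_noise"

DEFAULT_RATIO = 0.2
DEFAULT_NOISE_SCALE = 0.01


@dataclass
class AugmentationSpec:
    kind: str  # ATOM_DROP | ATTR_MASK | POSITION_NOISE
    ratio: float = DEFAULT_RATIO  # fraction of atoms affected (drop/mask)
    noise_scale: float = DEFAULT_NOISE_SCALE
    mask_token: int | None = None  # reserved atomic-number index; None = auto

    def __post_init__(self):
        if self.kind not in (ATOM_DROP, ATTR_MASK, POSITION_NOISE):
            raise ValueError(f"unknown augmentation kind {self.kind!r}")
        if self.kind in (ATOM_DROP, ATTR_MASK) and not 0 < self.ratio < 1:
            raise ValueError("ratio must lie in (0, 1)")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")


def _n_affected(n_atoms: int, ratio: float) -> int:
    # banker's rounding, same as np.round
    return int(np.round(ratio * n_atoms))


def atom_drop(mol: Molecule3D, ratio: float, rng: np.random.Generator) -> Molecule3D:
    """Remove round(ratio * n_atoms) uniformly chosen atoms.

    Survivors keep their positions and atomic numbers bit-for-bit; at least
    one atom is always retained.
    """
    k = _n_affected(mol.n_atoms, ratio)
    if k >= mol.n_atoms:
        raise ValueError("atom_drop would remove every atom")
    if k == 0:
        return Molecule3D(mol.atomic_numbers.copy(), mol.positions.copy(),
                          mol.energy, mol.source_smiles)
    dropped = rng.choice(mol.n_atoms, size=k, replace=False)
    keep = np.setdiff1d(np.arange(mol.n_atoms), dropped)
    return Molecule3D(mol.atomic_numbers[keep], mol.positions[keep],
                      None, mol.source_smiles)


def attr_mask(
    mol: Molecule3D, ratio: float, mask_token: int, rng: np.random.Generator
) -> Molecule3D:
    """Set round(ratio * n_atoms) atoms' atomic number to the mask token.

    Coordinates and atom count are untouched. The mask token must not collide
    with a real element of the molecule.
    """
    if mask_token in mol.atomic_numbers:
        raise ValueError(f"mask token {mask_token} collides with a real element")
    k = _n_affected(mol.n_atoms, ratio)
    z = mol.atomic_numbers.copy()
    if k > 0:
        chosen = rng.choice(mol.n_atoms, size=k, replace=False)
        z[chosen] = mask_token
    return Molecule3D(z, mol.positions.copy(), None, mol.source_smiles)


def position_noise(
    mol: Molecule3D, noise_scale: float, rng: np.random.Generator
) -> Molecule3D:
    """Add noise_scale * N(0,1) independently to every coordinate."""
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    noise = rng.standard_normal(mol.positions.shape) * noise_scale
    return Molecule3D(mol.atomic_numbers.copy(), mol.positions + noise,
                      None, mol.source_smiles)


def default_mask_token(atomic_numbers_in_use) -> int:
    """One past the largest atomic number the data uses."""
    return int(max(atomic_numbers_in_use)) + 1


def apply_augmentation(
    mol: Molecule3D, spec: AugmentationSpec, rng: np.random.Generator
) -> Molecule3D:
    if spec.kind == ATOM_DROP:
        return atom_drop(mol, spec.ratio, rng)
    if spec.kind == ATTR_MASK:
        token = spec.mask_token
        if token is None:
            token = default_mask_token(mol.atomic_numbers)
        return attr_mask(mol, spec.ratio, token, rng)
    return position_noise(mol, spec.noise_scale, rng)
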
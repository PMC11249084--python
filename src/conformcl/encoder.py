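"""Continuous-filter 3D message-passing encoder (SchNet family).

The encoder maps an all-atom point cloud (atomic numbers + coordinates) to a
fixed-size graph embedding using only interatomic distances, which makes it
invariant to rigid rotations/translations and to atom permutation:

1. atom states are initialized from an atomic-number embedding table,
   ``v_i^0 = a_{Z_i}``;
2. a radius graph connects every atom pair within a distance cutoff, and each
   edge distance is expanded in Gaussian radial basis functions
   ``e_k(d) = exp(-gamma (d - mu_k)^2)``;
3. each interaction block applies an atom-wise linear map, multiplies neighbor
   states element-wise with a filter generated from the RBF features by a
   two-layer filter network, sums over neighbors, sends the aggregate through
   a two-layer update network (shifted-softplus nonlinearities throughout) and
   adds the result residually to the atom state;
4. an atom-wise two-layer readout network is summed over atoms to give h_G.

Trainable-parameter count in closed form (H = hidden_dim, K = n_rbf,
L = n_layers, E = embed_dim, A = n_elements):

    A*H  +  L * (4*H^2 + K*H + 5*H)  +  H*(H//2) + H//2 + (H//2)*E + E

The defaults (H=128, L=4, K=50, E=128) give 319,680 encoder parameters.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, segment_sum
from .mol_io import Molecule3D
from .nn import MLP2, Dense

DEFAULT_CUTOFF = 10.0  # Å
DEFAULT_GAMMA = 10.0  # Å^-2


# ---------------------------------------------------------------------------
# radius graph & RBF expansion
# ---------------------------------------------------------------------------


@dataclass
class RadiusGraph:
    """Directed neighbor lists within a cutoff: edge k runs src[k] <- dst[k]."""

    src: np.ndarray  # receiving atom i
    dst: np.ndarray  # neighbor atom j
    distances: np.ndarray  # d_ij in Å
    cutoff: float


def _pairs_within_cutoff(pos: np.ndarray, cutoff: float):
    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    n = len(pos)
    mask = (d <= cutoff) & ~np.eye(n, dtype=bool) & (d > 0)
    src, dst = np.nonzero(mask)
    return src, dst, d[src, dst]


def build_radius_graph(mol: Molecule3D, cutoff: float) -> RadiusGraph:
    """All ordered atom pairs with Euclidean distance in (0, cutoff]."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    src, dst, dist = _pairs_within_cutoff(mol.positions, cutoff)
    return RadiusGraph(src, dst, dist, cutoff)


@dataclass
class RBFConfig:
    """Gaussian radial basis grid: centers mu_k (Å) and width gamma (Å^-2)."""

    centers: np.ndarray
    gamma: float

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if np.any(np.diff(self.centers) <= 0):
            raise ValueError("centers must be strictly increasing")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @classmethod
    def uniform(cls, n_rbf: int, cutoff: float, gamma: float = DEFAULT_GAMMA) -> "RBFConfig":
        return cls(np.linspace(0.0, cutoff, n_rbf), gamma)

    @property
    def n_rbf(self) -> int:
        return len(self.centers)


def rbf_expand(d: np.ndarray | float, cfg: RBFConfig) -> np.ndarray:
    """Component k is exp(-gamma (d - mu_k)^2); values lie in (0, 1]."""
    d = np.asarray(d, dtype=np.float64)
    return np.exp(-cfg.gamma * (d[..., None] - cfg.centers) ** 2)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


@dataclass
class MoleculeBatch:
    """Disjoint union of molecules with a per-atom molecule index."""

    atomic_numbers: np.ndarray
    positions: np.ndarray
    mol_index: np.ndarray
    n_mols: int

    @classmethod
    def from_molecules(cls, mols: list[Molecule3D]) -> "MoleculeBatch":
        z = np.concatenate([m.atomic_numbers for m in mols])
        pos = np.concatenate([m.positions for m in mols])
        idx = np.concatenate([np.full(m.n_atoms, k) for k, m in enumerate(mols)])
        return cls(z, pos, idx, len(mols))

    def radius_edges(self, cutoff: float):
        """Edges within molecules only; offsets respect the concatenation."""
        srcs, dsts, dists = [], [], []
        offset = 0
        for k in range(self.n_mols):
            sel = np.nonzero(self.mol_index == k)[0]
            s, t, d = _pairs_within_cutoff(self.positions[sel], cutoff)
            srcs.append(s + offset)
            dsts.append(t + offset)
            dists.append(d)
            offset += len(sel)
        return np.concatenate(srcs), np.concatenate(dsts), np.concatenate(dists)


@dataclass
class GraphEmbedding:
    """Encoder output: graph vector(s) h_G and final per-atom states."""

    h_G: Tensor  # (n_mols, embed_dim) or (embed_dim,) for a single molecule
    atom_states: Tensor


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------


@dataclass
class EncoderConfig:
    hidden_dim: int = 128
    n_layers: int = 4
    n_rbf: int = 50
    cutoff: float = DEFAULT_CUTOFF
    gamma: float = DEFAULT_GAMMA
    embed_dim: int = 128
    n_elements: int = 100  # embedding-table rows, indexed by atomic number

    def rbf(self) -> RBFConfig:
        return RBFConfig.uniform(self.n_rbf, self.cutoff, self.gamma)


class _InteractionBlock:
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        h = cfg.hidden_dim
        self.in2f = Dense(h, h, rng)  # atom-wise linear before the conv
        self.filter_net = MLP2(cfg.n_rbf, h, h, rng)
        self.update_net = MLP2(h, h, h, rng)

    def parameters(self) -> list[Tensor]:
        return self.in2f.parameters() + self.filter_net.parameters() + self.update_net.parameters()


class SchNetEncoder:
    """Distance-based message-passing encoder over all-atom point clouds."""

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        self.config = config or EncoderConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.embedding = Tensor(
            rng.uniform(-np.sqrt(3.0 / cfg.hidden_dim), np.sqrt(3.0 / cfg.hidden_dim),
                        size=(cfg.n_elements, cfg.hidden_dim)),
            requires_grad=True,
        )
        self.blocks = [_InteractionBlock(cfg, rng) for _ in range(cfg.n_layers)]
        self.readout = MLP2(cfg.hidden_dim, cfg.hidden_dim // 2, cfg.embed_dim, rng)
        self._rbf = cfg.rbf()

    # -- forward -----------------------------------------------------------

    def __call__(self, batch: MoleculeBatch) -> GraphEmbedding:
        cfg = self.config
        z = np.asarray(batch.atomic_numbers)
        if z.max(initial=0) >= cfg.n_elements:
            raise ValueError(
                f"atomic number {int(z.max())} outside embedding table ({cfg.n_elements} rows)"
            )
        src, dst, dist = batch.radius_edges(cfg.cutoff)
        e = Tensor(rbf_expand(dist, self._rbf))  # (n_edges, n_rbf), constant
        n_atoms = len(z)
        v = self.embedding.gather(z)
        for block in self.blocks:
            x = block.in2f(v)
            f = block.filter_net(e)
            messages = x.gather(dst) * f
            agg = segment_sum(messages, src, n_atoms)  # empty neighborhoods -> 0
            v = v + block.update_net(agg)
        per_atom = self.readout(v)
        h = segment_sum(per_atom, batch.mol_index, batch.n_mols)
        return GraphEmbedding(h_G=h, atom_states=v)

    def encode(self, mol: Molecule3D) -> np.ndarray:
        """Convenience single-molecule embedding as a plain array."""
        return self(MoleculeBatch.from_molecules([mol])).h_G.data[0]

    # -- parameters & persistence -------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = [self.embedding]
        for b in self.blocks:
            params += b.parameters()
        return params + self.readout.parameters()


def count_parameters(encoder: SchNetEncoder, head=None) -> int:
    """Exact count of trainable scalars in encoder plus an optional head."""
    n = sum(p.data.size for p in encoder.parameters())
    if head is not None:
        n += sum(p.data.size for p in head.parameters())
    return int(n)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def _weights_hash(params: list[Tensor]) -> str:
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def save_checkpoint(path: str | Path, encoder: SchNetEncoder, metadata: dict | None = None) -> None:
    """Serialize encoder weights (.npz) with a JSON sidecar holding the config."""
    path = Path(path)
    params = encoder.parameters()
    np.savez(path, **{f"p{i}": p.data for i, p in enumerate(params)})
    sidecar = {
        "config": asdict(encoder.config),
        "n_params": count_parameters(encoder),
        "weights_sha256": _weights_hash(params),
        "metadata": metadata or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> SchNetEncoder:
    """Load an encoder, verifying config sidecar and weight hash."""
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    encoder = SchNetEncoder(EncoderConfig(**sidecar["config"]))
    data = np.load(npz_path)
    params = encoder.parameters()
    if len(data.files) != len(params):
        raise ValueError("checkpoint does not match encoder architecture")
    for i, p in enumerate(params):
        arr = data[f"p{i}"]
        if arr.shape != p.data.shape:
            raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
        p.data = arr.astype(np.float64)
    if _weights_hash(params) != sidecar["weights_sha256"]:
        raise ValueError("checkpoint weight hash mismatch")
    return encoder
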
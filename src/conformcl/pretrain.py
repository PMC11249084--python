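"""Contrastive pretraining: projection head, NT-Xent loss, training loop.

Each molecule contributes one positive pair per epoch — two conformers drawn
from its pool (conformer-R/S) or two independently perturbed copies of its
most stable conformer (baseline augmentations). Both views pass through the
shared encoder and a two-layer projection head; the symmetric NT-Xent loss
pulls paired latent vectors together against all other in-batch views on
temperature-scaled cosine similarities.

With all 2N projected views identical the loss equals ln(2N-1), which serves
as the "no information" plateau; training on conformer pairs should fall
below it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationSpec, apply_augmentation
from .autodiff import Adam, Tensor, concat
from .conformers import ConformerPool, PairSamplingMode, sample_pair
from .encoder import EncoderConfig, GraphEmbedding, MoleculeBatch, SchNetEncoder
from .mol_io import Dataset
from .nn import Dense, relu
from .utils import derive_seed

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE = 0.1


class ProjectionHead:
    """Two-layer MLP (ReLU) mapping graph embeddings to the contrastive space.

    Output is not normalized here; the loss normalizes via cosine similarity.
    The head is discarded after pretraining.
    """

    def __init__(self, embed_dim: int, proj_dim: int | None = None, seed: int = 0):
        proj_dim = proj_dim or embed_dim // 2
        rng = np.random.default_rng(seed)
        self.lin1 = Dense(embed_dim, embed_dim, rng)
        self.lin2 = Dense(embed_dim, proj_dim, rng)

    def __call__(self, h: Tensor) -> Tensor:
        return self.lin2(relu(self.lin1(h)))

    def parameters(self) -> list[Tensor]:
        return self.lin1.parameters() + self.lin2.parameters()


def project(h: GraphEmbedding | Tensor, head: ProjectionHead) -> Tensor:
    """z = W2 relu(W1 h_G + b1) + b2."""
    h_G = h.h_G if isinstance(h, GraphEmbedding) else h
    return head(h_G)


def nt_xent(z1: Tensor, z2: Tensor, temperature: float = DEFAULT_TEMPERATURE) -> Tensor:
    """Symmetric NT-Xent over a minibatch of N positive pairs.

    All 2N views act as anchors; the positive of view k is its paired view,
    the denominator runs over the other 2N-1 views. Similarities are cosine,
    scaled by 1/temperature; the result is the mean over the 2N anchors.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if z1.shape != z2.shape:
        raise ValueError("view batches must have equal shape")
    n = z1.shape[0]
    z = concat([z1, z2])  # (2N, D)
    sq = (z * z).sum(axis=1, keepdims=True)
    if np.any(sq.data <= 0):
        raise ValueError("zero-norm embedding: cosine similarity undefined")
    zn = z * sq**-0.5
    sims = (zn @ zn.T) * (1.0 / temperature)  # (2N, 2N)

    off_diag = 1.0 - np.eye(2 * n)
    # constant shift for numerical stability; gradient-exact
    shift = np.where(off_diag.astype(bool), sims.data, -np.inf).max(axis=1, keepdims=True)
    exp_terms = (sims - shift).exp() * off_diag
    log_denom = exp_terms.sum(axis=1).log() + shift[:, 0]

    pos_mask = np.zeros((2 * n, 2 * n))
    idx = np.arange(n)
    pos_mask[idx, idx + n] = 1.0
    pos_mask[idx + n, idx] = 1.0
    positives = (sims * pos_mask).sum(axis=1)
    return (log_denom - positives).mean()


@dataclass
class PretrainConfig:
    epochs: int = 300
    batch_size: int = 400
    learning_rate: float = 1e-3
    lr_decay: float = 0.95  # exponential per-epoch factor (0.95 or 0.99 typical)
    temperature: float = DEFAULT_TEMPERATURE
    pairing: PairSamplingMode | AugmentationSpec = field(default_factory=PairSamplingMode)
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.lr_decay <= 1:
            raise ValueError("lr_decay must lie in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class PretrainResult:
    encoder: SchNetEncoder
    head: ProjectionHead
    loss_trace: list[float]  # per-epoch mean NT-Xent
    lr_trace: list[float]


def _draw_views(pool: ConformerPool, pairing, rng):
    if isinstance(pairing, PairSamplingMode):
        return sample_pair(pool, pairing, rng)
    # baseline augmentations perturb the most stable conformer, both views
    # independently
    base = pool.conformers[0]
    return apply_augmentation(base, pairing, rng), apply_augmentation(base, pairing, rng)


def pretrain(
    dataset: Dataset,
    pools: dict[str, ConformerPool],
    cfg: PretrainConfig,
    encoder: SchNetEncoder | None = None,
    head: ProjectionHead | None = None,
    encoder_config: EncoderConfig | None = None,
) -> PretrainResult:
    """Run contrastive pretraining over a molecule dataset.

    Per epoch: shuffle molecules, draw a fresh view pair per molecule via the
    configured pairing, encode both views with the shared encoder, project,
    apply NT-Xent and step Adam. The learning rate decays by ``lr_decay``
    each epoch. Fully reproducible for a fixed config seed.
    """
    smiles = [s for s in dataset.smiles() if s in pools]
    if not smiles:
        raise ValueError("no molecules with conformer pools to pretrain on")
    if encoder is None:
        encoder = SchNetEncoder(encoder_config, seed=derive_seed(cfg.seed, "encoder-init"))
    if head is None:
        head = ProjectionHead(encoder.config.embed_dim, seed=derive_seed(cfg.seed, "head-init"))
    params = encoder.parameters() + head.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    rng_shuffle = np.random.default_rng(derive_seed(cfg.seed, "shuffle"))
    rng_pair = np.random.default_rng(derive_seed(cfg.seed, "pairing"))

    loss_trace: list[float] = []
    lr_trace: list[float] = []
    n = len(smiles)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.learning_rate * cfg.lr_decay**epoch
        order = rng_shuffle.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            chunk = order[start : start + cfg.batch_size]
            views1, views2 = [], []
            for i in chunk:
                a, b = _draw_views(pools[smiles[i]], cfg.pairing, rng_pair)
                views1.append(a)
                views2.append(b)
            batch = MoleculeBatch.from_molecules(views1 + views2)
            z = project(encoder(batch), head)
            b = len(chunk)
            loss = nt_xent(z.gather(np.arange(b)), z.gather(np.arange(b, 2 * b)), cfg.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * b
            count += b
            del z, loss  # free the graph before building the next one
        loss_trace.append(total / count)
        lr_trace.append(opt.lr)
        logger.info("pretrain epoch %d: lr=%.2e mean_loss=%.4f", epoch, opt.lr, loss_trace[-1])
    return PretrainResult(encoder, head, loss_trace, lr_trace)
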
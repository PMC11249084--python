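"""Scaffold splitting, fine-tuning and the evaluation protocol.

Datasets are partitioned 80/10/10 by Bemis–Murcko scaffold so that no
scaffold appears in more than one split, testing structural generalization.
Fine-tuning attaches a linear task head to the (pretrained or fresh) encoder
and trains end to end with Adam under an exponentially decaying learning
rate; the reported test metric is taken at the epoch with the best
validation metric. Runs repeat over several seeds and report mean ± std.

Regression targets are standardized with train-split statistics during
optimization and predictions are mapped back before computing RMSE/MAE, so
metrics are in the original target units. Multi-task metrics are the
arithmetic mean of per-task metrics over tasks with usable entries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Adam
from .conformers import ConformerPool
from .encoder import EncoderConfig, MoleculeBatch, SchNetEncoder, load_checkpoint
from .mol_io import (
    CLASSIFICATION,
    REGRESSION,
    Dataset,
    EmbeddingError,
    Molecule3D,
    embed_molecule,
    scaffold_key,
)
from .nn import Dense
from .utils import derive_seed

logger = logging.getLogger(__name__)

RMSE = "RMSE"
MAE = "MAE"
ROC_AUC = "ROC-AUC"


# ---------------------------------------------------------------------------
# scaffold split
# ---------------------------------------------------------------------------


@dataclass
class SplitIndices:
    train: list[int]
    valid: list[int]
    test: list[int]
    chirality_aware: bool = True

    def all_indices(self) -> list[int]:
        return self.train + self.valid + self.test


def scaffold_split(
    dataset: Dataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    chirality_aware: bool = True,
) -> SplitIndices:
    """Greedy scaffold split: whole scaffold groups, largest first.

    Groups are ordered by (size descending, scaffold string ascending) and
    assigned to the first of train/valid/test whose capacity (fraction × n)
    they fit; a group too large for every split falls back to train with a
    warning. Deterministic for a given dataset.
    """
    if not len(dataset):
        raise ValueError("cannot split an empty dataset")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset.records):
        groups.setdefault(scaffold_key(rec.smiles, chirality_aware), []).append(i)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    n = len(dataset)
    caps = [f * n for f in fractions]
    splits: list[list[int]] = [[], [], []]
    for key, members in ordered:
        placed = False
        for s in range(3):
            if len(splits[s]) + len(members) <= caps[s] + 1e-9:
                splits[s].extend(members)
                placed = True
                break
        if not placed:
            warnings.warn(
                f"scaffold group of size {len(members)} exceeds every split capacity; "
                "assigning to train"
            )
            splits[0].extend(members)
    return SplitIndices(*(sorted(s) for s in splits), chirality_aware=chirality_aware)


def assert_no_scaffold_leakage(dataset: Dataset, split: SplitIndices) -> None:
    """Raise if any scaffold string occurs in more than one split."""
    seen: dict[str, int] = {}
    for s, idxs in enumerate((split.train, split.valid, split.test)):
        for i in idxs:
            key = scaffold_key(dataset.records[i].smiles, split.chirality_aware)
            if key in seen and seen[key] != s:
                raise AssertionError(f"scaffold {key!r} leaks across splits")
            seen[key] = s


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _per_task_mean(values: list[float]) -> float:
    # NaN when no task has usable entries (e.g. a single-class ROC-AUC split)
    return float(np.mean(values)) if values else float("nan")


def regression_metric(
    y_true: np.ndarray, y_pred: np.ndarray, mask: np.ndarray, metric: str
) -> float:
    """Masked multi-task RMSE or MAE, averaged over tasks."""
    vals = []
    for t in range(y_true.shape[1]):
        m = mask[:, t]
        if not m.any():
            continue
        err = y_pred[m, t] - y_true[m, t]
        vals.append(float(np.sqrt(np.mean(err**2)) if metric == RMSE else np.mean(np.abs(err))))
    return _per_task_mean(vals)


def classification_metric(y_true: np.ndarray, score: np.ndarray, mask: np.ndarray) -> float:
    """Masked multi-task ROC-AUC on the positive-class score, averaged over tasks."""
    vals = []
    for t in range(y_true.shape[1]):
        m = mask[:, t]
        labels = y_true[m, t]
        if m.sum() < 2 or len(np.unique(labels)) < 2:
            continue
        vals.append(float(roc_auc_score(labels, score[m, t])))
    return _per_task_mean(vals)


def evaluate_metric(
    y_true: np.ndarray, y_pred: np.ndarray, mask: np.ndarray, metric: str
) -> float:
    if metric in (RMSE, MAE):
        return regression_metric(y_true, y_pred, mask, metric)
    return classification_metric(y_true, y_pred, mask)


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------


@dataclass
class FinetuneConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 0.95
    seeds: tuple[int, ...] = (0, 1, 2)
    metric: str | None = None  # default: RMSE for regression, ROC-AUC for classification
    embed_seed: int = 0  # conformer embedding when no pool cache is given

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("at least one seed required")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class MetricsReport:
    metric: str
    per_seed: list[float]
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self):
        self.mean = float(np.mean(self.per_seed))
        self.std = float(np.std(self.per_seed))


def _lower_is_better(metric: str) -> bool:
    return metric in (RMSE, MAE)


def _resolve_geometries(
    dataset: Dataset,
    pools: dict[str, ConformerPool] | None,
    embed_seed: int,
) -> dict[int, Molecule3D]:
    """Most-stable-conformer 3D input per record; failures dropped with a warning."""
    out: dict[int, Molecule3D] = {}
    cache: dict[str, Molecule3D | None] = {}
    for i, rec in enumerate(dataset.records):
        if rec.smiles not in cache:
            if pools is not None and rec.smiles in pools:
                cache[rec.smiles] = pools[rec.smiles].conformers[0]
            else:
                try:
                    cache[rec.smiles] = embed_molecule(rec.smiles, embed_seed)
                except EmbeddingError as err:
                    logger.warning("dropping molecule from fine-tuning: %s", err)
                    cache[rec.smiles] = None
        if cache[rec.smiles] is not None:
            out[i] = cache[rec.smiles]
    return out


def _fresh_encoder(
    source: SchNetEncoder | str | None,
    encoder_config: EncoderConfig | None,
    init_seed: int,
) -> SchNetEncoder:
    if source is None:
        return SchNetEncoder(encoder_config, seed=init_seed)
    if isinstance(source, SchNetEncoder):
        clone = SchNetEncoder(source.config, seed=init_seed)
        for p, q in zip(clone.parameters(), source.parameters()):
            p.data = q.data.copy()
        return clone
    return load_checkpoint(source)


def _forward_predictions(encoder, head, geoms, idxs, batch_size=256) -> np.ndarray:
    preds = []
    for start in range(0, len(idxs), batch_size):
        chunk = idxs[start : start + batch_size]
        batch = MoleculeBatch.from_molecules([geoms[i] for i in chunk])
        preds.append(head(encoder(batch).h_G).data)
    return np.concatenate(preds)


def finetune(
    encoder_source: SchNetEncoder | str | None,
    dataset: Dataset,
    split: SplitIndices,
    cfg: FinetuneConfig,
    pools: dict[str, ConformerPool] | None = None,
    encoder_config: EncoderConfig | None = None,
) -> MetricsReport:
    """Fine-tune on property targets; report the test metric over seeds.

    ``encoder_source`` is a pretrained encoder (object or checkpoint path) or
    None for the train-from-scratch baseline. The whole model (encoder not
    frozen, plus a linear task head) trains with masked MSE (regression, on
    standardized targets) or masked binary cross-entropy with logits
    (classification). The test metric is recorded at the best-validation
    epoch, separately per seed.
    """
    metric = cfg.metric or (RMSE if dataset.task_type == REGRESSION else ROC_AUC)
    if dataset.task_type == CLASSIFICATION and metric != ROC_AUC:
        raise ValueError(f"metric {metric} incompatible with classification")
    geoms = _resolve_geometries(dataset, pools, cfg.embed_seed)
    train = [i for i in split.train if i in geoms]
    valid = [i for i in split.valid if i in geoms]
    test = [i for i in split.test if i in geoms]
    if not train or not test:
        raise ValueError("empty train or test split after geometry resolution")

    y = np.stack([dataset.records[i].targets for i in range(len(dataset))])
    mask = np.stack([dataset.records[i].target_mask for i in range(len(dataset))])

    # standardize regression targets with train statistics
    if dataset.task_type == REGRESSION:
        tr_y, tr_m = y[train], mask[train]
        mu = np.array([tr_y[tr_m[:, t], t].mean() if tr_m[:, t].any() else 0.0
                       for t in range(y.shape[1])])
        sd = np.array([tr_y[tr_m[:, t], t].std() if tr_m[:, t].any() else 1.0
                       for t in range(y.shape[1])])
        sd = np.where(sd > 1e-12, sd, 1.0)
    else:
        mu, sd = np.zeros(y.shape[1]), np.ones(y.shape[1])
    y_std = (y - mu) / sd

    per_seed: list[float] = []
    for seed in cfg.seeds:
        encoder = _fresh_encoder(encoder_source, encoder_config, derive_seed(seed, "ft-encoder"))
        rng = np.random.default_rng(derive_seed(seed, "ft-head"))
        head = Dense(encoder.config.embed_dim, dataset.n_tasks, rng)
        opt = Adam(encoder.parameters() + head.parameters(), lr=cfg.learning_rate)
        shuffle_rng = np.random.default_rng(derive_seed(seed, "ft-shuffle"))

        best_valid = np.inf if _lower_is_better(metric) else -np.inf
        best_test = np.nan
        for epoch in range(cfg.epochs):
            opt.lr = cfg.learning_rate * cfg.lr_decay**epoch
            order = shuffle_rng.permutation(len(train))
            for start in range(0, len(train), cfg.batch_size):
                idxs = [train[k] for k in order[start : start + cfg.batch_size]]
                batch = MoleculeBatch.from_molecules([geoms[i] for i in idxs])
                pred = head(encoder(batch).h_G)
                tgt = y_std[idxs]
                m = mask[idxs].astype(np.float64)
                denom = max(m.sum(), 1.0)
                if dataset.task_type == REGRESSION:
                    diff = (pred - tgt) * m
                    loss = (diff * diff).sum() * (1.0 / denom)
                else:
                    from .autodiff import softplus

                    # BCE with logits: softplus(x) - x*y, masked mean
                    loss = ((softplus(pred) - pred * tgt) * m).sum() * (1.0 / denom)
                opt.zero_grad()
                loss.backward()
                opt.step()
                del pred, loss  # free the graph before the next batch

            def _score(idxs):
                raw = _forward_predictions(encoder, head, geoms, idxs)
                pred = raw * sd + mu if dataset.task_type == REGRESSION else raw
                return evaluate_metric(y[idxs], pred, mask[idxs], metric)

            v = _score(valid) if valid else _score(train)
            better = (
                not np.isnan(v)
                and (v < best_valid if _lower_is_better(metric) else v > best_valid)
            )
            if better:
                best_valid = v
                best_test = _score(test)
        if np.isnan(best_test):  # validation metric never defined; use final model
            best_test = _score(test)
        per_seed.append(best_test)
        logger.info("finetune seed %d: best valid %s=%.4f test=%.4f",
                    seed, metric, best_valid, best_test)
    return MetricsReport(metric, per_seed)


def reduced_training_experiment(
    dataset: Dataset,
    sizes: list[int],
    cfg: FinetuneConfig,
    encoder_source: SchNetEncoder | str,
    split: SplitIndices | None = None,
    pools: dict[str, ConformerPool] | None = None,
    encoder_config: EncoderConfig | None = None,
    subsample_seed: int = 0,
) -> list[tuple[int, MetricsReport, MetricsReport]]:
    """Low-data study: fine-tune on seeded train subsets, with vs without pretraining.

    Returns one (size, pretrained_report, scratch_report) row per size.
    """
    split = split or scaffold_split(dataset)
    rows = []
    for size in sizes:
        if size > len(split.train):
            raise ValueError(f"requested {size} train molecules, split has {len(split.train)}")
        rng = np.random.default_rng(derive_seed(subsample_seed, "subsample", size))
        sub_train = sorted(rng.choice(split.train, size=size, replace=False).tolist())
        sub = replace(split, train=sub_train)
        pre = finetune(encoder_source, dataset, sub, cfg, pools, encoder_config)
        scratch = finetune(None, dataset, sub, cfg, pools, encoder_config)
        rows.append((size, pre, scratch))
    return rows
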
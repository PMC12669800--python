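"""Losses, label transforms, metrics, splits, and training loops.

Affinities in molar units are transformed to dimensionless p-affinity
scores, p = −log10(value / 1 M), so Ki/Kd/IC50 measurements share one
scale. Binding-site training uses the focal loss to cope with the
extreme residue-level class imbalance of real binding-site data (the
curated complex corpus this package models has ~134.9k binding vs
~6.489M nonbinding residues, about 1:48). Occurrence training uses
binary cross-entropy and affinity training mean squared error on the
p-affinity scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn import metrics as skm

from .autodiff import Adam, Tensor
from .complex_graph import build_hetero_graph
from .config import ModelConfig
from .decoders import AffinityDecoder, OccurrenceDecoder, SiteDecoder
from .drug_featurizer import DrugGraph, build_drug_graph
from .encoders import DrugEncoder, ProteinEncoder
from .autodiff import gather_rows
from .fixtures import ToyComplex, stub_embedder
from .protein_featurizer import ResidueGraph, build_residue_graph
from .structure_io import (ProteinStructure, extract_pocket,
                           pocket_from_ligand)

logger = logging.getLogger(__name__)

__all__ = [
    "PDBBIND_SITE_RESIDUE_COUNTS",
    "binding_imbalance_ratio",
    "paffinity",
    "focal_loss",
    "binary_cross_entropy",
    "compute_metrics",
    "MetricReport",
    "split_dataset",
    "read_site_labels",
    "PairRecord",
    "FeaturizedPair",
    "featurize_toy_complex",
    "TaskModel",
    "train_task",
    "TrainResult",
]

Task = Literal["occurrence", "site", "affinity"]

# residue-level label counts of the curated binding-site corpus
PDBBIND_SITE_RESIDUE_COUNTS = {"binding": 134_906, "nonbinding": 6_489_442}


def binding_imbalance_ratio(binding: int | None = None,
                            nonbinding: int | None = None) -> int:
    """Rounded nonbinding:binding residue ratio (the '1:N' imbalance)."""
    b = PDBBIND_SITE_RESIDUE_COUNTS["binding"] if binding is None else binding
    n = (PDBBIND_SITE_RESIDUE_COUNTS["nonbinding"] if nonbinding is None
         else nonbinding)
    return round(n / b)


# ---------------------------------------------------------------------------
# label transforms and losses

def paffinity(value: float) -> float:
    """p-affinity = −log10(molar value / 1 M); requires value > 0."""
    if value <= 0:
        raise ValueError(f"affinity must be positive molar, got {value}")
    return -math.log10(value)


def _clip_probs(probs: Tensor) -> Tensor:
    eps = 1e-7
    if np.any(probs.data <= 0.0) or np.any(probs.data >= 1.0):
        logger.warning("probabilities outside (0,1); clipping at %g", eps)
    return probs.clip(eps, 1.0 - eps)


def binary_cross_entropy(probs: Tensor, labels: np.ndarray) -> Tensor:
    p = _clip_probs(probs)
    y = Tensor(np.asarray(labels, dtype=np.float64))
    return (-(y * p.log() + (1.0 - y) * (1.0 - p).log())).mean()


def focal_loss(probs: Tensor | np.ndarray, labels: np.ndarray,
               alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Mean focal loss −α_t (1−p_t)^γ log(p_t) over the label vector.

    α weighs positives, (1−α) negatives; γ = 0 recovers an α-weighted
    cross-entropy. Probabilities at the boundary are clipped at 1e-7.
    """
    if not isinstance(probs, Tensor):
        probs = Tensor(probs)
    y = np.asarray(labels, dtype=np.float64)
    if probs.data.shape != y.shape:
        raise ValueError("probs and labels must be aligned")
    p = _clip_probs(probs)
    yt = Tensor(y)
    p_t = p * yt + (1.0 - p) * (1.0 - yt)
    alpha_t = Tensor(alpha * y + (1.0 - alpha) * (1.0 - y))
    return (-(alpha_t * (1.0 - p_t) ** gamma * p_t.log())).mean()


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricReport:
    task: str
    n: int
    values: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.values[key]

    def to_dict(self) -> dict:
        return {"task": self.task, "n": self.n, **self.values}


def compute_metrics(predictions: np.ndarray, labels: np.ndarray,
                    task: Task) -> MetricReport:
    """Standard classification or regression metrics for one task.

    Classification: MCC, F1, Accuracy, Specificity at a 0.5 threshold
    plus rank-based AUROC/AUPRC (reported as NaN when the labels are
    single-class). Regression: RMSE, MAE, Pearson, Spearman.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if len(predictions) == 0 or len(predictions) != len(labels):
        raise ValueError("predictions and labels must be nonempty and aligned")
    if task == "affinity":
        err = predictions - labels
        values = {
            "rmse": float(np.sqrt(np.mean(err ** 2))),
            "mae": float(np.mean(np.abs(err))),
            "pearson": float(stats.pearsonr(predictions, labels)[0])
            if len(labels) > 1 else float("nan"),
            "spearman": float(stats.spearmanr(predictions, labels)[0])
            if len(labels) > 1 else float("nan"),
        }
        return MetricReport(task=task, n=len(labels), values=values)

    y = labels.astype(int)
    yhat = (predictions >= 0.5).astype(int)
    tp = int(np.sum((yhat == 1) & (y == 1)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    single_class = len(np.unique(y)) < 2
    values = {
        "mcc": float(skm.matthews_corrcoef(y, yhat)) if not single_class
        else float("nan"),
        "f1": float(skm.f1_score(y, yhat, zero_division=0)),
        "accuracy": (tp + tn) / len(y),
        "specificity": tn / (tn + fp) if (tn + fp) > 0 else float("nan"),
        "auroc": float(skm.roc_auc_score(y, predictions))
        if not single_class else float("nan"),
        "auprc": float(skm.average_precision_score(y, predictions))
        if not single_class else float("nan"),
    }
    return MetricReport(task=task, n=len(y), values=values)


# ---------------------------------------------------------------------------
# dataset handling

@dataclass
class PairRecord:
    """One drug–target pair as listed in a pairs table."""
    pair_id: str
    protein_ref: str
    drug_ref: str
    occurrence: int | None = None
    affinity_molar: float | None = None
    measure: str = ""
    label_file: str | None = None

    def __post_init__(self):
        if self.affinity_molar is not None and self.affinity_molar <= 0:
            raise ValueError("affinity must be a positive molar value")


def split_dataset(records: Sequence, ratios: tuple[int, int, int] = (7, 1, 2),
                  seed: int = 0) -> tuple[list, list, list]:
    """Seeded disjoint train/val/test split at the given integer ratios."""
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    total = sum(ratios)
    n_val = round(n * ratios[1] / total)
    n_test = round(n * ratios[2] / total)
    order = np.random.default_rng(seed).permutation(n)
    test = [records[i] for i in order[:n_test]]
    val = [records[i] for i in order[n_test:n_test + n_val]]
    train = [records[i] for i in order[n_test + n_val:]]
    return train, val, test


def read_site_labels(path: str | Path, structure: ProteinStructure,
                     strict: bool = True) -> np.ndarray:
    """Binary site-label vector aligned with the structure's residues.

    The file lists one binding residue per line as
    ``<chain>:<resnum><icode?>``; unlisted residues are 0. Unknown
    residues raise in strict mode and are skipped with a warning
    otherwise.
    """
    from .structure_io import read_pocket_selection
    selection = read_pocket_selection(path)
    index = structure.residue_index()
    labels = np.zeros(structure.n_residues, dtype=np.intp)
    for member in selection.members:
        if member not in index:
            if strict:
                raise KeyError(f"label residue {member} absent from structure")
            logger.warning("skipping unknown label residue %s", member)
            continue
        labels[index[member]] = 1
    return labels


# ---------------------------------------------------------------------------
# featurized samples and task models

@dataclass
class FeaturizedPair:
    pair_id: str
    residue_graph: ResidueGraph
    drug_graph: DrugGraph
    pocket_indices: np.ndarray | None = None   # into the residue graph
    hetero: object | None = None               # HeteroComplexGraph
    occurrence: int | None = None
    site_labels: np.ndarray | None = None
    paffinity: float | None = None
    structure: ProteinStructure | None = None  # kept for residue-level output


def featurize_toy_complex(cx: ToyComplex, config: ModelConfig,
                          embedder=None, with_surface: bool = True,
                          with_hetero: bool = False) -> FeaturizedPair:
    """Featurize a synthetic complex for any of the three tasks."""
    embedder = embedder or stub_embedder()
    rg = build_residue_graph(cx.protein, embedder, cutoff=config.cutoff,
                             sigma=config.sigma,
                             surface_grid=config.surface_grid,
                             with_surface=with_surface)
    dg = build_drug_graph(cx.drug)
    pocket_idx = None
    hetero = None
    if with_hetero:
        selection = pocket_from_ligand(cx.protein, cx.drug.coords,
                                       cutoff=config.pocket_cutoff)
        pocket = extract_pocket(cx.protein, selection)
        pocket_idx = np.array(pocket.parent_indices, dtype=np.intp)
        hetero = build_hetero_graph(pocket, cx.drug.coords,
                                    k=config.k_neighbors, sigma=config.sigma)
    return FeaturizedPair(
        pair_id=f"toy{cx.seed}", residue_graph=rg, drug_graph=dg,
        pocket_indices=pocket_idx, hetero=hetero,
        occurrence=cx.occurrence_label, site_labels=cx.site_labels,
        paffinity=cx.affinity)


class TaskModel:
    """Shared encoders plus the task-specific decoder for one task."""

    def __init__(self, task: Task, config: ModelConfig, seed: int = 0):
        self.task = task
        self.config = config
        rng = np.random.default_rng(seed)
        self.protein_encoder = ProteinEncoder(config, rng)
        self.drug_encoder = DrugEncoder(config, rng)
        if task == "occurrence":
            self.decoder = OccurrenceDecoder(config, rng)
        elif task == "site":
            self.decoder = SiteDecoder(config, rng)
        elif task == "affinity":
            self.decoder = AffinityDecoder(config, rng)
        else:
            raise ValueError(f"unknown task {task!r}")

    def parameters(self) -> list[Tensor]:
        return (self.protein_encoder.parameters()
                + self.drug_encoder.parameters()
                + self.decoder.parameters())

    def state_dict(self) -> dict:
        out = {}
        for prefix, mod in (("protein", self.protein_encoder),
                            ("drug", self.drug_encoder),
                            ("decoder", self.decoder)):
            for k, v in mod.state_dict().items():
                out[f"{prefix}.{k}"] = v
        return out

    def load_state_dict(self, state: dict) -> None:
        for prefix, mod in (("protein", self.protein_encoder),
                            ("drug", self.drug_encoder),
                            ("decoder", self.decoder)):
            sub = {k[len(prefix) + 1:]: v for k, v in state.items()
                   if k.startswith(prefix + ".")}
            mod.load_state_dict(sub)

    def forward(self, sample: FeaturizedPair, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        hp = self.protein_encoder(sample.residue_graph)
        hd = self.drug_encoder(sample.drug_graph)
        if self.task == "occurrence":
            return self.decoder(hp, hd, training=training,
                                rng=rng).probability
        if self.task == "site":
            return self.decoder(hp, hd, training=training,
                                rng=rng).probabilities
        if sample.hetero is None or sample.pocket_indices is None:
            raise ValueError("affinity task needs a hetero graph and pocket")
        from .encoders import ProteinEncoding
        pocket_emb = ProteinEncoding(
            embeddings=gather_rows(hp.embeddings, sample.pocket_indices))
        return self.decoder(pocket_emb, hd, sample.hetero,
                            training=training, rng=rng).paffinity

    def predict(self, sample: FeaturizedPair) -> np.ndarray | float:
        out = self.forward(sample, training=False)
        return out.data if out.data.ndim else float(out.data)


def _sample_loss(model: TaskModel, sample: FeaturizedPair, out: Tensor,
                 loss_name: str, config: ModelConfig) -> Tensor:
    if model.task == "occurrence":
        return binary_cross_entropy(out.reshape(1),
                                    np.array([sample.occurrence]))
    if model.task == "site":
        if loss_name == "bce":
            return binary_cross_entropy(out, sample.site_labels)
        return focal_loss(out, sample.site_labels,
                          alpha=config.focal_alpha, gamma=config.focal_gamma)
    diff = out - sample.paffinity
    return diff * diff


@dataclass
class TrainResult:
    model: TaskModel
    history: list[float]
    train_metrics: MetricReport
    val_metrics: MetricReport | None
    best_state: dict


def _evaluate(model: TaskModel, samples: list[FeaturizedPair]) -> MetricReport:
    preds, labels = [], []
    for s in samples:
        out = model.predict(s)
        if model.task == "site":
            preds.append(out)
            labels.append(s.site_labels)
        elif model.task == "occurrence":
            preds.append([out])
            labels.append([s.occurrence])
        else:
            preds.append([out])
            labels.append([s.paffinity])
    preds = np.concatenate(preds)
    labels = np.concatenate(labels)
    report = compute_metrics(preds, labels,
                             "affinity" if model.task == "affinity"
                             else "occurrence")
    report.task = model.task
    return report


def train_task(task: Task, dataset: list[FeaturizedPair],
               config: ModelConfig, seed: int = 0,
               val_dataset: list[FeaturizedPair] | None = None,
               loss: str = "default",
               epochs: int | None = None) -> TrainResult:
    """Train one task head on featurized pairs with Adam.

    Per-sample gradient steps in a seeded shuffled order; the best state
    by validation loss (training loss when no validation set is given)
    is retained, with early stopping after ``config.patience`` epochs
    without improvement. Aborts on non-finite loss.
    """
    ss = np.random.SeedSequence(seed)
    init_seed, shuffle_seed, dropout_seed = [
        int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(3)]
    model = TaskModel(task, config, seed=init_seed)
    if task == "affinity":
        # start the regression head at the mean training target so early
        # epochs refine structure instead of traversing the offset
        ybar = float(np.mean([s.paffinity for s in dataset]))
        model.decoder._params["aff_b2"].data[:] = ybar
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    drop_rng = np.random.default_rng(dropout_seed)
    n_epochs = epochs if epochs is not None else config.epochs

    history: list[float] = []
    best_loss = np.inf
    best_state = model.state_dict()
    stale = 0
    for epoch in range(n_epochs):
        order = shuffle_rng.permutation(len(dataset))
        total = 0.0
        for idx in order:
            sample = dataset[idx]
            out = model.forward(sample, training=True, rng=drop_rng)
            loss_t = _sample_loss(model, sample, out, loss, config)
            if not np.isfinite(loss_t.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, sample "
                    f"{sample.pair_id}: {loss_t.data}")
            opt.zero_grad()
            loss_t.backward()
            opt.step()
            total += float(loss_t.data)
        epoch_loss = total / len(dataset)
        history.append(epoch_loss)

        if val_dataset:
            with_val = 0.0
            for s in val_dataset:
                out = model.forward(s, training=False)
                with_val += float(_sample_loss(model, s, out, loss,
                                               config).data)
            monitor = with_val / len(val_dataset)
        else:
            monitor = epoch_loss
        if monitor < best_loss - 1e-9:
            best_loss = monitor
            best_state = model.state_dict()
            stale = 0
        else:
            stale += 1
            if val_dataset and stale >= config.patience:
                logger.info("early stopping at epoch %d", epoch)
                break

    model.load_state_dict(best_state)
    train_metrics = _evaluate(model, dataset)
    val_metrics = _evaluate(model, val_dataset) if val_dataset else None
    return TrainResult(model=model, history=history,
                       train_metrics=train_metrics, val_metrics=val_metrics,
                       best_state=best_state)
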
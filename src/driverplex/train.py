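"""Supervised driver-gene classifier: directional encoder + linear head.

The classifier trains on the augmented label set (known + pseudo positives,
inferred negatives) with

    L = L_sup + lambda * L_reg

where L_sup is the summed cross-entropy over labeled nodes and L_reg the
consistency regularizer penalizing per-node directional gates that stray
from the population mean gate (computed after averaging each node's gate
over all layers and graphs).  Early stopping monitors the supervised loss
on a held-out fraction of the labeled nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .conv import DirectionalEncoder, EncoderConfig
from .graph import MultiplexGraph
from .nn import Tensor

logger = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    lr: float = 0.01
    weight_decay: float = 0.0
    dropout: float = 0.5
    n_layers: int = 3
    hidden: int = 256
    alpha: float = 0.5
    lam: float = 0.0003          # weight of the consistency regularizer
    epochs: int = 1000
    patience: int = 30
    min_delta: float = 1e-4      # minimum val-loss improvement that resets patience
    val_fraction: float = 0.1
    max_degree: int = 512
    ablate_directionality: bool = False

    def encoder_config(self, n_features: int) -> EncoderConfig:
        return EncoderConfig(n_features=n_features, hidden=self.hidden,
                             n_layers=self.n_layers, alpha=self.alpha,
                             dropout=self.dropout, max_degree=self.max_degree)


@dataclass
class ClassifierHead:
    W: Tensor
    b: Tensor

    @classmethod
    def create(cls, hidden: int, seed: int = 0) -> "ClassifierHead":
        rng = np.random.default_rng(seed)
        lim = np.sqrt(6.0 / (hidden + 2))
        return cls(nn.parameter(rng.uniform(-lim, lim, (hidden, 2))),
                   nn.parameter(np.zeros(2)))

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def classify(H: Tensor, head: ClassifierHead) -> Tensor:
    """Row-stochastic predictive distribution (n x 2); column 1 is the
    driver probability."""
    return nn.softmax(nn.matmul(H, head.W) + head.b, axis=1)


def _log_probs(H: Tensor, head: ClassifierHead) -> Tensor:
    return nn.log_softmax(nn.matmul(H, head.W) + head.b, axis=1)


def supervised_loss(log_probs: Tensor, labeled_idx: np.ndarray,
                    labels: np.ndarray) -> Tensor:
    """Summed (not averaged) cross-entropy over the labeled node set."""
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    picked = nn.take_rows(log_probs, np.asarray(labeled_idx, dtype=np.intp))
    onehot = np.zeros((len(labels), 2))
    onehot[np.arange(len(labels)), labels] = 1.0
    return -(picked * Tensor(onehot)).sum()


def consistency_reg(gates: list[tuple[int, int, Tensor]]) -> Tensor:
    """Mean squared deviation of per-node gates from the population mean.

    Each node's forward gate is first averaged over all (layer, graph)
    pairs; the backward gate is its complement.  The result equals
    2 * population-variance of the averaged forward gates.
    """
    if not gates:
        raise ValueError("no gate diagonals provided")
    K = len(gates)
    g_fwd = gates[0][2] * (1.0 / K)
    for _, _, g in gates[1:]:
        g_fwd = g_fwd + g * (1.0 / K)
    g_bwd = 1.0 - g_fwd
    n = g_fwd.shape[0]
    mean_fwd = g_fwd.mean()
    mean_bwd = g_bwd.mean()
    d_fwd = g_fwd - mean_fwd
    d_bwd = g_bwd - mean_bwd
    return ((d_fwd * d_fwd).sum() + (d_bwd * d_bwd).sum()) * (1.0 / n)


def total_loss(l_sup: Tensor, l_reg: Tensor, lam: float) -> Tensor:
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return l_sup + lam * l_reg


@dataclass
class TrainedModel:
    encoder: DirectionalEncoder
    head: ClassifierHead
    config: TrainingConfig
    history: dict[str, list[float]] = field(default_factory=dict)

    def scores(self, graph: MultiplexGraph) -> np.ndarray:
        """Eval-mode driver probability per gene."""
        H, _ = self.encoder.encode(
            graph, training=False,
            symmetrize=self.config.ablate_directionality)
        return classify(H, self.head).data[:, 1]


def _stratified_val_split(idx: np.ndarray, labels: np.ndarray,
                          fraction: float, rng: np.random.Generator):
    """Hold out ~fraction of each class for early stopping."""
    train_mask = np.ones(len(idx), dtype=bool)
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        n_val = int(round(fraction * len(members)))
        if n_val and len(members) > n_val:
            val = rng.choice(members, size=n_val, replace=False)
            train_mask[val] = False
    return idx[train_mask], labels[train_mask], idx[~train_mask], labels[~train_mask]


def train(graph: MultiplexGraph, labeled_idx: np.ndarray, labels: np.ndarray,
          config: TrainingConfig | None = None, seed: int = 0) -> TrainedModel:
    """Fit the classifier with early stopping on validation loss."""
    config = config or TrainingConfig()
    labeled_idx = np.asarray(labeled_idx, dtype=np.intp)
    labels = np.asarray(labels, dtype=int)
    if len(labeled_idx) == 0:
        raise ValueError("no labeled nodes")
    rng = np.random.default_rng(seed)
    tr_idx, tr_y, va_idx, va_y = _stratified_val_split(
        labeled_idx, labels, config.val_fraction, rng)
    if len(va_idx) == 0:  # too few labels for a validation split
        va_idx, va_y = tr_idx, tr_y

    target_graph = (graph.symmetrized() if config.ablate_directionality
                    else graph)
    operators = target_graph.operators()
    encoder = DirectionalEncoder(config.encoder_config(graph.n_features),
                                 n_graphs=graph.n_layers,
                                 seed=int(rng.integers(2**31)))
    head = ClassifierHead.create(config.hidden, seed=int(rng.integers(2**31)))
    params = encoder.parameters() + head.parameters()
    opt = nn.AdamW(params, lr=config.lr, weight_decay=config.weight_decay)

    history = {"train": [], "val": []}
    best_val, stall = np.inf, 0
    best_state = None
    drop_rng = np.random.default_rng(int(rng.integers(2**31)))
    for epoch in range(config.epochs):
        H, gates = encoder.encode(operators=operators, X=graph.X,
                                  training=True, rng=drop_rng,
                                  collect_gates=True)
        logp = _log_probs(H, head)
        l_sup = supervised_loss(logp, tr_idx, tr_y)
        loss = total_loss(l_sup, consistency_reg(gates), config.lam)
        value = loss.item()
        if not np.isfinite(value):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        H_eval, _ = encoder.encode(operators=operators, X=graph.X,
                                   training=False)
        val_loss = supervised_loss(_log_probs(H_eval, head), va_idx,
                                   va_y).item() / len(va_idx)
        history["train"].append(value)
        history["val"].append(val_loss)
        if val_loss < best_val - config.min_delta:
            best_val, stall = val_loss, 0
            best_state = (encoder.state_dict(),
                          [p.data.copy() for p in head.parameters()])
        else:
            stall += 1
            if stall >= config.patience:
                logger.info("early stop at epoch %d (best val %.4f)",
                            epoch, best_val)
                break
    if best_state is not None:
        encoder.load_state_dict(best_state[0])
        for p, d in zip(head.parameters(), best_state[1]):
            p.data[...] = d
    return TrainedModel(encoder, head, config, history)


def ranked_table(graph: MultiplexGraph, scores: np.ndarray,
                 positive_idx: np.ndarray, pseudo_idx: np.ndarray,
                 negative_idx: np.ndarray, exclude_train: bool = False):
    """Ranked gene table (symbol, score, label_status), best first."""
    import pandas as pd

    status = np.array(["unlabeled"] * graph.n, dtype=object)
    status[np.asarray(negative_idx, dtype=np.intp)] = "inferred_negative"
    status[np.asarray(pseudo_idx, dtype=np.intp)] = "pseudo_positive"
    status[np.asarray(positive_idx, dtype=np.intp)] = "known_positive"
    df = pd.DataFrame({"gene": graph.universe.symbols, "score": scores,
                       "label_status": status})
    if exclude_train:
        df = df[df.label_status == "unlabeled"]
    return df.sort_values(["score", "gene"], ascending=[False, True],
                          ignore_index=True)
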
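"""Negative-sample inference by internal contrastive learning (ICL).

No trustworthy non-driver gene list exists, so high-confidence negatives
are inferred from the positives alone.  A one-class model is trained on
positive samples to capture the internal consistency of their feature
vectors: each vector x of length f is decomposed into m = f - k + 1 sliding
window pairs (a_j, b_j), where a_j is the contiguous window of length k
starting at position j and b_j the concatenation of the remaining entries.
Dual encoders G (window) and F (complement) with unit-norm outputs are
trained so that F(b_j) identifies its own window a_j among all m candidate
windows of the same sample:

    l_j = -log softmax_j( F(b_j) . G(a_j') / tau )

The anomaly score of any gene is y(x) = sum_j l_j; genes whose windows are
hard to match violate the internal structure of the positive class, so the
top-scoring genes are selected as the negative set (one per positive).

By default the model runs on the consensus embeddings Z from contrastive
pretraining; raw feature mode is available for direct use and testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

logger = logging.getLogger(__name__)


@dataclass
class WindowPairs:
    """Sliding windows and their complements for one feature vector."""

    windows: np.ndarray      # (m, k)
    complements: np.ndarray  # (m, f - k)
    k: int

    @property
    def m(self) -> int:
        return self.windows.shape[0]


def build_windows(x: np.ndarray, k: int) -> WindowPairs:
    x = np.asarray(x, dtype=np.float64).ravel()
    f = len(x)
    if not 1 <= k < f:
        raise ValueError(f"window length k={k} must satisfy 1 <= k < f={f}")
    m = f - k + 1
    windows = np.stack([x[j:j + k] for j in range(m)])
    complements = np.stack(
        [np.concatenate([x[:j], x[j + k:]]) for j in range(m)])
    return WindowPairs(windows, complements, k)


@dataclass
class NegInferConfig:
    window: int = 8          # k
    tau: float = 0.1
    hidden: int = 64
    out_dim: int = 32
    epochs: int = 100
    lr: float = 0.01
    weight_decay: float = 0.0


class ICLModel:
    """Dual two-layer feedforward encoders with unit-norm outputs."""

    def __init__(self, n_features: int, config: NegInferConfig, seed: int = 0):
        if config.tau <= 0:
            raise ValueError("temperature tau must be positive")
        self.config = config
        self.n_features = n_features
        k = config.window
        rng = np.random.default_rng(seed)

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return nn.parameter(rng.uniform(-lim, lim, size=shape))

        h, o = config.hidden, config.out_dim
        self.params = {
            "G1": glorot((k, h)), "G1b": nn.parameter(np.zeros(h)),
            "G2": glorot((h, o)), "G2b": nn.parameter(np.zeros(o)),
            "F1": glorot((n_features - k, h)), "F1b": nn.parameter(np.zeros(h)),
            "F2": glorot((h, o)), "F2b": nn.parameter(np.zeros(o)),
        }

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def _mlp(self, x: Tensor, prefix: str) -> Tensor:
        p = self.params
        hidden = nn.relu(nn.matmul(x, p[prefix + "1"]) + p[prefix + "1b"])
        return nn.l2_normalize_rows(
            nn.matmul(hidden, p[prefix + "2"]) + p[prefix + "2b"])

    def encode_windows(self, windows) -> Tensor:
        return self._mlp(nn.ensure_tensor(windows), "G")

    def encode_complements(self, complements) -> Tensor:
        return self._mlp(nn.ensure_tensor(complements), "F")

    # -- losses and scores ------------------------------------------------
    def window_losses(self, pairs: WindowPairs) -> Tensor:
        """Vector of l_j for one sample (length m), differentiable."""
        a = self.encode_windows(pairs.windows)         # (m, o)
        b = self.encode_complements(pairs.complements)  # (m, o)
        logits = nn.matmul(b, a.T) * (1.0 / self.config.tau)
        lsm = nn.log_softmax(logits, axis=1)
        eye = Tensor(np.eye(pairs.m))
        return -(lsm * eye).sum(axis=1)

    def anomaly_score(self, x: np.ndarray) -> float:
        """y(x) = sum_j l_j, evaluated without the tape."""
        pairs = build_windows(x, self.config.window)
        losses = self.window_losses(pairs)
        return float(losses.data.sum())


def icl_loss(model: ICLModel, pairs: WindowPairs, j: int) -> float:
    """The j-th window's contrastive loss for one sample."""
    return float(model.window_losses(pairs).data[j])


def train_icl(positive_features: np.ndarray,
              config: NegInferConfig | None = None,
              seed: int = 0) -> tuple[ICLModel, list[float]]:
    """Fit the one-class model on positive samples only."""
    config = config or NegInferConfig()
    X = np.atleast_2d(positive_features)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 positive samples")
    model = ICLModel(X.shape[1], config, seed=seed)
    opt = nn.AdamW(model.parameters(), lr=config.lr,
                   weight_decay=config.weight_decay)
    all_pairs = [build_windows(x, config.window) for x in X]
    m = all_pairs[0].m
    traj: list[float] = []
    for epoch in range(config.epochs):
        total = None
        for pairs in all_pairs:
            sample_loss = model.window_losses(pairs).mean()
            total = sample_loss if total is None else total + sample_loss
        total = total * (1.0 / len(all_pairs))
        value = total.item()
        if not np.isfinite(value):
            raise RuntimeError(f"ICL training diverged at epoch {epoch}")
        traj.append(value)
        opt.zero_grad()
        total.backward()
        opt.step()
    logger.info("ICL trained on %d positives (m=%d windows): loss %.4f -> %.4f",
                len(X), m, traj[0], traj[-1])
    return model, traj


@dataclass
class AnomalyScores:
    pool_indices: np.ndarray      # candidate gene indices (global)
    scores: np.ndarray            # y(x) per pool gene, aligned with pool
    negative_indices: np.ndarray  # selected high-confidence negatives

    @property
    def ranking(self) -> np.ndarray:
        """Pool indices sorted by descending score, index-ascending ties."""
        order = np.lexsort((self.pool_indices, -self.scores))
        return self.pool_indices[order]


def score_and_select(model: ICLModel, features: np.ndarray,
                     pool_indices: np.ndarray, n_select: int) -> AnomalyScores:
    """Score the candidate pool and select the top-n as negatives.

    Descending score order; ties broken by ascending gene index.  If the
    pool is smaller than ``n_select`` the whole pool is taken with a
    warning.
    """
    pool_indices = np.asarray(pool_indices, dtype=np.intp)
    scores = np.array([model.anomaly_score(features[i]) for i in pool_indices])
    if len(pool_indices) < n_select:
        logger.warning("candidate pool (%d) smaller than requested negatives "
                       "(%d); taking all", len(pool_indices), n_select)
        n_select = len(pool_indices)
    result = AnomalyScores(pool_indices, scores, np.empty(0, dtype=np.intp))
    result.negative_indices = result.ranking[:n_select]
    return result


def infer_negatives(features: np.ndarray, positive_idx: np.ndarray,
                    config: NegInferConfig | None = None, seed: int = 0,
                    n_select: int | None = None,
                    exclude: np.ndarray | None = None) -> AnomalyScores:
    """End-to-end negative inference.

    ``features`` is either the consensus embedding matrix Z or the raw
    feature matrix; ``positive_idx`` is the (augmented) positive set that
    both trains the model and sets the default negative count.  ``exclude``
    removes further indices (e.g. test genes) from the candidate pool.
    """
    config = config or NegInferConfig()
    positive_idx = np.asarray(positive_idx, dtype=np.intp)
    model, _ = train_icl(features[positive_idx], config, seed=seed)
    banned = set(positive_idx.tolist())
    if exclude is not None:
        banned.update(np.asarray(exclude, dtype=np.intp).tolist())
    pool = np.array([i for i in range(features.shape[0]) if i not in banned],
                    dtype=np.intp)
    if n_select is None:
        n_select = len(positive_idx)
    return score_and_select(model, features, pool, n_select)
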
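"""Multiplex contrastive pretraining with cross-graph consensus.

Each layer graph is encoded twice — once with the original feature matrix
(positive view) and once with a row-permuted corruption (negative view).  A
per-graph bilinear discriminator scores node embeddings against a mean-pooled
graph summary vector, and an infomax-style contrastive loss pushes positive
scores up and corrupted scores down.  A learnable consensus matrix Z is
simultaneously pulled toward the mean positive-view embedding and away from
the mean corrupted-view embedding.  The pretraining objective is

    J = sum_m L_contrast^(m) + beta * L_consensus

Z is the consensus node representation consumed by negative-sample
inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .conv import DirectionalEncoder, EncoderConfig
from .graph import MultiplexGraph, corrupt
from .nn import Tensor

logger = logging.getLogger(__name__)


def graph_readout(h_pos: Tensor, node_subset: np.ndarray | None = None) -> Tensor:
    """Graph-level summary: mean pooling of positive-view node embeddings.

    By default the mean runs over all nodes of the positive view (the
    infomax convention); ``node_subset`` restricts pooling to a set of node
    indices (e.g. labeled positives only).
    """
    if h_pos.shape[0] == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    if node_subset is not None:
        h_pos = nn.take_rows(h_pos, np.asarray(node_subset))
    return h_pos.mean(axis=0)


def contrastive_loss(h_pos: Tensor, h_neg: Tensor, discriminator: Tensor,
                     g: Tensor, *, literal_second_term: bool = True) -> Tensor:
    """Per-graph bilinear contrastive loss.

    L = -(1/n) sum_v log sigma(h_pos M g) - (1/n) sum_v log sigma(1 - h_neg M g)

    The second term penalizes corrupted-view scores near 1 via
    log sigma(1 - score); ``literal_second_term=False`` switches to the
    conventional log(1 - sigma(score)) = log sigma(-score).
    """
    mg = nn.matmul(discriminator, g.reshape(-1, 1))  # (hidden, 1)
    s_pos = nn.matmul(h_pos, mg)
    s_neg = nn.matmul(h_neg, mg)
    term_pos = nn.logsigmoid(s_pos).mean()
    if literal_second_term:
        term_neg = nn.logsigmoid(1.0 - s_neg).mean()
    else:
        term_neg = nn.logsigmoid(-s_neg).mean()
    return -term_pos - term_neg


def consensus_loss(Z: Tensor, h_pos_views: list[Tensor],
                   h_neg_views: list[Tensor]) -> Tensor:
    """Squared-Frobenius pull toward the mean positive view and push from
    the mean corrupted view; may be negative."""
    M = len(h_pos_views)
    mean_pos = h_pos_views[0] * (1.0 / M)
    mean_neg = h_neg_views[0] * (1.0 / M)
    for hp, hn in zip(h_pos_views[1:], h_neg_views[1:]):
        mean_pos = mean_pos + hp * (1.0 / M)
        mean_neg = mean_neg + hn * (1.0 / M)
    dp = Z - mean_pos
    dn = Z - mean_neg
    return (dp * dp).sum() - (dn * dn).sum()


@dataclass
class PretrainConfig:
    hidden: int = 256
    n_layers: int = 3
    alpha: float = 0.5
    dropout: float = 0.5
    beta: float = 0.001
    lr: float = 0.01
    weight_decay: float = 0.0
    epochs: int = 200
    patience: int = 20          # early abort on loss plateau
    min_delta: float = 1e-4
    literal_second_term: bool = True
    readout_positives_only: bool = False
    max_degree: int = 512


@dataclass
class PretrainResult:
    Z: np.ndarray
    encoder: DirectionalEncoder
    loss_trajectory: list[float] = field(default_factory=list)


def pretrain(graph: MultiplexGraph, config: PretrainConfig, seed: int = 0,
             positives: np.ndarray | None = None) -> PretrainResult:
    """Optimize the pretraining objective; returns consensus Z and encoder.

    One corrupted view is resampled per epoch.  Each layer graph is encoded
    separately (single-graph multiplex) with a shared encoder, per Eq.-style
    per-graph embeddings.
    """
    n, M = graph.n, graph.n_layers
    enc_cfg = EncoderConfig(n_features=graph.n_features, hidden=config.hidden,
                            n_layers=config.n_layers, alpha=config.alpha,
                            dropout=config.dropout, max_degree=config.max_degree)
    rng = np.random.default_rng(seed)
    encoder = DirectionalEncoder(enc_cfg, n_graphs=M,
                                 seed=int(rng.integers(2**31)))
    discriminators = [
        nn.parameter(rng.normal(0, 0.1, (config.hidden, config.hidden)))
        for _ in range(M)]
    Z = nn.parameter(rng.normal(0, 0.1, (n, config.hidden)))
    params = encoder.parameters() + discriminators + [Z]
    opt = nn.AdamW(params, lr=config.lr, weight_decay=config.weight_decay)

    per_graph_ops = [[op] for op in graph.operators()]
    subset = np.asarray(positives) if config.readout_positives_only else None

    traj: list[float] = []
    best, stall = np.inf, 0
    for epoch in range(config.epochs):
        view = corrupt(graph.X, seed=int(rng.integers(2**31)))
        drop_rng = np.random.default_rng(int(rng.integers(2**31)))
        h_pos_views, h_neg_views = [], []
        total = None
        for m in range(M):
            h_pos, _ = encoder.encode(operators=per_graph_ops[m], X=graph.X,
                                      training=True, rng=drop_rng)
            h_neg, _ = encoder.encode(operators=per_graph_ops[m],
                                      X=view.X_tilde, training=True,
                                      rng=drop_rng)
            g = graph_readout(h_pos, subset)
            loss_m = contrastive_loss(
                h_pos, h_neg, discriminators[m], g,
                literal_second_term=config.literal_second_term)
            total = loss_m if total is None else total + loss_m
            h_pos_views.append(h_pos)
            h_neg_views.append(h_neg)
        if config.beta:
            total = total + config.beta * consensus_loss(Z, h_pos_views,
                                                         h_neg_views)
        value = total.item()
        if not np.isfinite(value):
            raise RuntimeError(f"pretraining diverged at epoch {epoch}: "
                               f"loss={value}")
        traj.append(value)
        opt.zero_grad()
        total.backward()
        opt.step()
        if value < best - config.min_delta:
            best, stall = value, 0
        else:
            stall += 1
            if stall >= config.patience:
                logger.info("pretraining plateaued at epoch %d", epoch)
                break
    return PretrainResult(Z.data.copy(), encoder, traj)
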
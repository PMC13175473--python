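"""Directional multiplex graph convolution.

Each layer aggregates messages along out-edges and in-edges separately and
weighs the two directions per node with a learnable gate.  The gate fuses
two signals:

* neighbor diversity — a per-node directional Dirichlet energy measuring how
  much a node's representation disagrees with its in- or out-neighborhood
  (high energy: the neighborhood likely belongs to another class);
* degree diversity — trainable embeddings indexed by the node's raw in- and
  out-degree.

For direction ``dir`` at layer ``l`` the gate logit is

    q_dir = (-e_dir + Deg_dir) w_dir + b_dir

and the two directions are normalized by a temperature softmax, so the
forward and backward gates are exactly complementary.  The layer update
averages the gated directional messages over all M graphs and keeps an
``alpha``-weighted residual of the previous representation:

    H' = alpha * H + (1/M) * sum_m (G_fwd S_fwd H W_fwd + G_bwd S_bwd H W_bwd)

Node features are lifted once by a learnable input projection so the
residual is well-defined at every layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .graph import MultiplexGraph, NormalizedOperators
from .nn import Tensor


def dirichlet_energy(H: Tensor, S) -> Tensor:
    """Per-node directional Dirichlet energy, one value per feature channel.

    e = (I+S)(H o H) - 2((I+S)H o H - H o H), evaluated with sparse matvecs;
    algebraically e_i = sum_j s_ij (h_i - h_j)^2 + (1 - sum_j s_ij) h_i^2.
    """
    H2 = H * H
    return H2 + nn.spmm(S, H2) - 2.0 * (nn.spmm(S, H) * H)


def directional_gate(e_fwd: Tensor, e_bwd: Tensor,
                     deg_emb_fwd: Tensor, deg_emb_bwd: Tensor,
                     w_fwd: Tensor, b_fwd: Tensor,
                     w_bwd: Tensor, b_bwd: Tensor,
                     log_tau: Tensor) -> tuple[Tensor, Tensor]:
    """Complementary per-node direction weights (each shape (n, 1)).

    The two-way temperature softmax is computed as
    sigmoid((q_fwd - q_bwd)/tau), which is exactly the softmax over
    {q_fwd, q_bwd} and makes gate_bwd = 1 - gate_fwd hold identically.
    """
    q_fwd = nn.matmul(-e_fwd + deg_emb_fwd, w_fwd) + b_fwd
    q_bwd = nn.matmul(-e_bwd + deg_emb_bwd, w_bwd) + b_bwd
    tau = nn.exp(log_tau)
    gate_fwd = nn.sigmoid((q_fwd - q_bwd) / tau)
    return gate_fwd, 1.0 - gate_fwd


@dataclass
class EncoderConfig:
    n_features: int
    hidden: int = 256
    n_layers: int = 3
    alpha: float = 0.5
    dropout: float = 0.5
    max_degree: int = 512
    use_relu: bool = False  # the gating is the nonlinearity; ReLU optional


class DirectionalEncoder:
    """L stacked directional multiplex convolution layers.

    Gate projections (w, b, tau) are shared across graphs within a layer;
    degree-embedding tables are per layer, per graph, per direction.
    """

    VERSION = 1

    def __init__(self, config: EncoderConfig, n_graphs: int, seed: int = 0):
        self.config = config
        self.n_graphs = n_graphs
        rng = np.random.default_rng(seed)
        h = config.hidden
        self.params: dict[str, Tensor] = {}

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[-1]))
            return nn.parameter(rng.uniform(-lim, lim, size=shape))

        self.params["w_in"] = glorot((config.n_features, h))
        for l in range(config.n_layers):
            for d in ("fwd", "bwd"):
                self.params[f"W_{d}_{l}"] = glorot((h, h))
                self.params[f"wgate_{d}_{l}"] = glorot((h, 1))
                self.params[f"bgate_{d}_{l}"] = nn.parameter(np.zeros(1))
                for m in range(n_graphs):
                    self.params[f"deg_{d}_{l}_{m}"] = nn.parameter(
                        rng.normal(0.0, 0.1, size=(config.max_degree + 1, h)))
            self.params[f"log_tau_{l}"] = nn.parameter(np.zeros(1))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward --------------------------------------------------------
    def _deg_embedding(self, layer: int, graph: int, direction: str,
                       degrees: np.ndarray) -> Tensor:
        idx = np.clip(degrees, 0, self.config.max_degree)
        return nn.take_rows(self.params[f"deg_{direction}_{layer}_{graph}"], idx)

    def layer_forward(self, H: Tensor, operators: list[NormalizedOperators],
                      layer: int, collect_gates: list | None = None) -> Tensor:
        p = self.params
        M = len(operators)
        acc = None
        for m, ops in enumerate(operators):
            e_fwd = dirichlet_energy(H, ops.s_fwd)
            e_bwd = dirichlet_energy(H, ops.s_bwd)
            g_fwd, g_bwd = directional_gate(
                e_fwd, e_bwd,
                self._deg_embedding(layer, m, "fwd", ops.deg_out),
                self._deg_embedding(layer, m, "bwd", ops.deg_in),
                p[f"wgate_fwd_{layer}"], p[f"bgate_fwd_{layer}"],
                p[f"wgate_bwd_{layer}"], p[f"bgate_bwd_{layer}"],
                p[f"log_tau_{layer}"])
            if collect_gates is not None:
                collect_gates.append((layer, m, g_fwd))
            msg = (g_fwd * nn.spmm(ops.s_fwd, nn.matmul(H, p[f"W_fwd_{layer}"]))
                   + g_bwd * nn.spmm(ops.s_bwd, nn.matmul(H, p[f"W_bwd_{layer}"])))
            acc = msg if acc is None else acc + msg
        out = self.config.alpha * H + acc * (1.0 / M)
        if self.config.use_relu:
            out = nn.relu(out)
        return out

    def encode(self, graph: MultiplexGraph | None = None, *,
               operators: list[NormalizedOperators] | None = None,
               X: np.ndarray | None = None,
               training: bool = False,
               rng: np.random.Generator | None = None,
               collect_gates: bool = False,
               symmetrize: bool = False):
        """Run all layers; returns (H_final, gate_list).

        gate_list holds (layer, graph, gate_fwd Tensor) triples when
        ``collect_gates`` is set (the consistency regularizer needs them
        inside the autodiff graph).  ``symmetrize`` encodes the
        directionality-ablated graph instead.
        """
        if operators is None:
            g = graph.symmetrized() if symmetrize else graph
            operators = g.operators()
        if X is None:
            X = graph.X
        if training and rng is None:
            rng = np.random.default_rng(0)
        gates: list = [] if collect_gates else None
        H = nn.matmul(Tensor(X), self.params["w_in"])
        for l in range(self.config.n_layers):
            if training and l > 0 and self.config.dropout > 0:
                H = nn.dropout(H, self.config.dropout, rng)
            H = self.layer_forward(H, operators, l, collect_gates=gates)
        return H, (gates or [])

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data[...] = state[k]

    def save(self, path: str) -> None:
        np.savez_compressed(
            path, __version__=np.array(self.VERSION),
            __n_graphs__=np.array(self.n_graphs), **self.state_dict())

    @classmethod
    def load(cls, path: str, config: EncoderConfig) -> "DirectionalEncoder":
        with np.load(path) as z:
            enc = cls(config, int(z["__n_graphs__"]), seed=0)
            enc.load_state_dict({k: z[k] for k in enc.params})
        return enc
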
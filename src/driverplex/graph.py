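"""Multiplex graph container, directed normalization, and corrupted views.

A multiplex graph is a set of M binary adjacency layers over one shared gene
universe, plus one dense gene x feature matrix.  Directed layers are
normalized with the symmetric directed scheme

    S_fwd = D_out^{-1/2} A D_in^{-1/2}

which propagates messages along out-edges, and its in-direction mirror

    S_bwd = D_in^{-1/2} A^T D_out^{-1/2}

which propagates along reversed arcs.  For symmetric A both collapse to the
classical D^{-1/2} A D^{-1/2}.  Zero degrees contribute a factor of 0 (an
isolated node neither sends nor receives messages), so the operators are
always finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .universe import GeneUniverse


@dataclass
class NormalizedOperators:
    """Per-layer normalized propagation operators and degree vectors."""

    s_fwd: sp.csr_matrix
    s_bwd: sp.csr_matrix
    deg_out: np.ndarray
    deg_in: np.ndarray


@dataclass
class MultiplexGraph:
    """Shared gene universe, M adjacency layers, and node features."""

    universe: GeneUniverse
    layers: list[sp.csr_matrix]
    directed: list[bool]
    X: np.ndarray
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.universe)
        if self.X.shape[0] != n:
            raise ValueError("feature matrix row count != universe size")
        if len(self.layers) != len(self.directed):
            raise ValueError("one directed flag per layer required")
        if not self.layer_names:
            self.layer_names = [f"layer{m}" for m in range(len(self.layers))]
        for m, a in enumerate(self.layers):
            if a.shape != (n, n):
                raise ValueError(f"layer {m} shape {a.shape} != ({n},{n})")
        self.validate()

    # -- properties -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.universe)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def validate(self) -> None:
        for m, (a, is_dir) in enumerate(zip(self.layers, self.directed)):
            _check_adjacency(a, m)
            if not is_dir and (a != a.T).nnz != 0:
                raise ValueError(f"undirected layer {m} is not symmetric")

    # -- operators ------------------------------------------------------
    def operators(self) -> list[NormalizedOperators]:
        return [normalize_directed(a) for a in self.layers]

    def symmetrized(self) -> "MultiplexGraph":
        """Directionality ablation: every layer becomes undirected."""
        layers = []
        for a in self.layers:
            s = a.maximum(a.T).tocsr()
            s.data[:] = 1.0
            layers.append(s)
        return MultiplexGraph(self.universe, layers,
                              [False] * self.n_layers, self.X.copy(),
                              list(self.layer_names))

    def union_layer(self) -> sp.csr_matrix:
        """Symmetrized union of all layers (single undirected graph)."""
        acc = self.layers[0].copy()
        for a in self.layers[1:]:
            acc = acc.maximum(a)
        acc = acc.maximum(acc.T).tocsr()
        acc.data[:] = 1.0
        return acc


def _check_adjacency(a: sp.spmatrix, m: int = 0) -> None:
    if a.diagonal().sum() != 0:
        raise ValueError(f"layer {m}: adjacency has nonzero diagonal")
    if a.nnz and not np.all(a.data == 1.0):
        raise ValueError(f"layer {m}: adjacency entries must be binary")


def normalize_directed(a: sp.spmatrix) -> NormalizedOperators:
    """Symmetric directed normalization with the zero-degree convention.

    Returns S_fwd = D_out^{-1/2} A D_in^{-1/2}, S_bwd = D_in^{-1/2} A^T
    D_out^{-1/2}, and the raw integer out-/in-degree vectors.
    """
    a = sp.csr_matrix(a, dtype=np.float64)
    _check_adjacency(a)
    deg_out = np.asarray(a.sum(axis=1)).ravel()
    deg_in = np.asarray(a.sum(axis=0)).ravel()
    with np.errstate(divide="ignore"):
        io = np.where(deg_out > 0, deg_out ** -0.5, 0.0)
        ii = np.where(deg_in > 0, deg_in ** -0.5, 0.0)
    d_out = sp.diags(io)
    d_in = sp.diags(ii)
    s_fwd = (d_out @ a @ d_in).tocsr()
    s_bwd = (d_in @ a.T @ d_out).tocsr()
    return NormalizedOperators(s_fwd, s_bwd,
                               deg_out.astype(np.int64), deg_in.astype(np.int64))


@dataclass
class CorruptedView:
    """Row-permuted feature matrix: the negative view for pretraining."""

    permutation: np.ndarray
    X_tilde: np.ndarray
    seed: int


def corrupt(X: np.ndarray, seed: int) -> CorruptedView:
    """Permute feature rows uniformly at random (seeded, reproducible)."""
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to corrupt")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return CorruptedView(perm, X[perm], seed)


# -- serialization ------------------------------------------------------

def save_graph(graph: MultiplexGraph, path: str) -> None:
    """Archive a prepared multiplex graph to a single .npz file."""
    payload = {
        "symbols": np.array(graph.universe.symbols, dtype=object),
        "X": graph.X,
        "directed": np.array(graph.directed, dtype=bool),
        "layer_names": np.array(graph.layer_names, dtype=object),
        "n_layers": np.array(graph.n_layers),
    }
    for m, a in enumerate(graph.layers):
        coo = a.tocoo()
        payload[f"layer{m}_row"] = coo.row
        payload[f"layer{m}_col"] = coo.col
    np.savez_compressed(path, **payload, allow_pickle=True)


def load_graph(path: str) -> MultiplexGraph:
    with np.load(path, allow_pickle=True) as z:
        symbols = [str(s) for s in z["symbols"]]
        universe = GeneUniverse(symbols)
        n = len(universe)
        layers = []
        for m in range(int(z["n_layers"])):
            row, col = z[f"layer{m}_row"], z[f"layer{m}_col"]
            a = sp.csr_matrix((np.ones(len(row)), (row, col)), shape=(n, n))
            layers.append(a)
        return MultiplexGraph(universe, layers,
                              [bool(d) for d in z["directed"]], z["X"],
                              [str(s) for s in z["layer_names"]])
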
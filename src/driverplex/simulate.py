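"""Synthetic multiplex graphs with planted driver structure.

The generator emulates the shapes of the real task — M layer graphs (a mix
of directed and undirected) over one gene universe, a dense z-scored
feature matrix, a small positive class — with three planted, tunable
signals:

* homophily ``h``: pair probabilities interpolate between the exactly
  class-blind uniform graph at h = 0.5 and a degree-balanced fully
  homophilous graph at h = 1 (within-class probability scaled per class so
  the expected total degree is d = density*(n-1) for every node at every
  h).  Degree therefore never carries class signal; neighborhood
  *composition* does, increasingly with h;
* direction asymmetry ``delta``: in directed layers, arcs emitted by
  drivers are upweighted by (1 + delta) and arcs received by drivers
  downweighted by (1 - delta) — drivers act as regulatory sources, with
  high out-degree and low in-degree.  The symmetrized degree of a driver
  stays class-neutral (the up- and down-weighting cancel to first order),
  so the class signal rides on edge *orientation* and is destroyed by
  treating the layers as undirected;
* feature effect size: the two class-conditional Gaussian feature means
  differ by ``effect_size`` standard deviations along a fixed random
  direction.

A fraction of the true positives is hidden (relabeled unlabeled) so that
pseudo-label augmentation and negative inference can be scored against
ground truth.  Everything is reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp

from .graph import MultiplexGraph
from .io import zscore_columns
from .universe import GeneUniverse


@dataclass
class SynthConfig:
    n: int = 300
    n_layers: int = 6
    n_directed: int = 3          # first n_directed layers are directed
    n_positives: int = 40
    n_features: int = 48
    homophily: float = 0.8       # h
    delta: float = 0.5           # direction asymmetry of cross-class arcs
    density: float = 0.02        # expected edge probability per layer
    effect_size: float = 1.5     # class-mean separation in sigma units
    hidden_fraction: float = 0.2  # true positives relabeled unlabeled
    label_noise: float = 0.0     # visible positives flipped to unlabeled
    seed: int = 0

    def __post_init__(self):
        for name in ("homophily", "delta", "hidden_fraction", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 < self.n_positives < self.n:
            raise ValueError("need 0 < n_positives < n")
        if not 0 < self.density < 0.5:
            raise ValueError("density must be in (0, 0.5) for the planted "
                             "probabilities to stay valid")
        if self.n_directed > self.n_layers:
            raise ValueError("n_directed exceeds n_layers")


@dataclass
class SynthData:
    graph: MultiplexGraph
    true_labels: np.ndarray       # 1 = driver, for every gene
    visible_positives: np.ndarray  # labeled positive indices
    hidden_positives: np.ndarray   # true positives relabeled unlabeled
    config: SynthConfig


def _edge_probability(cfg: SynthConfig, yi: np.ndarray, yj: np.ndarray,
                      directed: bool) -> np.ndarray:
    """Arc probability matrix for ordered pairs (i -> j).

    For h >= 0.5, pair probabilities are the t-blend (t = 2h - 1) of the
    uniform class-blind graph p_all = d/(n-1) and the fully homophilous
    graph d/(n_c - 1): every node has expected total degree d at every h,
    so degree is class-neutral by construction.  For the (unused by any
    preset) heterophilous regime h < 0.5 the simple planted-partition
    probabilities 2hp / 2(1-h)p are used instead; there the minority class
    acquires higher degree, which is documented rather than corrected.
    """
    n = len(yi)
    d = cfg.density * (n - 1)
    n1 = int((yi == 1).sum())
    n0 = n - n1
    h = cfg.homophily
    same = yi[:, None] == yj[None, :]
    if h >= 0.5:
        t = 2.0 * h - 1.0
        p_all = d / (n - 1)
        p_within = {c: (1 - t) * p_all + t * d / max(nc - 1, 1)
                    for c, nc in ((0, n0), (1, n1))}
        p_cross = (1 - t) * p_all
        p = np.where(same,
                     np.where(yi[:, None] == 1, p_within[1], p_within[0]),
                     p_cross)
    else:
        p = np.where(same, 2.0 * h * cfg.density,
                     2.0 * (1.0 - h) * cfg.density)
    if directed and cfg.delta > 0:
        p = p * np.where(yi[:, None] == 1, 1.0 + cfg.delta, 1.0)
        p = p * np.where(yj[None, :] == 1, 1.0 - cfg.delta, 1.0)
    return np.clip(p, 0.0, 1.0)


def generate(config: SynthConfig) -> SynthData:
    """Sample one synthetic multiplex dataset."""
    rng = np.random.default_rng(config.seed)
    n = config.n
    y = np.zeros(n, dtype=int)
    pos = rng.choice(n, size=config.n_positives, replace=False)
    y[pos] = 1

    layers, flags = [], []
    for m in range(config.n_layers):
        directed = m < config.n_directed
        p = _edge_probability(config, y, y, directed)
        if directed:
            a = (rng.random((n, n)) < p).astype(float)
        else:
            upper = np.triu(rng.random((n, n)) < p, k=1)
            a = (upper | upper.T).astype(float)
        np.fill_diagonal(a, 0.0)
        layers.append(sp.csr_matrix(a))
        flags.append(directed)

    direction = rng.normal(size=config.n_features)
    direction /= np.linalg.norm(direction)
    X = rng.normal(size=(n, config.n_features))
    X[y == 1] += config.effect_size * direction
    X = zscore_columns(X)

    universe = GeneUniverse([f"G{i:05d}" for i in range(n)])
    names = [("dir" if f else "undir") + f"_layer{m}"
             for m, f in enumerate(flags)]
    graph = MultiplexGraph(universe, layers, flags, X, names)

    pos_sorted = np.sort(pos)
    n_hidden = int(round(config.hidden_fraction * len(pos_sorted)))
    hidden = np.sort(rng.choice(pos_sorted, size=n_hidden, replace=False))
    visible = np.setdiff1d(pos_sorted, hidden)
    if config.label_noise > 0:
        n_drop = int(round(config.label_noise * len(visible)))
        if n_drop:
            dropped = rng.choice(visible, size=n_drop, replace=False)
            visible = np.setdiff1d(visible, dropped)
    return SynthData(graph, y, visible, hidden, config)


# -- presets --------------------------------------------------------------

PRESETS: dict[str, dict] = {
    # strong planted structure: homophilous layers, separated features
    "easy": dict(homophily=0.9, effect_size=2.0, delta=0.5),
    "medium": dict(homophily=0.7, effect_size=1.0, delta=0.3),
    # no signal at all: the null control
    "hard": dict(homophily=0.5, effect_size=0.0, delta=0.0),
}


def preset(name: str, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    return SynthConfig(**{**PRESETS[name], **overrides})


def difficulty_sweep(base: SynthConfig,
                     grid: dict[str, list] | None = None) -> list[SynthData]:
    """Deterministic collection of datasets over a parameter grid.

    ``grid`` maps SynthConfig field names to value lists; the sweep takes
    the Cartesian product in field order.  Defaults to the three presets.
    """
    if grid is None:
        return [generate(replace(base, **PRESETS[k])) for k in PRESETS]
    import itertools

    keys = list(grid)
    out = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        out.append(generate(replace(base, **dict(zip(keys, combo)))))
    return out


# -- file export ----------------------------------------------------------

def write_dataset(data: SynthData, outdir) -> None:
    """Write edge lists, manifest, feature table and gene lists in the
    formats the I/O module consumes."""
    import pandas as pd
    import yaml
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    symbols = data.graph.universe.symbols
    for name, adj, directed in zip(data.graph.layer_names, data.graph.layers,
                                   data.graph.directed):
        path = outdir / f"{name}.tsv"
        coo = adj.tocoo()
        with open(path, "w") as fh:
            written = set()
            for i, j in zip(coo.row, coo.col):
                key = (min(i, j), max(i, j)) if not directed else (i, j)
                if key in written:
                    continue
                written.add(key)
                fh.write(f"{symbols[key[0]]}\t{symbols[key[1]]}\n")
        manifest.append({"path": path.name, "directed": bool(directed),
                         "name": name})
    with open(outdir / "networks.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    feat = pd.DataFrame(data.graph.X, index=symbols,
                        columns=[f"f{i}" for i in range(data.graph.n_features)])
    feat.index.name = "gene"
    feat.to_csv(outdir / "features.tsv", sep="\t")
    for fname, idx in (("positives.txt", data.visible_positives),
                       ("hidden_positives.txt", data.hidden_positives),
                       ("true_drivers.txt", np.flatnonzero(data.true_labels))):
        with open(outdir / fname, "w") as fh:
            for i in idx:
                fh.write(symbols[i] + "\n")
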
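"""Positive pseudo-label augmentation.

Unlabeled genes are promoted to pseudo-positives when three filters agree:

1. a Chebyshev + GCN class-probability model assigns them to the positive
   class with low prediction entropy (only the ``retain_count``
   lowest-entropy candidates survive);
2. the positive-class probability reaches the confidence threshold
   ``theta_p``;
3. their distance in standardized feature space to the nearest of two
   RBF-spectral-clustering centroids of the labeled positives is at most
   mean + std of the positives' own centroid distances.

Because only positive labels exist at this stage, the probability model is
trained on the labeled positives against an equal-sized random sample of
unlabeled genes used as provisional negatives (standard positive-unlabeled
practice); the sample is seeded for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from sklearn.cluster import SpectralClustering

from . import nn
from .graph import MultiplexGraph, normalize_directed
from .nn import Tensor

logger = logging.getLogger(__name__)

POSITIVE_CLASS = 1


@dataclass
class AugmentConfig:
    cheb_order: int = 2          # K
    hidden: int = 64
    theta_p: float = 0.8
    retain_factor: float = 2.0   # retain_count = retain_factor * |S+|
    sigma: float | None = None   # None -> median pairwise-distance heuristic
    epochs: int = 200
    lr: float = 0.01
    weight_decay: float = 0.0
    probability_layer: int | None = None  # None -> symmetrized union of layers


@dataclass
class PseudoLabel:
    index: int
    probability: float
    entropy: float
    distance: float


@dataclass
class PseudoLabelSet:
    members: list[PseudoLabel] = field(default_factory=list)

    @property
    def indices(self) -> np.ndarray:
        return np.array([m.index for m in self.members], dtype=np.intp)

    def __len__(self) -> int:
        return len(self.members)


# -- probability model (Chebyshev + GCN) ---------------------------------

def scaled_laplacian(a: sp.spmatrix) -> sp.csr_matrix:
    """L_hat = 2 L / lambda_max - I with L the symmetric normalized
    Laplacian; spectrum scaled into [-1, 1]."""
    ops = normalize_directed(a.maximum(a.T).tocsr())
    n = a.shape[0]
    lap = sp.eye(n) - ops.s_fwd
    if n > 2:
        try:
            lmax = float(spla.eigsh(lap, k=1, which="LA",
                                    return_eigenvectors=False,
                                    tol=1e-6, maxiter=2000)[0])
        except (spla.ArpackNoConvergence, RuntimeError):
            lmax = 2.0
    else:
        lmax = float(np.linalg.eigvalsh(lap.toarray()).max())
    lmax = max(lmax, 1e-9)
    return (2.0 / lmax) * lap - sp.eye(n)


def chebyshev_basis(l_hat: sp.spmatrix, X: np.ndarray,
                    order: int) -> list[np.ndarray]:
    """[T_0 X, ..., T_K X] via the recurrence T_k = 2 L_hat T_{k-1} - T_{k-2}."""
    if order < 0:
        raise ValueError("Chebyshev order must be >= 0")
    out = [X]
    if order >= 1:
        out.append(l_hat @ X)
    for _ in range(2, order + 1):
        out.append(2.0 * (l_hat @ out[-1]) - out[-2])
    return out


class ProbModel:
    """Chebyshev convolution followed by a GCN layer and softmax."""

    def __init__(self, graph_adj: sp.spmatrix, X: np.ndarray,
                 config: AugmentConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        f, h = X.shape[1], config.hidden
        self.config = config
        a = graph_adj.maximum(graph_adj.T).tocsr()
        a.data[:] = 1.0
        self.a_norm = normalize_directed(a).s_fwd
        self.tx = chebyshev_basis(scaled_laplacian(a), X, config.cheb_order)

        def glorot(shape):
            lim = np.sqrt(6.0 / (shape[0] + shape[1]))
            return nn.parameter(rng.uniform(-lim, lim, size=shape))

        self.thetas = [glorot((f, h)) for _ in range(config.cheb_order + 1)]
        self.w_out = glorot((h, 2))

    def parameters(self) -> list[Tensor]:
        return self.thetas + [self.w_out]

    def logits(self) -> Tensor:
        z = nn.matmul(Tensor(self.tx[0]), self.thetas[0])
        for txk, theta in zip(self.tx[1:], self.thetas[1:]):
            z = z + nn.matmul(Tensor(txk), theta)
        return nn.matmul(nn.spmm(self.a_norm, z), self.w_out)

    def fit(self, labeled_idx: np.ndarray, labels: np.ndarray) -> list[float]:
        opt = nn.AdamW(self.parameters(), lr=self.config.lr,
                       weight_decay=self.config.weight_decay)
        traj = []
        for _ in range(self.config.epochs):
            logp = nn.log_softmax(self.logits(), axis=1)
            picked = nn.take_rows(logp, labeled_idx)
            onehot = np.zeros((len(labels), 2))
            onehot[np.arange(len(labels)), labels] = 1.0
            loss = -(picked * Tensor(onehot)).sum() * (1.0 / len(labels))
            traj.append(loss.item())
            opt.zero_grad()
            loss.backward()
            opt.step()
        return traj

    def predict_proba(self) -> np.ndarray:
        p = nn.softmax(self.logits(), axis=1).data
        return p


def class_probabilities(graph: MultiplexGraph, positives: np.ndarray,
                        config: AugmentConfig, seed: int = 0) -> np.ndarray:
    """Train the probability model and return the n x 2 row-stochastic P.

    Provisional negatives are an equal-sized seeded random draw from the
    unlabeled pool.
    """
    rng = np.random.default_rng(seed)
    adj = (graph.layers[config.probability_layer]
           if config.probability_layer is not None else graph.union_layer())
    model = ProbModel(adj, graph.X, config, seed=int(rng.integers(2**31)))
    positives = np.asarray(positives, dtype=np.intp)
    unlabeled = np.setdiff1d(np.arange(graph.n), positives)
    prov_neg = rng.choice(unlabeled, size=min(len(positives), len(unlabeled)),
                          replace=False)
    idx = np.concatenate([positives, prov_neg])
    labels = np.concatenate([np.ones(len(positives), dtype=int),
                             np.zeros(len(prov_neg), dtype=int)])
    model.fit(idx, labels)
    return model.predict_proba()


# -- entropy filtering ----------------------------------------------------

def prediction_entropy(P: np.ndarray) -> np.ndarray:
    """Shannon entropy per row, natural log; 0 log 0 := 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=1)


def entropy_rank(P: np.ndarray, unlabeled: np.ndarray,
                 retain_count: int) -> list[tuple[int, float]]:
    """Unlabeled nodes provisionally assigned to the positive class, sorted
    by ascending entropy and truncated to ``retain_count``.

    Returns (node index, entropy) pairs.
    """
    unlabeled = np.asarray(unlabeled, dtype=np.intp)
    H = prediction_entropy(P)
    yhat = P.argmax(axis=1)
    cand = unlabeled[yhat[unlabeled] == POSITIVE_CLASS]
    order = np.lexsort((cand, H[cand]))  # entropy asc, index tie-break
    cand = cand[order][:max(retain_count, 0)]
    return [(int(i), float(H[i])) for i in cand]


# -- RBF spectral clustering constraint ----------------------------------

@dataclass
class PositiveClusters:
    centroids: np.ndarray          # (2, f) in standardized space
    assignments: np.ndarray        # cluster id per positive
    positive_distances: np.ndarray  # d_j per positive
    mean_: np.ndarray              # standardization fitted on S+
    std_: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean_) / self.std_

    def distance(self, x: np.ndarray) -> np.ndarray:
        """min-centroid Euclidean distance for raw feature rows."""
        phi = self.transform(np.atleast_2d(x))
        d = np.linalg.norm(phi[:, None, :] - self.centroids[None], axis=2)
        return d.min(axis=1)


def rbf_kernel_matrix(phi: np.ndarray, sigma: float) -> np.ndarray:
    sq = ((phi[:, None, :] - phi[None]) ** 2).sum(axis=2)
    return np.exp(-sq / (2.0 * sigma ** 2))


def median_sigma(phi: np.ndarray) -> float:
    d = np.sqrt(((phi[:, None, :] - phi[None]) ** 2).sum(axis=2))
    tri = d[np.triu_indices(len(phi), k=1)]
    med = float(np.median(tri)) if len(tri) else 0.0
    return med if med > 0 else 1.0


def rbf_cluster_positives(features: np.ndarray, sigma: float | None = None,
                          seed: int = 0) -> PositiveClusters:
    """Two-way spectral clustering of labeled positives under an RBF kernel.

    ``features`` are the raw feature rows of S+; standardization (per-column
    z-score, population std) is fit here and reused for candidates.
    """
    features = np.atleast_2d(features)
    if len(features) < 2:
        raise ValueError("need at least 2 labeled positives to cluster")
    mean_ = features.mean(axis=0)
    std_ = features.std(axis=0)
    std_ = np.where(std_ > 0, std_, 1.0)
    phi = (features - mean_) / std_
    if sigma is None:
        sigma = median_sigma(phi)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    affinity = rbf_kernel_matrix(phi, sigma)
    if np.allclose(affinity, affinity[0, 0]):
        raise ValueError("degenerate RBF affinity: all feature rows identical")
    sc = SpectralClustering(n_clusters=2, affinity="precomputed",
                            random_state=seed, assign_labels="kmeans")
    labels = sc.fit_predict(affinity)
    centroids = np.stack([phi[labels == k].mean(axis=0) for k in (0, 1)])
    d = np.linalg.norm(phi[:, None, :] - centroids[None], axis=2).min(axis=1)
    return PositiveClusters(centroids, labels, d, mean_, std_)


# -- final selection rule -------------------------------------------------

def select_pseudo_positives(candidates: list[tuple[int, float]],
                            P: np.ndarray,
                            clusters: PositiveClusters,
                            X: np.ndarray,
                            theta_p: float) -> PseudoLabelSet:
    """Keep candidates with p_{i,+} >= theta_p (inclusive) and centroid
    distance <= mean + std (population) of the positives' own distances
    (inclusive)."""
    cutoff = (clusters.positive_distances.mean()
              + clusters.positive_distances.std())
    out = PseudoLabelSet()
    if not candidates:
        return out
    idx = np.array([c[0] for c in candidates], dtype=np.intp)
    dists = clusters.distance(X[idx])
    for (i, h), d in zip(candidates, dists):
        p = float(P[i, POSITIVE_CLASS])
        if p >= theta_p and d <= cutoff:
            out.members.append(PseudoLabel(i, p, h, float(d)))
    return out


def augment_positives(graph: MultiplexGraph, positives: np.ndarray,
                      config: AugmentConfig | None = None,
                      seed: int = 0) -> PseudoLabelSet:
    """Full augmentation pass: probabilities -> entropy rank -> RBF filter."""
    config = config or AugmentConfig()
    positives = np.asarray(positives, dtype=np.intp)
    P = class_probabilities(graph, positives, config, seed=seed)
    unlabeled = np.setdiff1d(np.arange(graph.n), positives)
    retain = int(round(config.retain_factor * len(positives)))
    candidates = entropy_rank(P, unlabeled, retain)
    if not candidates:
        return PseudoLabelSet()
    clusters = rbf_cluster_positives(graph.X[positives], config.sigma,
                                     seed=seed)
    selected = select_pseudo_positives(candidates, P, clusters, graph.X,
                                       config.theta_p)
    logger.info("pseudo-positive augmentation: %d candidates -> %d selected",
                len(candidates), len(selected))
    return selected
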
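"""Metrics, cross-validation harness, imbalance experiments, and the
known-driver interaction analysis.

The cross-validation protocol splits the known positives into stratified
folds and, by default, re-runs pseudo-positive augmentation and negative
inference inside each training fold using only that fold's training
positives, so test positives are never seen by any training-side component
(test genes are also excluded from the pseudo-label candidates and the
negative pool).  Test negatives come from the same ICL ranking as training
negatives; the selected block is shuffled before being split between train
and test so neither side systematically receives higher-confidence
negatives.  ``paper_mode`` performs a single global augmentation and folds
the fixed labeled set instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .graph import MultiplexGraph
from .pipeline import PipelineConfig, prepare_labels
from .pretrain import pretrain
from .train import train

logger = logging.getLogger(__name__)


# -- metrics --------------------------------------------------------------

def metrics(scores: np.ndarray, labels: np.ndarray,
            threshold: float = 0.5) -> tuple[float, float, float]:
    """(AUROC, AUPRC, F1).  AUROC uses midrank tie handling; AUPRC is the
    step-integrated precision-recall curve; F1 thresholds at 0.5 by
    default."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to compute ranking metrics")
    auroc = roc_auc_score(labels, scores)
    auprc = average_precision_score(labels, scores)
    f1 = f1_score(labels, (np.asarray(scores) >= threshold).astype(int))
    return float(auroc), float(auprc), float(f1)


# -- cross-validation -----------------------------------------------------

@dataclass
class CVResult:
    records: pd.DataFrame  # columns: seed, fold, auroc, auprc, f1

    @property
    def summary(self) -> pd.Series:
        return self.records[["auroc", "auprc", "f1"]].mean()

    @property
    def spread(self) -> pd.Series:
        return self.records[["auroc", "auprc", "f1"]].std()


def _fold_negative_sets(selected: np.ndarray, n_train: int, n_test: int,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    shuffled = selected[rng.permutation(len(selected))]
    return shuffled[:n_train], shuffled[n_train:n_train + n_test]


def run_fold(graph: MultiplexGraph, train_pos: np.ndarray,
             test_pos: np.ndarray, config: PipelineConfig, seed: int,
             ratio: float = 1.0, Z: np.ndarray | None = None,
             known_negatives: np.ndarray | None = None,
             true_labels: np.ndarray | None = None) -> dict:
    """Train on one fold and evaluate on the held-out positives plus
    held-out inferred negatives (or true negatives when ``true_labels`` is
    given)."""
    rng = np.random.default_rng(seed)
    train_pos = np.asarray(train_pos, dtype=np.intp)
    test_pos = np.asarray(test_pos, dtype=np.intp)
    n_test_neg = int(round(ratio * len(test_pos)))

    # negative count: ratio * |augmented train positives| for training plus
    # a held-out block for the test fold, drawn from one ranking
    pseudo, pos_aug, negs, _, _ = prepare_labels(
        graph, train_pos, config, seed=int(rng.integers(2**31)),
        known_negatives=known_negatives, exclude=test_pos, Z=Z,
        neg_ratio=ratio, extra_negatives=n_test_neg)
    n_train_neg = len(negs) - n_test_neg
    train_negs, test_negs = _fold_negative_sets(negs, n_train_neg,
                                                n_test_neg, rng)

    labeled = np.concatenate([pos_aug, train_negs])
    labels = np.concatenate([np.ones(len(pos_aug), dtype=int),
                             np.zeros(len(train_negs), dtype=int)])
    model = train(graph, labeled, labels, config.training,
                  seed=int(rng.integers(2**31)))
    scores = model.scores(graph)

    if true_labels is not None:
        eval_idx = np.setdiff1d(np.arange(graph.n), labeled)
        y = np.asarray(true_labels)[eval_idx]
    else:
        eval_idx = np.concatenate([test_pos, test_negs])
        y = np.concatenate([np.ones(len(test_pos), dtype=int),
                            np.zeros(len(test_negs), dtype=int)])
    auroc, auprc, f1 = metrics(scores[eval_idx], y)
    return {"auroc": auroc, "auprc": auprc, "f1": f1, "scores": scores,
            "n_pseudo": len(pseudo), "n_train_neg": len(train_negs)}


def cross_validate(graph: MultiplexGraph, positives: np.ndarray,
                   config: PipelineConfig | None = None,
                   n_seeds: int = 10, n_folds: int = 5, ratio: float = 1.0,
                   base_seed: int = 0, paper_mode: bool = False,
                   known_negatives: np.ndarray | None = None) -> CVResult:
    """Repeated stratified k-fold CV over the labeled genes."""
    config = config or PipelineConfig()
    positives = np.asarray(positives, dtype=np.intp)
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        rng = np.random.default_rng(seed)
        Z = None
        if (config.icl_input == "consensus"
                and not config.ablate_neg_infer):
            # pretraining is label-free, so one run per seed serves all folds
            Z = pretrain(graph, config.pretrain,
                         seed=int(rng.integers(2**31))).Z
        if paper_mode:
            rows += _paper_mode_seed(graph, positives, config, seed, rng,
                                     ratio, Z, known_negatives, s)
            continue
        # positives are a single class, so plain shuffled folds suffice
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for fold, (tr, te) in enumerate(kf.split(positives.reshape(-1, 1))):
            res = run_fold(graph, positives[tr], positives[te], config,
                           seed=int(rng.integers(2**31)), ratio=ratio, Z=Z,
                           known_negatives=known_negatives)
            rows.append({"seed": s, "fold": fold, "auroc": res["auroc"],
                         "auprc": res["auprc"], "f1": res["f1"]})
    return CVResult(pd.DataFrame(rows))


def _paper_mode_seed(graph, positives, config, seed, rng, ratio, Z,
                     known_negatives, seed_id) -> list[dict]:
    """Single global augmentation; stratified folds over the fixed labeled
    set."""
    _, pos_aug, negs, _, _ = prepare_labels(
        graph, positives, config, seed=int(rng.integers(2**31)),
        known_negatives=known_negatives, Z=Z, neg_ratio=ratio)
    idx = np.concatenate([pos_aug, negs])
    y = np.concatenate([np.ones(len(pos_aug), dtype=int),
                        np.zeros(len(negs), dtype=int)])
    kf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(kf.split(idx.reshape(-1, 1), y)):
        model = train(graph, idx[tr], y[tr], config.training,
                      seed=int(rng.integers(2**31)))
        scores = model.scores(graph)
        auroc, auprc, f1 = metrics(scores[idx[te]], y[te])
        rows.append({"seed": seed_id, "fold": fold, "auroc": auroc,
                     "auprc": auprc, "f1": f1})
    return rows


# -- imbalance experiment -------------------------------------------------

def imbalance_experiment(graph: MultiplexGraph, positives: np.ndarray,
                         config: PipelineConfig | None = None,
                         ratios: tuple[float, ...] = (1.0, 1.5, 2.0),
                         n_seeds: int = 5, n_folds: int = 5,
                         base_seed: int = 0) -> pd.DataFrame:
    """CV metrics for each positive:negative ratio (1:r)."""
    frames = []
    for r in ratios:
        cv = cross_validate(graph, positives, config, n_seeds=n_seeds,
                            n_folds=n_folds, ratio=r, base_seed=base_seed)
        rec = cv.records.copy()
        rec["ratio"] = r
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


# -- interaction analysis -------------------------------------------------

@dataclass
class InteractionCounts:
    per_network: dict[str, pd.DataFrame]  # columns in/out/total per gene
    correlations: pd.DataFrame            # network, kind, rho, pvalue


def cdg_interaction_analysis(graph: MultiplexGraph, known_cdg: np.ndarray,
                             scores: np.ndarray,
                             gene_subset: np.ndarray | None = None
                             ) -> InteractionCounts:
    """Per-network known-driver neighbor counts and their Spearman rank
    correlation with the model score.

    ``total`` counts unique known-driver neighbors regardless of direction
    (a driver adjacent in both directions counts once); for undirected
    layers in = out = total.
    """
    known_cdg = np.asarray(known_cdg, dtype=np.intp)
    if len(known_cdg) == 0:
        raise ValueError("empty known-driver set")
    if gene_subset is None:
        gene_subset = np.setdiff1d(np.arange(graph.n), known_cdg)
    gene_subset = np.asarray(gene_subset, dtype=np.intp)
    mask = np.zeros(graph.n)
    mask[known_cdg] = 1.0

    tables: dict[str, pd.DataFrame] = {}
    corr_rows = []
    for name, adj, directed in zip(graph.layer_names, graph.layers,
                                   graph.directed):
        out_counts = np.asarray(adj @ mask).ravel()           # successors
        in_counts = np.asarray(adj.T @ mask).ravel()          # predecessors
        union = adj.maximum(adj.T)
        total = np.asarray(union @ mask).ravel()
        df = pd.DataFrame({
            "gene": graph.universe.symbols,
            "in": in_counts.astype(int),
            "out": out_counts.astype(int),
            "total": total.astype(int),
            "score": scores,
        }).iloc[gene_subset].reset_index(drop=True)
        tables[name] = df
        kinds = ("in", "out", "total") if directed else ("total",)
        for kind in kinds:
            if df[kind].nunique() < 2 or df["score"].nunique() < 2:
                rho, p = np.nan, np.nan  # constant input: undefined
            else:
                rho, p = stats.spearmanr(df["score"], df[kind])
            corr_rows.append({"network": name, "kind": kind,
                              "rho": float(rho), "pvalue": float(p)})
    return InteractionCounts(tables, pd.DataFrame(corr_rows))


def sign_test_greater(a: np.ndarray, b: np.ndarray) -> float:
    """One-sided sign test p-value for median(a) > median(b), paired."""
    diff = np.asarray(a) - np.asarray(b)
    wins = int((diff > 0).sum())
    trials = int((diff != 0).sum())
    if trials == 0:
        return 1.0
    return float(stats.binomtest(wins, trials, p=0.5,
                                 alternative="greater").pvalue)
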
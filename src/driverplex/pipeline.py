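"""End-to-end pipeline: augmentation -> pretraining -> negative inference
-> supervised training -> ranked gene scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import MultiplexGraph
from .negatives import AnomalyScores, NegInferConfig, infer_negatives
from .pretrain import PretrainConfig, PretrainResult, pretrain
from .pseudolabel import AugmentConfig, PseudoLabelSet, augment_positives
from .train import TrainedModel, TrainingConfig, train

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    pretrain: PretrainConfig = field(default_factory=PretrainConfig)
    neg_infer: NegInferConfig = field(default_factory=NegInferConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    neg_ratio: float = 1.0            # negatives per (augmented) positive
    icl_input: str = "consensus"      # "consensus" | "raw"
    ablate_pos_augment: bool = False
    ablate_neg_infer: bool = False    # use the provided negative list instead

    def __post_init__(self):
        # the encoders share architecture hyperparameters
        self.pretrain.hidden = self.training.hidden
        self.pretrain.n_layers = self.training.n_layers
        self.pretrain.alpha = self.training.alpha
        self.pretrain.max_degree = self.training.max_degree


def desk_config(hidden: int = 16, n_layers: int = 2,
                icl_input: str = "consensus") -> PipelineConfig:
    """Scaled-down configuration for synthetic benchmark graphs.

    The full-size defaults (hidden 256, 3 layers, 1000 epochs) target
    genome-scale networks; synthetic studies in this package run on a few
    hundred genes, where a 16-unit 2-layer encoder, shorter training and a
    window of 4 on the consensus embedding give the same qualitative
    behavior in seconds per run.
    """
    cfg = PipelineConfig(
        augment=AugmentConfig(hidden=32, epochs=100),
        pretrain=PretrainConfig(epochs=30, patience=10),
        neg_infer=NegInferConfig(epochs=40,
                                 window=4 if icl_input == "consensus" else 8),
        training=TrainingConfig(hidden=hidden, n_layers=n_layers, epochs=150,
                                patience=15),
        icl_input=icl_input,
    )
    return cfg


@dataclass
class PipelineResult:
    pseudo: PseudoLabelSet
    pretrain_result: PretrainResult | None
    anomalies: AnomalyScores | None
    negative_idx: np.ndarray
    positive_idx: np.ndarray          # known + pseudo
    model: TrainedModel
    scores: np.ndarray


def prepare_labels(graph: MultiplexGraph, positives: np.ndarray,
                   config: PipelineConfig, seed: int,
                   known_negatives: np.ndarray | None = None,
                   exclude: np.ndarray | None = None,
                   Z: np.ndarray | None = None,
                   n_negatives: int | None = None,
                   neg_ratio: float | None = None,
                   extra_negatives: int = 0):
    """Run augmentation and negative inference; returns the training label
    material plus intermediate artifacts.

    ``exclude`` keeps the given genes out of the pseudo-label candidate set
    and the negative pool (used by the cross-validation harness to protect
    test genes).  ``Z`` short-circuits pretraining with a precomputed
    consensus embedding.
    """
    rng = np.random.default_rng(seed)
    positives = np.asarray(positives, dtype=np.intp)
    exclude = (np.asarray(exclude, dtype=np.intp)
               if exclude is not None else np.empty(0, dtype=np.intp))

    pseudo = PseudoLabelSet()
    if not config.ablate_pos_augment:
        pseudo = augment_positives(graph, positives, config.augment,
                                   seed=int(rng.integers(2**31)))
        if len(exclude):
            keep = [m for m in pseudo.members if m.index not in set(exclude)]
            pseudo = PseudoLabelSet(keep)
    pos_aug = np.concatenate([positives, pseudo.indices]).astype(np.intp)

    pre_result = None
    anomalies = None
    if n_negatives is None:
        ratio = config.neg_ratio if neg_ratio is None else neg_ratio
        n_negatives = int(round(ratio * len(pos_aug))) + extra_negatives
    if config.ablate_neg_infer:
        if known_negatives is None:
            raise ValueError("negative-inference ablation requires a "
                             "known-negative list")
        pool = np.setdiff1d(np.asarray(known_negatives, dtype=np.intp),
                            np.concatenate([pos_aug, exclude]))
        if len(pool) < n_negatives:
            logger.warning("known-negative pool too small (%d < %d)",
                           len(pool), n_negatives)
            n_negatives = len(pool)
        negative_idx = np.sort(rng.choice(pool, size=n_negatives,
                                          replace=False))
    else:
        if config.icl_input == "consensus":
            if Z is None:
                pre_result = pretrain(graph, config.pretrain,
                                      seed=int(rng.integers(2**31)),
                                      positives=positives)
                Z = pre_result.Z
            icl_features = Z
        else:
            icl_features = graph.X
        anomalies = infer_negatives(icl_features, pos_aug,
                                    config.neg_infer,
                                    seed=int(rng.integers(2**31)),
                                    n_select=n_negatives, exclude=exclude)
        negative_idx = anomalies.negative_indices
    return pseudo, pos_aug, negative_idx, pre_result, anomalies


def run_pipeline(graph: MultiplexGraph, positives: np.ndarray,
                 config: PipelineConfig | None = None, seed: int = 0,
                 known_negatives: np.ndarray | None = None,
                 Z: np.ndarray | None = None) -> PipelineResult:
    """Full pipeline on one labeled set; returns scores for every gene."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    pseudo, pos_aug, neg_idx, pre_result, anomalies = prepare_labels(
        graph, positives, config, seed=int(rng.integers(2**31)),
        known_negatives=known_negatives, Z=Z)
    labeled = np.concatenate([pos_aug, neg_idx])
    labels = np.concatenate([np.ones(len(pos_aug), dtype=int),
                             np.zeros(len(neg_idx), dtype=int)])
    model = train(graph, labeled, labels, config.training,
                  seed=int(rng.integers(2**31)))
    return PipelineResult(pseudo, pre_result, anomalies, neg_idx, pos_aug,
                          model, model.scores(graph))
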
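"""Disease-oriented (local) AUC and cross-validation protocols.

For each disease with at least one held-out positive, the local AUC is the
fraction of (test-positive, unlabeled) microbe pairs where the positive
outscores the unlabeled microbe, ties counting one half; the aggregate AUC
is the unweighted mean over evaluable diseases.  Two protocols are
implemented: leave-one-out (every known association held out in turn, the
model retrained on the remainder) and repeated k-fold over the positives,
reported as mean +/- standard deviation across repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import AssociationDataset, ScoreMatrix, SimilarityMatrix
from .model import (
    TrainingConfig,
    augment_with_similarity,
    predict_scores,
    train,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CvSplit",
    "EvaluationResult",
    "local_auc",
    "aggregate_auc",
    "score_split",
    "run_loocv",
    "run_kfold",
]


@dataclass
class CvSplit:
    """One train/test partition of the known positives.

    ``test_pairs`` are (microbe_idx, disease_idx) positives withheld from
    training; the training matrix is the full matrix with them zeroed.
    """

    dataset: AssociationDataset
    test_pairs: np.ndarray
    fold: int = 0
    repeat: int = 0

    def __post_init__(self) -> None:
        self.test_pairs = np.asarray(self.test_pairs, dtype=int).reshape(-1, 2)
        for i, j in self.test_pairs:
            if self.dataset.matrix[i, j] != 1:
                raise ValueError(f"test pair ({i}, {j}) is not a known positive")

    def train_dataset(self) -> AssociationDataset:
        matrix = self.dataset.matrix.copy()
        matrix[self.test_pairs[:, 0], self.test_pairs[:, 1]] = 0
        return self.dataset.with_matrix(matrix)


@dataclass
class EvaluationResult:
    """Aggregate local-AUC outcome of a cross-validation run."""

    protocol: str
    aggregate: float
    std: float | None = None
    per_repeat: list[float] = field(default_factory=list)
    per_disease: dict[str, float] = field(default_factory=dict)
    n_folds: int = 0

    def summary(self) -> str:
        out = f"{self.protocol}: AUC = {self.aggregate:.4f}"
        if self.std is not None:
            out += f" +/- {self.std:.4f} ({len(self.per_repeat)} repeats)"
        return out


def local_auc(
    scores_d: np.ndarray,
    test_positives: np.ndarray,
    all_positives: np.ndarray,
) -> float | None:
    """Local AUC for one disease.

    Parameters
    ----------
    scores_d
        Score vector over all microbes for the disease.
    test_positives
        Microbe indices of held-out positives for the disease.
    all_positives
        Microbe indices positive for the disease in the *full* network
        (train and test); everything else is unlabeled.

    Returns None (disease skipped) when there are no unlabeled microbes.
    """
    test_positives = np.asarray(test_positives, dtype=int)
    if test_positives.size == 0:
        return None
    labelled = np.zeros(len(scores_d), dtype=bool)
    labelled[np.asarray(all_positives, dtype=int)] = True
    unl = np.flatnonzero(~labelled)
    if unl.size == 0:
        logger.warning("disease has no unlabeled microbes; skipped")
        return None
    pos_scores = scores_d[test_positives][:, None]
    unl_scores = scores_d[unl][None, :]
    wins = (pos_scores > unl_scores).sum() + 0.5 * (pos_scores == unl_scores).sum()
    return float(wins / (test_positives.size * unl.size))


def aggregate_auc(per_disease: list[float]) -> float:
    """Unweighted mean local AUC over evaluable diseases."""
    if not per_disease:
        raise ValueError("no evaluable diseases")
    return float(np.mean(per_disease))


def score_split(
    split: CvSplit,
    config: TrainingConfig,
    S_d: SimilarityMatrix | None = None,
    S_m: SimilarityMatrix | None = None,
    rng: np.random.Generator | None = None,
) -> ScoreMatrix:
    """Train on the split's training positives and score all pairs."""
    train_data = split.train_dataset()
    params = train(train_data, config, rng=rng)
    scores = predict_scores(params, train_data)
    if S_d is not None or S_m is not None:
        scores = augment_with_similarity(
            scores, train_data, S_d, S_m, config.alpha_d, config.alpha_m
        )
    return scores


def _split_aucs(
    split: CvSplit, scores: ScoreMatrix
) -> list[float]:
    """Per-disease local AUCs for the split's evaluable diseases."""
    dataset = split.dataset
    aucs = []
    for j in np.unique(split.test_pairs[:, 1]):
        test_pos = split.test_pairs[split.test_pairs[:, 1] == j, 0]
        all_pos = np.flatnonzero(dataset.matrix[:, j])
        auc = local_auc(scores.values[j], test_pos, all_pos)
        if auc is not None:
            aucs.append(auc)
    return aucs


def run_loocv(
    dataset: AssociationDataset,
    config: TrainingConfig,
    S_d: SimilarityMatrix | None = None,
    S_m: SimilarityMatrix | None = None,
    seed: int | None = None,
) -> EvaluationResult:
    """Leave-one-out: each positive is held out and the model retrained.

    The aggregate is the mean of the singleton-test local AUCs over all
    held-out associations.
    """
    positives = dataset.positives()
    if len(positives) < 2:
        raise ValueError("leave-one-out needs at least two positives")
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    child_seeds = ss.spawn(len(positives))
    aucs = []
    per_disease: dict[str, list[float]] = {}
    for k, pair in enumerate(positives):
        split = CvSplit(dataset, pair[None, :], fold=k)
        rng = np.random.default_rng(child_seeds[k])
        scores = score_split(split, config, S_d, S_m, rng=rng)
        fold_aucs = _split_aucs(split, scores)
        if not fold_aucs:
            continue
        aucs.extend(fold_aucs)
        dname = dataset.disease_names[pair[1]]
        per_disease.setdefault(dname, []).extend(fold_aucs)
    return EvaluationResult(
        protocol="loocv",
        aggregate=aggregate_auc(aucs),
        per_disease={d: float(np.mean(v)) for d, v in per_disease.items()},
        n_folds=len(positives),
    )


def kfold_splits(
    dataset: AssociationDataset, k: int, rng: np.random.Generator, repeat: int = 0
) -> list[CvSplit]:
    """Shuffle the positives into k near-equal folds."""
    positives = dataset.positives()
    perm = rng.permutation(len(positives))
    return [
        CvSplit(dataset, positives[perm[f::k]], fold=f, repeat=repeat)
        for f in range(k)
    ]


def run_kfold(
    dataset: AssociationDataset,
    config: TrainingConfig,
    k: int = 5,
    repeats: int = 50,
    S_d: SimilarityMatrix | None = None,
    S_m: SimilarityMatrix | None = None,
    seed: int | None = None,
) -> EvaluationResult:
    """Repeated k-fold cross-validation over the known positives.

    Per repeat the positives are reshuffled into k folds; the repeat's value
    is the mean aggregate AUC over its folds, and the report is the mean
    +/- standard deviation across repeats.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(dataset.positives()) < k:
        raise ValueError("fewer positives than folds")
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    per_repeat = []
    for r, rep_seed in enumerate(ss.spawn(repeats)):
        rep_rng = np.random.default_rng(rep_seed)
        fold_values = []
        for split in kfold_splits(dataset, k, rep_rng, repeat=r):
            scores = score_split(split, config, S_d, S_m, rng=rep_rng)
            fold_aucs = _split_aucs(split, scores)
            if not fold_aucs:
                logger.warning(
                    "repeat %d fold %d: no evaluable diseases; skipped",
                    r,
                    split.fold,
                )
                continue
            fold_values.append(aggregate_auc(fold_aucs))
        if fold_values:
            per_repeat.append(float(np.mean(fold_values)))
    if not per_repeat:
        raise ValueError("no evaluable folds in any repeat")
    return EvaluationResult(
        protocol=f"{k}-fold x {repeats}",
        aggregate=float(np.mean(per_repeat)),
        std=float(np.std(per_repeat)),
        per_repeat=per_repeat,
        n_folds=k,
    )
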
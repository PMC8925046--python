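"""Group-preference Bayesian pairwise ranking of microbes for diseases.

The model is a latent-factor recommender over an implicit-feedback bipartite
network: each microbe i carries a latent vector U_i, each disease d a latent
vector V_d and a bias b_d, and the raw preference of d for i is

    r_di = V_d . U_i + b_d.

Training follows the Bayesian personalized ranking recipe extended with
*group preference*: a sampled quadruple consists of a known association
(i, d), a negative disease b not associated with i, and a group G of
microbes all known-associated with d (with i in G).  The group preference
r_Gd is the mean raw score of the group members, and the blended preference

    r_Gid = rho * r_Gd + (1 - rho) * r_id

is pushed above the individual negative preference r_ib via the logistic
pairwise loss

    F = softplus(-(r_Gid - r_ib))
        + a_u/2 sum_{j in G} |U_j|^2 + a_v/2 (|V_d|^2 + |V_b|^2)
        + b_v/2 (b_d^2 + b_b^2),

minimized by stochastic gradient descent.  After training, scores can be
additively augmented with disease- and microbe-similarity evidence: the mean
semantic similarity of the target disease to the candidate microbe's known
diseases, and the mean sequence similarity of the candidate microbe to the
target disease's known microbes.

A mirror-image *disease-axis* grouping (group of diseases associated with
the sampled microbe, negative microbe) is available for ablation studies;
``group_axis="none"`` degenerates to plain pairwise ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .containers import AssociationDataset, ScoreMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "LatentModel",
    "GroupSample",
    "init_model",
    "raw_score",
    "group_preference",
    "combined_preference",
    "sample_quadruple",
    "sample_loss",
    "sgd_step",
    "train",
    "predict_scores",
    "augment_with_similarity",
    "rank_microbes_for_disease",
]

_AXES = ("microbe", "disease", "none")


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the ranking model.

    z: latent dimensionality; group_size: |G|, microbes (or diseases)
    sampled per quadruple; rho: weight of the group preference in the blend;
    gamma: SGD learning rate; alpha_u / alpha_v / beta_v: L2 weights on
    microbe vectors, disease vectors and biases; alpha_d / alpha_m: weights
    of the disease- and microbe-similarity augmentation terms; iterations:
    training epochs (each epoch draws one quadruple per known association);
    group_axis: which side is grouped ("none" disables grouping).
    """

    z: int = 30
    group_size: int = 5
    rho: float = 0.5
    gamma: float = 0.01
    alpha_u: float = 0.01
    alpha_v: float = 0.01
    beta_v: float = 0.01
    alpha_d: float = 0.5
    alpha_m: float = 0.5
    iterations: int = 100
    group_axis: str = "microbe"
    init_scale: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.z < 1:
            raise ValueError("z must be >= 1")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        for name in ("gamma", "alpha_u", "alpha_v", "beta_v", "alpha_d", "alpha_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.group_axis not in _AXES:
            raise ValueError(f"group_axis must be one of {_AXES}")

    def replace(self, **kwargs) -> "TrainingConfig":
        return replace(self, **kwargs)


@dataclass
class LatentModel:
    """Learned parameters: microbe vectors U, disease vectors V, biases b."""

    U: np.ndarray  # nm x z
    V: np.ndarray  # nd x z
    b: np.ndarray  # nd

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.U.ndim != 2 or self.V.ndim != 2 or self.b.ndim != 1:
            raise ValueError("U, V must be 2-d and b 1-d")
        if self.U.shape[1] != self.V.shape[1]:
            raise ValueError("U and V latent dimensions differ")
        if self.V.shape[0] != self.b.shape[0]:
            raise ValueError("V and b disagree on the number of diseases")
        for arr in (self.U, self.V, self.b):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model parameters must be finite")

    def copy(self) -> "LatentModel":
        return LatentModel(self.U.copy(), self.V.copy(), self.b.copy())


@dataclass(frozen=True)
class GroupSample:
    """One SGD quadruple.

    On the microbe axis: microbe ``i``, positive disease ``d``, negative
    disease ``neg`` and microbe group ``group`` (subset of d's known
    microbes, containing i).  On the disease axis the roles mirror: ``group``
    is a subset of i's known diseases containing d, and ``neg`` is a microbe
    not associated with d.
    """

    i: int
    d: int
    neg: int
    group: tuple[int, ...]
    axis: str = "microbe"

    def __post_init__(self) -> None:
        if len(self.group) < 1:
            raise ValueError("group must be nonempty")
        anchor = self.i if self.axis != "disease" else self.d
        if anchor not in self.group:
            raise ValueError("anchor element must belong to the group")


def init_model(
    nm: int,
    nd: int,
    config: TrainingConfig,
    rng: np.random.Generator | None = None,
) -> LatentModel:
    """Zero-mean Gaussian initialization at scale ``config.init_scale``."""
    if nm < 1 or nd < 1:
        raise ValueError("dimensions must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    U = rng.normal(0.0, 1.0, size=(nm, config.z)) * config.init_scale
    V = rng.normal(0.0, 1.0, size=(nd, config.z)) * config.init_scale
    b = np.zeros(nd)
    return LatentModel(U, V, b)


def raw_score(model: LatentModel, d: int, i: int) -> float:
    return float(model.V[d] @ model.U[i] + model.b[d])


def group_preference(model: LatentModel, group: tuple[int, ...], d: int) -> float:
    """Mean raw score of the group's microbes on disease d."""
    if len(group) == 0:
        raise ValueError("empty group")
    g = np.asarray(group)
    return float((model.U[g] @ model.V[d]).mean() + model.b[d])


def combined_preference(
    model: LatentModel, group: tuple[int, ...], i: int, d: int, rho: float
) -> float:
    """Linear blend of group preference and individual preference."""
    return rho * group_preference(model, group, d) + (1 - rho) * raw_score(model, d, i)


class _TrainIndex:
    """Precomputed sampling structures over the training positives."""

    def __init__(self, dataset: AssociationDataset):
        R = dataset.matrix
        self.nm, self.nd = R.shape
        self.positives = np.argwhere(R == 1)
        if len(self.positives) == 0:
            raise ValueError("training matrix has no positive associations")
        self.microbes_of = [np.flatnonzero(R[:, j]) for j in range(self.nd)]
        self.diseases_of = [np.flatnonzero(R[i, :]) for i in range(self.nm)]
        # negative candidates span the full roster: any disease (microbe)
        # without a known association to the anchor is unlabeled
        all_diseases = np.arange(self.nd)
        all_microbes = np.arange(self.nm)
        self.neg_diseases_of = [
            np.setdiff1d(all_diseases, self.diseases_of[i], assume_unique=True)
            for i in range(self.nm)
        ]
        self.neg_microbes_of = [
            np.setdiff1d(all_microbes, self.microbes_of[j], assume_unique=True)
            for j in range(self.nd)
        ]


def sample_quadruple(
    dataset: AssociationDataset | _TrainIndex,
    rng: np.random.Generator,
    config: TrainingConfig,
    _max_retries: int = 100,
) -> GroupSample:
    """Draw one training quadruple uniformly.

    The positive (i, d) is uniform over known associations; the negative is
    uniform over the complementary training items for the anchor; the group
    is the anchor plus a uniform without-replacement sample of the positive
    item's other known partners (capped at their count).
    """
    index = dataset if isinstance(dataset, _TrainIndex) else _TrainIndex(dataset)
    axis = config.group_axis
    for _ in range(_max_retries):
        i, d = index.positives[rng.integers(len(index.positives))]
        if axis == "disease":
            negs = index.neg_microbes_of[d]
        else:
            negs = index.neg_diseases_of[i]
        if len(negs) == 0:
            continue  # anchor saturates its side; resample another positive
        neg = int(negs[rng.integers(len(negs))])
        if axis == "none":
            group: tuple[int, ...] = (int(i),)
        elif axis == "microbe":
            members = index.microbes_of[d]
            k = min(config.group_size, len(members))
            others = members[members != i]
            chosen = rng.choice(others, size=k - 1, replace=False) if k > 1 else []
            group = tuple(sorted({int(i), *map(int, chosen)}))
        else:  # disease axis
            members = index.diseases_of[i]
            k = min(config.group_size, len(members))
            others = members[members != d]
            chosen = rng.choice(others, size=k - 1, replace=False) if k > 1 else []
            group = tuple(sorted({int(d), *map(int, chosen)}))
        return GroupSample(int(i), int(d), neg, group, axis)
    raise RuntimeError(
        "could not sample a quadruple: every drawn positive saturates its "
        "negative side"
    )


def _margin(model: LatentModel, sample: GroupSample, rho: float) -> float:
    """Blended-positive minus negative score difference."""
    if sample.axis == "disease":
        g = np.asarray(sample.group)
        r_G = float((model.V[g] @ model.U[sample.i]).mean() + model.b[g].mean())
        r_di = raw_score(model, sample.d, sample.i)
        r_neg = raw_score(model, sample.d, sample.neg)
        return rho * r_G + (1 - rho) * r_di - r_neg
    r_Gid = combined_preference(model, sample.group, sample.i, sample.d, rho)
    r_ib = raw_score(model, sample.neg, sample.i)
    return r_Gid - r_ib


def sample_loss(
    model: LatentModel, sample: GroupSample, config: TrainingConfig
) -> float:
    """Per-quadruple objective: logistic pairwise loss plus L2 terms."""
    s = _margin(model, sample, config.rho)
    loss = float(np.logaddexp(0.0, -s))
    if sample.axis == "disease":
        g = np.asarray(sample.group)
        loss += config.alpha_v / 2 * float((model.V[g] ** 2).sum())
        loss += config.beta_v / 2 * float((model.b[g] ** 2).sum())
        loss += config.alpha_u / 2 * float(
            (model.U[sample.i] ** 2).sum() + (model.U[sample.neg] ** 2).sum()
        )
    else:
        g = np.asarray(sample.group)
        loss += config.alpha_u / 2 * float((model.U[g] ** 2).sum())
        loss += config.alpha_v / 2 * float(
            (model.V[sample.d] ** 2).sum() + (model.V[sample.neg] ** 2).sum()
        )
        loss += config.beta_v / 2 * float(
            model.b[sample.d] ** 2 + model.b[sample.neg] ** 2
        )
    return loss


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def sgd_step(
    model: LatentModel, sample: GroupSample, config: TrainingConfig
) -> LatentModel:
    """One in-place stochastic gradient step on the sampled quadruple."""
    rho, gamma = config.rho, config.gamma
    s = _margin(model, sample, rho)
    c = -_sigmoid(-s)  # d softplus(-s) / d s
    if not np.isfinite(c):  # pragma: no cover - sigmoid is bounded
        raise FloatingPointError(f"non-finite gradient for sample {sample}")
    U, V, b = model.U, model.V, model.b
    if sample.axis == "disease":
        i, j, d = sample.i, sample.neg, sample.d
        g = np.asarray(sample.group)
        size = len(g)
        VG = V[g].copy()
        Ui = U[i].copy()
        Uj = U[j].copy()
        Vd = V[d].copy()
        gVG = c * (rho / size) * Ui + config.alpha_v * VG
        gbG = c * (rho / size) + config.beta_v * b[g]
        extra_Vd = c * ((1 - rho) * Ui - Uj)
        extra_bd = c * ((1 - rho) - 1.0)
        gUi = c * (rho * VG.mean(axis=0) + (1 - rho) * Vd) + config.alpha_u * Ui
        gUj = c * (-Vd) + config.alpha_u * Uj
        V[g] = VG - gamma * gVG
        b[g] = b[g] - gamma * gbG
        V[d] -= gamma * extra_Vd
        b[d] -= gamma * extra_bd
        U[i] = Ui - gamma * gUi
        U[j] = Uj - gamma * gUj
        return model
    i, d, neg = sample.i, sample.d, sample.neg
    g = np.asarray(sample.group)
    size = len(g)
    UG = U[g].copy()
    Ui = U[i].copy()
    Vd = V[d].copy()
    Vb = V[neg].copy()
    gUG = c * (rho / size) * Vd + config.alpha_u * UG
    extra_Ui = c * ((1 - rho) * Vd - Vb)
    gVd = c * (rho * UG.mean(axis=0) + (1 - rho) * Ui) + config.alpha_v * Vd
    gVb = c * (-Ui) + config.alpha_v * Vb
    gbd = c * 1.0 + config.beta_v * b[d]
    gbb = -c + config.beta_v * b[neg]
    U[g] = UG - gamma * gUG
    U[i] -= gamma * extra_Ui
    V[d] = Vd - gamma * gVd
    V[neg] = Vb - gamma * gVb
    b[d] -= gamma * gbd
    b[neg] -= gamma * gbb
    return model


def train(
    dataset: AssociationDataset,
    config: TrainingConfig,
    rng: np.random.Generator | None = None,
    model: LatentModel | None = None,
) -> LatentModel:
    """Run SGD for ``config.iterations`` epochs.

    Each epoch draws as many quadruples as there are training positives.
    Fully deterministic given ``config.seed`` (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    index = _TrainIndex(dataset)
    if model is None:
        model = init_model(index.nm, index.nd, config, rng)
    n_per_epoch = len(index.positives)
    for epoch in range(config.iterations):
        total = 0.0
        for _ in range(n_per_epoch):
            sample = sample_quadruple(index, rng, config)
            total += sample_loss(model, sample, config)
            sgd_step(model, sample, config)
        logger.info(
            "epoch %d/%d mean loss %.6f",
            epoch + 1,
            config.iterations,
            total / n_per_epoch,
        )
    return model


def predict_scores(
    model: LatentModel, dataset: AssociationDataset
) -> ScoreMatrix:
    """Dense raw preference scores, diseases x microbes."""
    values = model.V @ model.U.T + model.b[:, None]
    return ScoreMatrix(
        list(dataset.disease_names), list(dataset.microbe_names), values
    )


def augment_with_similarity(
    scores: ScoreMatrix,
    dataset_train: AssociationDataset,
    S_d: SimilarityMatrix | None,
    S_m: SimilarityMatrix | None,
    alpha_d: float = 0.5,
    alpha_m: float = 0.5,
) -> ScoreMatrix:
    """Add similarity evidence to the raw scores.

    For a pair (disease d_i, microbe m_j): alpha_d times the mean semantic
    similarity of d_i to m_j's training diseases, plus alpha_m times the
    mean sequence similarity of m_j to d_i's training microbes.  Empty
    neighbor sets contribute nothing.  Neighbor sets come from the training
    positives only.
    """
    values = scores.values.copy()
    R = dataset_train.matrix.astype(float)  # nm x nd
    if S_d is not None and alpha_d > 0:
        sd = S_d.reindex(scores.disease_names).values
        counts = R.sum(axis=1)  # diseases per microbe
        num = sd @ R.T  # nd x nm: sum over d' in D_{m_j} of S_d(d_i, d')
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(counts[None, :] > 0, num / counts[None, :], 0.0)
        values += alpha_d * term
    if S_m is not None and alpha_m > 0:
        sm = S_m.reindex(scores.microbe_names).values
        counts = R.sum(axis=0)  # microbes per disease
        num = (sm @ R).T  # nd x nm: sum over m' in M_{d_i} of S_m(m_j, m')
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(counts[:, None] > 0, num / counts[:, None], 0.0)
        values += alpha_m * term
    return ScoreMatrix(
        list(scores.disease_names),
        list(scores.microbe_names),
        values,
        augmented=True,
    )


def rank_microbes_for_disease(
    scores: ScoreMatrix,
    disease: str,
    exclude_train: bool = False,
    dataset_train: AssociationDataset | None = None,
) -> list[tuple[str, float]]:
    """Microbes sorted by descending score; ties broken by name order."""
    row = scores.row(disease)
    names = scores.microbe_names
    keep = np.ones(len(names), dtype=bool)
    if exclude_train:
        if dataset_train is None:
            raise ValueError("exclude_train requires the training dataset")
        j = dataset_train.disease_names.index(disease)
        mi = {m: k for k, m in enumerate(names)}
        for m_idx in np.flatnonzero(dataset_train.matrix[:, j]):
            name = dataset_train.microbe_names[m_idx]
            if name in mi:
                keep[mi[name]] = False
    entries = [(names[k], float(row[k])) for k in np.flatnonzero(keep)]
    entries.sort(key=lambda e: e[0])  # lexicographic tie-break
    entries.sort(key=lambda e: -e[1])  # stable by score
    return entries
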
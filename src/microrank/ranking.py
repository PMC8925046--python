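"""Model / Results objects wrapping the ranking machinery.

`MicrobeDiseaseBPR` is built from an association dataset (plus optional
similarity matrices); `fit()` runs the seeded SGD training and returns a
`BPRResults` carrying the learned parameters, score matrices and ranking
helpers, with a text `summary()`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AssociationDataset, ScoreMatrix, SimilarityMatrix
from .model import (
    LatentModel,
    TrainingConfig,
    augment_with_similarity,
    predict_scores,
    rank_microbes_for_disease,
    sample_loss,
    sample_quadruple,
    train,
    _TrainIndex,
)

__all__ = ["MicrobeDiseaseBPR", "BPRResults"]


class MicrobeDiseaseBPR:
    """Group-preference pairwise ranking model for a microbe-disease network.

    Parameters
    ----------
    data
        Binary association dataset (training positives).
    disease_similarity, microbe_similarity
        Optional similarity matrices used for score augmentation; they must
        cover the dataset's disease / microbe names.
    config
        Training hyperparameters; keyword overrides are applied on top.

    Examples
    --------
    >>> model = MicrobeDiseaseBPR(data, config=TrainingConfig(seed=0))
    >>> res = model.fit()
    >>> res.rank_microbes("colitis", top=10)
    """

    def __init__(
        self,
        data: AssociationDataset,
        disease_similarity: SimilarityMatrix | None = None,
        microbe_similarity: SimilarityMatrix | None = None,
        config: TrainingConfig | None = None,
        **overrides,
    ):
        self.data = data
        config = config or TrainingConfig()
        if overrides:
            config = config.replace(**overrides)
        self.config = config
        if disease_similarity is not None:
            disease_similarity = disease_similarity.reindex(data.disease_names)
        if microbe_similarity is not None:
            microbe_similarity = microbe_similarity.reindex(data.microbe_names)
        self.disease_similarity = disease_similarity
        self.microbe_similarity = microbe_similarity

    @classmethod
    def from_files(
        cls,
        associations_path,
        disease_similarity_path=None,
        microbe_similarity_path=None,
        config: TrainingConfig | None = None,
        **overrides,
    ) -> "MicrobeDiseaseBPR":
        from . import io

        data = io.load_associations(associations_path)
        sd = (
            io.read_similarity(disease_similarity_path)
            if disease_similarity_path
            else None
        )
        sm = (
            io.read_similarity(microbe_similarity_path)
            if microbe_similarity_path
            else None
        )
        return cls(data, sd, sm, config=config, **overrides)

    def fit(
        self, rng: np.random.Generator | None = None
    ) -> "BPRResults":
        params = train(self.data, self.config, rng=rng)
        return BPRResults(self, params)


class BPRResults:
    """Fitted parameters plus prediction, augmentation and ranking."""

    def __init__(self, model: MicrobeDiseaseBPR, params: LatentModel):
        self.model = model
        self.params = params
        self._raw: ScoreMatrix | None = None
        self._augmented: ScoreMatrix | None = None

    @property
    def scores(self) -> ScoreMatrix:
        """Raw latent-factor scores V_d . U_i + b_d."""
        if self._raw is None:
            self._raw = predict_scores(self.params, self.model.data)
        return self._raw

    @property
    def augmented_scores(self) -> ScoreMatrix:
        """Raw scores plus similarity evidence (falls back to raw when the
        model holds no similarity matrices)."""
        if self._augmented is None:
            cfg = self.model.config
            self._augmented = augment_with_similarity(
                self.scores,
                self.model.data,
                self.model.disease_similarity,
                self.model.microbe_similarity,
                alpha_d=cfg.alpha_d,
                alpha_m=cfg.alpha_m,
            )
        return self._augmented

    def rank_microbes(
        self, disease: str, top: int | None = None, exclude_train: bool = True
    ) -> list[tuple[str, float]]:
        ranked = rank_microbes_for_disease(
            self.augmented_scores,
            disease,
            exclude_train=exclude_train,
            dataset_train=self.model.data,
        )
        return ranked[:top] if top is not None else ranked

    def ranking_table(
        self, top: int | None = None, exclude_train: bool = True
    ) -> pd.DataFrame:
        """Long-format table (disease, microbe, score, rank) for all diseases."""
        rows = []
        for disease in self.model.data.disease_names:
            for rank, (microbe, score) in enumerate(
                self.rank_microbes(disease, top=top, exclude_train=exclude_train),
                start=1,
            ):
                rows.append((disease, microbe, score, rank))
        return pd.DataFrame(rows, columns=["disease", "microbe", "score", "rank"])

    def mean_training_loss(self, n_samples: int = 200, seed: int = 0) -> float:
        """Monte-Carlo estimate of the per-quadruple objective at the fit."""
        rng = np.random.default_rng(seed)
        index = _TrainIndex(self.model.data)
        cfg = self.model.config
        return float(
            np.mean(
                [
                    sample_loss(
                        self.params, sample_quadruple(index, rng, cfg), cfg
                    )
                    for _ in range(n_samples)
                ]
            )
        )

    def summary(self) -> str:
        data, cfg = self.model.data, self.model.config
        sims = []
        if self.model.disease_similarity is not None:
            sims.append("disease semantic")
        if self.model.microbe_similarity is not None:
            sims.append("microbe sequence")
        lines = [
            "Group-preference Bayesian microbe-disease ranking",
            "=" * 50,
            f"microbes (nm):        {data.nm}",
            f"diseases (nd):        {data.nd}",
            f"known associations:   {data.n_assoc}",
            f"latent dimension z:   {cfg.z}",
            f"group axis / size:    {cfg.group_axis} / {cfg.group_size}",
            f"rho (group weight):   {cfg.rho}",
            f"learning rate gamma:  {cfg.gamma}",
            f"L2 (a_u, a_v, b_v):   ({cfg.alpha_u}, {cfg.alpha_v}, {cfg.beta_v})",
            f"augment (a_d, a_m):   ({cfg.alpha_d}, {cfg.alpha_m})",
            f"epochs:               {cfg.iterations}",
            f"similarities in use:  {', '.join(sims) if sims else 'none'}",
            f"mean sample loss:     {self.mean_training_loss():.4f}",
        ]
        return "\n".join(lines)
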
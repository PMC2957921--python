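"""Synthetic docking-score generator standing in for the commercial docking
engine.

Each synthetic compound gets, per receptor structure, a best-pose score
drawn from a class-conditional normal distribution (truncated at zero) in
the regime of published PXR GoldScores — nonagonist means around 35–45,
agonist means around 55–70, spread ~8. The remaining poses sit below the
best pose by folded-normal jitter, so best-of-poses aggregation recovers the
drawn score exactly. Tanimoto-like weights are drawn independently from a
Beta distribution on [0, 1]. Everything is reproducible from the seed.

The generator makes no attempt to simulate molecular structures or a
physically meaningful score–similarity correlation; it exists so every
pipeline stage downstream of the docking engine is testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    DockingScoreMatrix,
    DomainError,
    Label,
    PipelineConfig,
    PXR_STRUCTURES,
    Scheme,
    SimilarityWeights,
)

#: Default class-conditional best-pose score means per structure.
AGONIST_MEANS: dict[str, float] = {
    "1M13": 65.0, "1NRL": 55.0, "1SKX": 60.0, "2O9I": 56.0, "2QNV": 58.0,
}
NONAGONIST_MEANS: dict[str, float] = {
    "1M13": 42.0, "1NRL": 36.0, "1SKX": 40.0, "2O9I": 37.0, "2QNV": 39.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic docking-score model.

    ``weight_alpha``/``weight_beta`` parameterise the Beta distribution of
    similarity weights; the default Beta(2, 5) (mean ≈ 0.29) mimics typical
    MACCS Tanimoto values of chemically diverse compounds against a handful
    of reference ligands.
    """

    n_agonists: int = 50
    n_nonagonists: int = 50
    agonist_means: Mapping[str, float] = field(default_factory=lambda: dict(AGONIST_MEANS))
    nonagonist_means: Mapping[str, float] = field(default_factory=lambda: dict(NONAGONIST_MEANS))
    score_sd: float = 8.0
    n_poses: int = 20
    pose_jitter_sd: float = 5.0
    weight_alpha: float = 2.0
    weight_beta: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agonists <= 0 or self.n_nonagonists <= 0:
            raise DomainError("both classes need at least one compound")
        if self.score_sd <= 0 or self.pose_jitter_sd <= 0:
            raise DomainError("standard deviations must be positive")
        if self.n_poses < 1:
            raise DomainError("n_poses must be >= 1")
        if set(self.agonist_means) != set(self.nonagonist_means):
            raise DomainError("class means must cover the same structures")

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(self.agonist_means)

    def with_separation(self, separation_sd: float) -> "GeneratorConfig":
        """Config whose agonist means sit ``separation_sd`` standard
        deviations above the nonagonist means on every structure."""
        ag = {
            pdb: m + separation_sd * self.score_sd
            for pdb, m in self.nonagonist_means.items()
        }
        return replace(self, agonist_means=ag)


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[DockingScoreMatrix, SimilarityWeights, dict[str, Label]]:
    """Draw a synthetic score matrix, weights, and ground-truth labels.

    The drawn best-pose score is exactly the maximum over the generated
    poses, and the best pose lands at a random pose index.
    """
    rng = np.random.default_rng(config.rng_seed)
    structures = config.structures
    n = config.n_agonists + config.n_nonagonists
    ids = np.array(
        [f"ag{i:05d}" for i in range(config.n_agonists)]
        + [f"non{i:05d}" for i in range(config.n_nonagonists)]
    )
    truth = {
        cid: (Label.AGONIST if cid.startswith("ag") else Label.NONAGONIST) for cid in ids
    }

    means = np.empty((n, len(structures)))
    for j, pdb in enumerate(structures):
        means[: config.n_agonists, j] = config.agonist_means[pdb]
        means[config.n_agonists :, j] = config.nonagonist_means[pdb]
    best = rng.normal(means, config.score_sd)
    best = np.clip(best, 0.0, None)  # scores truncated at zero

    # poses: best minus folded-normal offsets, best placed at a random index
    k = config.n_poses
    offsets = np.abs(rng.normal(0.0, config.pose_jitter_sd, size=(n, len(structures), k)))
    scores = best[:, :, None] - offsets
    scores = np.clip(scores, 0.0, None)
    best_slot = rng.integers(0, k, size=(n, len(structures)))
    idx0, idx1 = np.ogrid[:n, : len(structures)]
    scores[idx0, idx1, best_slot] = best

    frame = pd.DataFrame(
        {
            "compound_id": np.repeat(ids, len(structures) * k),
            "receptor_pdb": np.tile(np.repeat(list(structures), k), n),
            "pose_index": np.tile(np.arange(1, k + 1), n * len(structures)),
            "score": scores.reshape(-1),
        }
    )
    matrix = DockingScoreMatrix(frame, structures=structures)

    w = rng.beta(config.weight_alpha, config.weight_beta, size=(n, len(structures)))
    weights = SimilarityWeights(
        {
            (cid, pdb): float(w[i, j])
            for i, cid in enumerate(ids)
            for j, pdb in enumerate(structures)
        }
    )
    return matrix, weights, truth


def recovery_experiment(
    config: GeneratorConfig,
    pipeline_config: Optional[PipelineConfig] = None,
):
    """Generate a dataset, classify it with dataset-mean cutoffs, and score
    the recovered labels against the generator's truth.

    Returns a dict mapping scheme -> ConfusionStats.
    """
    from .model import ConsensusDockingModel  # deferred: circular import

    from .datatypes import CutoffPolicy, MissingLabelPolicy

    if pipeline_config is None:
        pipeline_config = PipelineConfig(
            cutoff_policy=CutoffPolicy.MEAN_OF_DATASET,
            structures=config.structures,
        )
    matrix, weights, truth = generate_dataset(config)
    model = ConsensusDockingModel(matrix, weights=weights, config=pipeline_config)
    results = model.fit()
    return results.evaluate(truth)
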
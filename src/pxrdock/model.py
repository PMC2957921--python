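"""Model/Results interface over the consensus-docking classification chain.

``ConsensusDockingModel`` holds the data (per-pose docking scores, optional
similarity weights and reference ligands) and the pipeline configuration;
``fit()`` derives the per-structure cutoffs under the configured policy and
produces a ``ConsensusDockingResults`` carrying the cutoff table, the
per-structure calls, the consensus labels, and evaluation/summary methods.

Example
-------
>>> from pxrdock import ConsensusDockingModel, simulate
>>> matrix, weights, truth = simulate.generate_dataset(simulate.GeneratorConfig(rng_seed=7))
>>> res = ConsensusDockingModel(matrix, weights=weights).fit()
>>> stats = res.evaluate(truth)
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import classify as _classify
from .datatypes import (
    AssayRecord,
    Consensus,
    ConsensusCall,
    CutoffPolicy,
    CutoffTable,
    DockingScoreMatrix,
    Label,
    PipelineConfig,
    ReferenceLigand,
    Scheme,
    SimilarityWeights,
)
from .evaluate import ConfusionStats, confusion, summary_frame


class ConsensusDockingModel:
    """Consensus docking classifier over five receptor structures.

    Parameters
    ----------
    scores
        Per-pose docking scores (``DockingScoreMatrix`` or a tidy DataFrame
        with compound_id / receptor_pdb / pose_index / score columns).
    weights
        Tanimoto similarity weights to each structure's cocrystal ligand;
        omit to run the GoldScore scheme only.
    references
        Cocrystallized reference ligands; required for the
        ``pct80_of_reference`` cutoff policy.
    config
        Pipeline configuration (cutoff policy, pose aggregation, vote
        threshold, missing-label policy).
    """

    def __init__(
        self,
        scores: Union[DockingScoreMatrix, pd.DataFrame],
        weights: Optional[SimilarityWeights] = None,
        references: Optional[Sequence[ReferenceLigand]] = None,
        config: Optional[PipelineConfig] = None,
    ):
        if isinstance(scores, pd.DataFrame):
            scores = DockingScoreMatrix(scores)
        self.scores = scores
        self.weights = weights
        self.references = references
        if config is None:
            config = PipelineConfig(structures=scores.structures)
        self.config = config

    @classmethod
    def from_dataframes(
        cls,
        score_frame: pd.DataFrame,
        weight_frame: Optional[pd.DataFrame] = None,
        references: Optional[Sequence[ReferenceLigand]] = None,
        config: Optional[PipelineConfig] = None,
    ) -> "ConsensusDockingModel":
        weights = SimilarityWeights.from_frame(weight_frame) if weight_frame is not None else None
        return cls(score_frame, weights=weights, references=references, config=config)

    def fit(self, cutoffs: Optional[CutoffTable] = None) -> "ConsensusDockingResults":
        """Derive cutoffs (unless supplied) and classify every compound."""
        if cutoffs is None:
            cutoffs = _classify.derive_cutoffs(
                self.scores, self.weights, self.config, references=self.references
            )
        calls = _classify.classify_dataset(self.scores, self.weights, cutoffs, self.config)
        return ConsensusDockingResults(self, cutoffs, calls)


class ConsensusDockingResults:
    """Fitted cutoffs and consensus calls, with evaluation and reporting."""

    def __init__(
        self,
        model: ConsensusDockingModel,
        cutoffs: CutoffTable,
        calls: list[ConsensusCall],
    ):
        self.model = model
        self.cutoffs = cutoffs
        self.calls = calls

    @property
    def calls_frame(self) -> pd.DataFrame:
        return _classify.calls_to_frame(self.calls)

    def consensus(self, scheme: Scheme = Scheme.GOLDSCORE) -> dict[str, Consensus]:
        return {c.compound_id: c.consensus for c in self.calls if c.scheme is scheme}

    def evaluate(
        self,
        truth: Union[Mapping[str, Label], Sequence[AssayRecord]],
    ) -> dict[Scheme, ConfusionStats]:
        """Confusion statistics per scheme against truth labels.

        ``truth`` is either a mapping compound_id -> label or a sequence of
        assay records (their reporter-assay class is used).
        """
        if not isinstance(truth, Mapping):
            truth = {a.compound_id: a.ncgc_class for a in truth}
        out: dict[Scheme, ConfusionStats] = {}
        for scheme in Scheme:
            preds = self.consensus(scheme)
            if preds:
                out[scheme] = confusion(preds, truth, self.model.config.missing_label_policy)
        return out

    def summary(
        self,
        truth: Optional[Union[Mapping[str, Label], Sequence[AssayRecord]]] = None,
    ) -> str:
        """Human-readable summary: cutoffs, call counts, and (when truth
        labels are given) the SE/SP/Q/C table."""
        cfg = self.model.config
        lines = [
            "Consensus Docking Classification Results",
            "=" * 48,
            f"Compounds:        {len(self.model.scores.compound_ids)}",
            f"Structures:       {', '.join(cfg.structures)}",
            f"Cutoff policy:    {self.cutoffs.policy.value}",
            f"Pose aggregation: {cfg.pose_aggregation.value}",
            f"Vote threshold:   {cfg.vote_threshold} of {len(cfg.structures)}",
            "",
            "Cutoffs (GoldScore / hybrid):",
        ]
        for pdb in self.cutoffs.structures:
            lines.append(
                f"  {pdb}: {self.cutoffs.gs_cutoff[pdb]:.2f} / {self.cutoffs.hs_cutoff[pdb]:.2f}"
            )
        lines.append("")
        for scheme in Scheme:
            cons = self.consensus(scheme)
            if not cons:
                continue
            n_a = sum(1 for v in cons.values() if v is Consensus.AGONIST)
            n_n = sum(1 for v in cons.values() if v is Consensus.NONAGONIST)
            n_i = len(cons) - n_a - n_n
            lines.append(
                f"{scheme.value:>9} consensus: {n_a} agonist, {n_n} nonagonist, "
                f"{n_i} indeterminate"
            )
        if truth is not None:
            stats = self.evaluate(truth)
            lines += ["", summary_frame(stats).to_string(index=False)]
        return "\n".join(lines)
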
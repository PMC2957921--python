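"""Hybrid scores, cutoff derivation, per-structure calls, and the 3-of-5
majority-vote consensus.

Two scoring schemes run side by side. The GoldScore scheme compares the
best-pose docking score of a compound against a per-structure cutoff. The
hybrid scheme first multiplies that score by the compound's Tanimoto
similarity w to the structure's own cocrystallized ligand, widening the gap
between agonists and nonagonists when the test compound resembles a known
binder. Each structure votes agonist/nonagonist and a compound is called an
agonist when at least ``vote_threshold`` (default 3 of 5) structures agree.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping, Optional, Sequence

import pandas as pd

from .datatypes import (
    Consensus,
    ConsensusCall,
    CutoffPolicy,
    CutoffTable,
    DockingScoreMatrix,
    DomainError,
    Label,
    PipelineConfig,
    PoseAggregation,
    ReferenceLigand,
    Scheme,
    SimilarityWeights,
)


def aggregate_poses(
    matrix: DockingScoreMatrix,
    compound_id: str,
    receptor_pdb: str,
    mode: PoseAggregation = PoseAggregation.MAX,
) -> Optional[float]:
    """Reduce the per-pose scores of one complex to a single score.

    ``max`` keeps the best-scored docking solution (default); ``mean``
    averages the independent runs. Returns ``None`` when the compound has no
    poses for the structure (missing-data signal).
    """
    poses = matrix.poses(compound_id, receptor_pdb)
    if not poses:
        return None
    return max(poses) if mode is PoseAggregation.MAX else sum(poses) / len(poses)


def aggregate_all(matrix: DockingScoreMatrix, mode: PoseAggregation) -> pd.DataFrame:
    """Vectorised pose aggregation: one row per (compound, structure)."""
    agg = "max" if mode is PoseAggregation.MAX else "mean"
    out = (
        matrix.frame.groupby(["compound_id", "receptor_pdb"], sort=False)["score"]
        .agg(agg)
        .reset_index()
    )
    return out


def hybrid_score(s: float, w: Optional[float]) -> Optional[float]:
    """Similarity-weighted docking score S = w × s.

    Negative raw scores are clamped to 0 with a warning (a GoldScore below 0
    carries no binding signal); a missing weight propagates as ``None``.
    """
    if w is None:
        return None
    if s < 0:
        warnings.warn(f"negative raw score {s} clamped to 0", stacklevel=2)
        s = 0.0
    return w * s


def derive_cutoff_pct80(reference_goldscore: float) -> int:
    """Per-structure GoldScore cutoff: 80% of the cocrystal ligand's own
    score, rounded to the nearest integer (half away from zero)."""
    if reference_goldscore <= 0:
        raise DomainError(f"reference goldscore must be positive: {reference_goldscore}")
    return int(math.floor(0.8 * reference_goldscore + 0.5))


def derive_cutoff_mean(scores: Sequence[float]) -> float:
    """Dataset-mean cutoff: the average score over all compounds docked to
    one structure (used for the full-library classification)."""
    if len(scores) == 0:
        raise DomainError("cannot derive a mean cutoff from an empty score list")
    return sum(scores) / len(scores)


def classify_structure(score: float, cutoff: float) -> Label:
    """Agonist iff score >= cutoff (the boundary counts as active)."""
    return Label.AGONIST if score >= cutoff else Label.NONAGONIST


def consensus_vote(calls: Mapping[str, Label], threshold: int = 3) -> Consensus:
    """Majority vote over the per-structure calls.

    Agonist when at least ``threshold`` structures call agonist, nonagonist
    when at least ``threshold`` call nonagonist; otherwise indeterminate,
    which can only happen when calls are missing.
    """
    n_a = sum(1 for v in calls.values() if v is Label.AGONIST)
    n_n = sum(1 for v in calls.values() if v is Label.NONAGONIST)
    if n_a + n_n == 0:
        warnings.warn("no non-missing per-structure calls; consensus indeterminate",
                      stacklevel=2)
        return Consensus.INDETERMINATE
    if n_a >= threshold:
        return Consensus.AGONIST
    if n_n >= threshold:
        return Consensus.NONAGONIST
    return Consensus.INDETERMINATE


def derive_cutoffs(
    matrix: DockingScoreMatrix,
    weights: Optional[SimilarityWeights],
    config: PipelineConfig,
    references: Optional[Sequence[ReferenceLigand]] = None,
    gs_fixed: Optional[Mapping[str, float]] = None,
    hs_fixed: Optional[Mapping[str, float]] = None,
) -> CutoffTable:
    """Build the per-structure cutoff table under the configured policy.

    ``pct80_of_reference``: GoldScore cutoffs from the 80% rule on the
    cocrystal ligands, hybrid cutoff the fixed value (default 15) for every
    structure. ``mean_of_dataset``: both cutoffs are dataset means per
    structure. ``fixed``: caller supplies explicit per-structure maps
    (``gs_fixed``/``hs_fixed``); the hybrid map defaults to the configured
    fixed hybrid cutoff, the GoldScore map to the 80% rule when references
    are given.
    """
    structures = config.structures
    if config.cutoff_policy is CutoffPolicy.PCT80_OF_REFERENCE:
        if references is None:
            raise DomainError("pct80_of_reference policy requires reference ligands")
        by_pdb = {r.receptor_pdb: r for r in references}
        gs = {pdb: float(derive_cutoff_pct80(by_pdb[pdb].goldscore)) for pdb in structures}
        hs = {pdb: float(config.hybrid_fixed_cutoff) for pdb in structures}
        return CutoffTable(gs_cutoff=gs, hs_cutoff=hs, policy=config.cutoff_policy)

    if config.cutoff_policy is CutoffPolicy.MEAN_OF_DATASET:
        agg = aggregate_all(matrix, config.pose_aggregation)
        gs = {}
        hs = {}
        for pdb in structures:
            col = agg.loc[agg["receptor_pdb"] == pdb]
            gs[pdb] = derive_cutoff_mean(col["score"].tolist())
            if weights is None:
                raise DomainError("mean_of_dataset hybrid cutoffs require weights")
            hybrids = [
                h
                for cid, s in zip(col["compound_id"], col["score"])
                if (h := hybrid_score(s, weights.get(cid, pdb))) is not None
            ]
            hs[pdb] = derive_cutoff_mean(hybrids)
        return CutoffTable(gs_cutoff=gs, hs_cutoff=hs, policy=config.cutoff_policy)

    # fixed
    hs = dict(hs_fixed) if hs_fixed is not None else {
        pdb: float(config.hybrid_fixed_cutoff) for pdb in structures
    }
    if gs_fixed is not None:
        gs = dict(gs_fixed)
    elif references is not None:
        gs = {r.receptor_pdb: float(derive_cutoff_pct80(r.goldscore)) for r in references}
    else:
        raise DomainError("fixed policy requires gs_fixed cutoffs or reference ligands")
    return CutoffTable(gs_cutoff=gs, hs_cutoff=hs, policy=CutoffPolicy.FIXED)


def classify_dataset(
    matrix: DockingScoreMatrix,
    weights: Optional[SimilarityWeights],
    cutoffs: CutoffTable,
    config: PipelineConfig,
) -> list[ConsensusCall]:
    """Per-structure calls plus consensus for every compound, both schemes.

    The GoldScore scheme never reads the similarity weights; when weights
    are absent entirely, only GoldScore calls are produced. A (compound,
    structure) pair with no poses — or no weight, for the hybrid scheme —
    yields a missing call which simply does not vote.
    """
    agg = aggregate_all(matrix, config.pose_aggregation)
    scores: dict[tuple[str, str], float] = {
        (r.compound_id, r.receptor_pdb): r.score for r in agg.itertuples()
    }
    schemes = [Scheme.GOLDSCORE] + ([Scheme.HYBRID] if weights is not None else [])
    calls: list[ConsensusCall] = []
    for cid in matrix.compound_ids:
        for scheme in schemes:
            per_structure: dict[str, Label] = {}
            for pdb in config.structures:
                s = scores.get((cid, pdb))
                if s is None:
                    per_structure[pdb] = Label.MISSING
                    continue
                if scheme is Scheme.GOLDSCORE:
                    eff = s
                else:
                    eff = hybrid_score(s, weights.get(cid, pdb))
                    if eff is None:
                        per_structure[pdb] = Label.MISSING
                        continue
                per_structure[pdb] = classify_structure(eff, cutoffs.for_scheme(scheme)[pdb])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                consensus = consensus_vote(per_structure, config.vote_threshold)
            calls.append(
                ConsensusCall(
                    compound_id=cid,
                    scheme=scheme,
                    per_structure_calls=per_structure,
                    consensus=consensus,
                )
            )
    return calls


def calls_to_frame(calls: Sequence[ConsensusCall]) -> pd.DataFrame:
    """Tidy view of consensus calls: one row per compound per scheme."""
    rows = []
    for c in calls:
        row = {"compound_id": c.compound_id, "scheme": c.scheme.value}
        for pdb, lab in c.per_structure_calls.items():
            row[f"call_{pdb}"] = lab.value
        row["consensus"] = c.consensus.value
        rows.append(row)
    return pd.DataFrame(rows)
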
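import math
import random

import pandas as pd
import pytest

from pxrdock import (
    Consensus,
    CutoffPolicy,
    CutoffTable,
    DockingScoreMatrix,
    GeneratorConfig,
    Label,
    PipelineConfig,
    PoseAggregation,
    PXR_STRUCTURES,
    Scheme,
    SimilarityWeights,
    generate_dataset,
)
from pxrdock.classify import (
    aggregate_poses,
    classify_dataset,
    classify_structure,
    consensus_vote,
    derive_cutoff_mean,
    derive_cutoff_pct80,
    derive_cutoffs,
    hybrid_score,
)
from pxrdock.datatypes import DomainError


def _matrix_from_poses(poses, compound="c", pdb="1M13"):
    rows = [
        {"compound_id": compound, "receptor_pdb": pdb, "pose_index": i + 1, "score": s}
        for i, s in enumerate(poses)
    ]
    return DockingScoreMatrix(pd.DataFrame(rows), structures=(pdb,))


class TestAggregatePoses:
    @pytest.mark.parametrize(
        "poses,mode,expected",
        [
            ([50, 62.3, 48], PoseAggregation.MAX, 62.3),
            ([41.7], PoseAggregation.MAX, 41.7),
            ([41.7], PoseAggregation.MEAN, 41.7),
            ([40, 60], PoseAggregation.MEAN, 50),
        ],
    )
    def test_reduction(self, poses, mode, expected):
        m = _matrix_from_poses(poses)
        assert aggregate_poses(m, "c", "1M13", mode) == pytest.approx(expected)

    def test_no_poses_is_missing(self):
        m = _matrix_from_poses([50.0])
        assert aggregate_poses(m, "c", "2QNV") is None


class TestHybridScore:
    @pytest.mark.parametrize("s,w,expected", [(50, 0.0, 0.0), (50, 1.0, 50.0), (60, 0.25, 15.0)])
    def test_product(self, s, w, expected):
        assert hybrid_score(s, w) == pytest.approx(expected)

    def test_negative_raw_score_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert hybrid_score(-3.0, 0.5) == 0.0

    def test_missing_weight_propagates(self):
        assert hybrid_score(50.0, None) is None


class TestCutoffs:
    def test_pct80_reproduces_published_sample_cutoffs(self, table1):
        refs, cutoffs = table1
        derived = {r.receptor_pdb: derive_cutoff_pct80(r.goldscore) for r in refs}
        assert derived == {k: int(v) for k, v in cutoffs["sample"].gs_cutoff.items()}

    @pytest.mark.parametrize("gs,expected", [(82.06, 66), (55.19, 44), (100, 80)])
    def test_pct80_rounding(self, gs, expected):
        assert derive_cutoff_pct80(gs) == expected

    def test_pct80_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            derive_cutoff_pct80(0)

    @pytest.mark.parametrize("scores,expected", [([40, 50, 60], 50.0), ([44], 44.0)])
    def test_mean_cutoff(self, scores, expected):
        assert derive_cutoff_mean(scores) == pytest.approx(expected)

    def test_mean_cutoff_matches_summation_oracle(self):
        rng = random.Random(7)
        scores = [rng.uniform(20, 90) for _ in range(1000)]
        assert derive_cutoff_mean(scores) == pytest.approx(math.fsum(scores) / 1000)

    def test_mean_cutoff_empty_is_domain_error(self):
        with pytest.raises(DomainError):
            derive_cutoff_mean([])

    def test_derive_cutoffs_pct80_policy(self, table1):
        refs, _ = table1
        config = PipelineConfig()
        matrix = _matrix_from_poses([50.0])
        table = derive_cutoffs(matrix, None, config, references=refs)
        assert table.gs_cutoff["1SKX"] == 52
        assert all(v == 15 for v in table.hs_cutoff.values())

    def test_derive_cutoffs_mean_policy(self, small_dataset):
        matrix, weights, _ = small_dataset
        config = PipelineConfig(cutoff_policy=CutoffPolicy.MEAN_OF_DATASET)
        table = derive_cutoffs(matrix, weights, config)
        # hand-check one structure against a direct mean of best poses
        best = [max(matrix.poses(c, "1M13")) for c in matrix.compound_ids]
        assert table.gs_cutoff["1M13"] == pytest.approx(sum(best) / len(best))


class TestPerStructureCall:
    @pytest.mark.parametrize(
        "score,cutoff,expected",
        [(66, 66, Label.AGONIST), (65.99, 66, Label.NONAGONIST), (80, 66, Label.AGONIST)],
    )
    def test_inclusive_boundary(self, score, cutoff, expected):
        assert classify_structure(score, cutoff) is expected


class TestConsensusVote:
    A, N, M = Label.AGONIST, Label.NONAGONIST, Label.MISSING

    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([A, A, A, N, N], Consensus.AGONIST),
            ([A, A, N, N, N], Consensus.NONAGONIST),
            ([A, A, M, M, M], Consensus.INDETERMINATE),
        ],
    )
    def test_three_of_five(self, labels, expected):
        calls = dict(zip(PXR_STRUCTURES, labels))
        assert consensus_vote(calls, threshold=3) is expected

    def test_all_missing_warns_indeterminate(self):
        calls = {pdb: self.M for pdb in PXR_STRUCTURES}
        with pytest.warns(UserWarning):
            assert consensus_vote(calls) is Consensus.INDETERMINATE

    def test_order_invariance(self):
        labels = [self.A, self.N, self.A, self.N, self.A]
        forward = consensus_vote(dict(zip(PXR_STRUCTURES, labels)))
        backward = consensus_vote(dict(zip(reversed(PXR_STRUCTURES), labels)))
        assert forward is backward


def brute_force_classify(matrix, weights, cutoffs, config):
    """Independent per-compound loop used as the oracle for classify_dataset."""
    out = {}
    for cid in matrix.compound_ids:
        for scheme in (Scheme.GOLDSCORE, Scheme.HYBRID):
            n_a = n_n = n_present = 0
            for pdb in config.structures:
                poses = matrix.poses(cid, pdb)
                if not poses:
                    continue
                s = max(poses) if config.pose_aggregation is PoseAggregation.MAX \
                    else sum(poses) / len(poses)
                if scheme is Scheme.HYBRID:
                    w = weights.get(cid, pdb)
                    if w is None:
                        continue
                    s = w * s
                n_present += 1
                if s >= cutoffs.for_scheme(scheme)[pdb]:
                    n_a += 1
                else:
                    n_n += 1
            if n_a >= config.vote_threshold:
                out[(cid, scheme)] = Consensus.AGONIST
            elif n_n >= config.vote_threshold:
                out[(cid, scheme)] = Consensus.NONAGONIST
            else:
                out[(cid, scheme)] = Consensus.INDETERMINATE
    return out


class TestClassifyDataset:
    def test_matches_brute_force_oracle(self):
        config_gen = GeneratorConfig(n_agonists=50, n_nonagonists=50, rng_seed=11)
        matrix, weights, _ = generate_dataset(config_gen)
        config = PipelineConfig(cutoff_policy=CutoffPolicy.MEAN_OF_DATASET)
        cutoffs = derive_cutoffs(matrix, weights, config)
        calls = classify_dataset(matrix, weights, cutoffs, config)
        expected = brute_force_classify(matrix, weights, cutoffs, config)
        assert len(calls) == 200  # 100 compounds x 2 schemes
        for c in calls:
            assert c.consensus is expected[(c.compound_id, c.scheme)]

    def test_all_zero_weights_give_hybrid_nonagonist(self, tiny_matrix):
        weights = SimilarityWeights(
            {(c, pdb): 0.0 for c in ("c1", "c2") for pdb in PXR_STRUCTURES}
        )
        cutoffs = CutoffTable(
            gs_cutoff={pdb: 30.0 for pdb in PXR_STRUCTURES},
            hs_cutoff={pdb: 15.0 for pdb in PXR_STRUCTURES},
            policy=CutoffPolicy.FIXED,
        )
        calls = classify_dataset(tiny_matrix, weights, cutoffs, PipelineConfig())
        hybrid = [c for c in calls if c.scheme is Scheme.HYBRID]
        assert all(c.consensus is Consensus.NONAGONIST for c in hybrid)

    def test_goldscore_scheme_ignores_weights(self, small_dataset):
        matrix, weights, _ = small_dataset
        config = PipelineConfig(cutoff_policy=CutoffPolicy.MEAN_OF_DATASET)
        cutoffs = derive_cutoffs(matrix, weights, config)
        with_w = classify_dataset(matrix, weights, cutoffs, config)
        without_w = classify_dataset(matrix, None, cutoffs, config)
        gs_with = {c.compound_id: c.consensus for c in with_w if c.scheme is Scheme.GOLDSCORE}
        gs_without = {c.compound_id: c.consensus for c in without_w}
        assert gs_with == gs_without

    def test_raising_a_score_never_demotes(self, tiny_matrix):
        cutoffs = CutoffTable(
            gs_cutoff={pdb: 36.0 for pdb in PXR_STRUCTURES},
            hs_cutoff={pdb: 15.0 for pdb in PXR_STRUCTURES},
            policy=CutoffPolicy.FIXED,
        )
        config = PipelineConfig()
        base = classify_dataset(tiny_matrix, None, cutoffs, config)
        base_cons = {c.compound_id: c.consensus for c in base}
        rank = {Consensus.NONAGONIST: 0, Consensus.INDETERMINATE: 1, Consensus.AGONIST: 2}
        for i in range(len(tiny_matrix.frame)):
            bumped = tiny_matrix.frame.copy()
            bumped.loc[i, "score"] += 25.0
            calls = classify_dataset(DockingScoreMatrix(bumped), None, cutoffs, config)
            for c in calls:
                assert rank[c.consensus] >= rank[base_cons[c.compound_id]]
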
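# Methods

## The classification model

The package treats docking output as opaque numbers: for compound *i*,
receptor structure *k* ∈ {1M13, 1NRL, 1SKX, 2O9I, 2QNV}, and pose *j*, a
score s<sub>ijk</sub> (higher is better, GoldScore-like scale ≈ 20–90 for
plausible binders). The chain is

    pose aggregation → (optional) similarity weighting → per-structure
    threshold call → 3-of-5 majority vote → confusion statistics.

**Pose aggregation.** Default is the maximum over a compound's poses per
structure, matching the genetic-algorithm docking convention of keeping the
best-scored solution; an arithmetic-mean mode is provided. A pair with no
poses yields a *missing* call that simply does not vote.

**Hybrid score.** S = w·s with w the Tanimoto coefficient between the
compound's 2D fingerprint and that of the structure's own cocrystallized
ligand — per-structure pairing, never a maximum over references. The
product form is used: with raw scores of ~40–80 and typical Tanimoto
weights well below 1, it is the only simple form consistent with hybrid
cutoffs in the low teens. Negative raw scores are clamped to 0 with a
warning (they carry no binding signal); a missing weight (compound without
a structure) propagates as a missing call.

**Fingerprints.** The public 166-key MACCS dictionary as implemented in
RDKit, recorded as `maccs-166` in every `Fingerprint` so caches from other
key sets cannot be mixed. Salts/mixtures are reduced to the largest
covalent fragment before keying (standard practice). Two empty fingerprints
compare as similarity 0, not NaN, so downstream hybrid scores stay defined.
Fingerprints from different toolkits or key-set versions can differ in a
few keys; for strict reproducibility the weights CSV produced by one run
can be fed back instead of recomputing.

**Cutoff policies.** Three are supported, all per structure:

| policy | GoldScore cutoff | hybrid cutoff |
|---|---|---|
| `pct80_of_reference` | nearest-integer of 0.8 × cocrystal ligand's score | fixed value (default 15) |
| `mean_of_dataset` | mean of aggregated scores over the dataset | mean of hybrid scores |
| `fixed` | caller-supplied map | caller-supplied map |

Rounding in the 80% rule is nearest integer, half away from zero — this
reproduces all five published sample-set cutoffs (66, 39, 52, 39, 44)
exactly. The dataset-mean policy averages over *all* compounds in the
dataset; averaging over flagged actives only is possible by calling
`derive_cutoff_mean` on a filtered column, but nothing in the package
asserts which variant produced the published full-library cutoff table,
which is ambiguous on this point and is therefore shipped verbatim as a
fixture rather than re-derived.

**Boundary rule.** A score exactly at the cutoff counts as agonist (≥).
Cutoffs were rounded down from 80% values in two of five structures, and an
inclusive rule keeps a reference ligand scored at its own rounded cutoff
classified active.

**Consensus.** Agonist iff ≥ `vote_threshold` (default 3) of the structure
calls are agonist; nonagonist iff ≥ threshold are nonagonist; otherwise
indeterminate, which with five structures and threshold 3 can only occur
when calls are missing. The vote is order-invariant and monotone: raising
any single score can never demote a consensus from agonist toward
nonagonist (property-tested).

**Evaluation.** SE, SP, Q on the 0–100 scale and the Matthews coefficient
from the standard formula; any statistic with a zero denominator is
reported as undefined (`None`) with a warning rather than silently 0 or
NaN. Compounds whose truth label is missing — and predictions that are
themselves indeterminate — are excluded and counted in
`n_excluded_missing`; an alternative `count_as_negative` policy scores
unlabeled compounds as experimental negatives. The exclude default is what
makes the 28-compound sample set evaluate over n = 27 (one compound has no
reporter-assay record), which is the denominator behind the published
specificity 7/15 and accuracy 15/27. Note 100·15/27 = 55.56 while the
published table prints 55.55 — that table mixes truncation and rounding;
statistics here are printed rounded at two decimals. One published
full-library row (GoldScore SP/Q/C) is arithmetically inconsistent with its
own printed counts (120 correct of 246 nonagonists is 48.78, not 51.22);
the package reports the arithmetic truth and does not attempt to match
those three cells.

**Potency classes.** strong: EC50 ≤ 10 µM; medium: 10 < EC50 ≤ 50 µM; weak:
EC50 > 50 µM with relative efficacy ≥ 0.10 of 10 µM rifampicin; otherwise
nonagonist (including a missing EC50, or a high EC50 without efficacy
evidence). The printed class definitions leave a gap between "<10" and
"11–50"; the boundary is closed at 10 µM so the rule is total — no
published compound falls in the gap. Censored entries like "> 50" are
stored with a missing numeric EC50 and the printed class letter retained.

## Fixtures

Two reference tables are transcribed into `pxrdock.fixtures`: the five
cocrystallized ligands (HYF/SRL/RFP/444/CDZ) with their GoldScores and both
cutoff sets, and the 28-compound sample set (docking consensus, external
Bayesian-classifier score, reporter-assay class with EC50s, efficacy and
viability). Conventions: "X" = assayed, no measurable activity (class
nonagonist); "–" = no data (class missing). Compound names are normalized
to lower-case slugs for joining, since the tables join by name only.
Reference-ligand SMILES are not part of the published record and are left
unset; the external Bayesian classifier's threshold (−5.792) is carried as
metadata only — that model is not reimplemented.

## Synthetic data generator

`GeneratorConfig` draws, per compound and structure, a best-pose score from
a class-conditional normal truncated at 0, then constructs the remaining
poses as the best pose minus folded-normal jitter with the best pose placed
at a random pose index — so max-aggregation recovers the drawn score
exactly, decoupling generator calibration from the aggregation choice.
Similarity weights are i.i.d. Beta(2, 5) (mean ≈ 0.29, the magnitude of
typical MACCS Tanimoto values between diverse chemicals and a few reference
ligands). Defaults: 20 poses, score sd 8, nonagonist means 36–42 and
agonist means 55–65 across the five structures, sized to the published
score regime so that dataset-mean and 80%-rule cutoffs land in the
published cutoff range (roughly 39–66).

What the generator does *not* emulate: correlation between similarity and
activity (weights are classless noise, so the hybrid scheme is
systematically handicapped on synthetic data), inter-structure score
correlation for a given compound, heavy tails or multimodality of real
docking scores, and any pose geometry. Passing recovery tests therefore
demonstrate that the classification chain is correct and well-calibrated
given separable score distributions — not that docking scores separate
real agonists from nonagonists.

## Simulation experiment sizes

The recovery experiments used in the tests run the full pipeline
(generate → dataset-mean cutoffs → classify → evaluate): the null check
uses 20 seeds at 250 + 250 compounds with zero class separation (expected
|MCC| ≈ 1/√500 per seed); the high-separation check uses 500 + 500
compounds at 4 sd separation, where the per-structure error rate is
Φ(−2) ≈ 0.023 and the 3-of-5 vote drives the consensus error below 10⁻³;
the monotonicity check averages sensitivity over 20 seeds at each of three
separations (0, 2, 4 sd) with 150 + 150 compounds. These sizes make the
statistical margins wide relative to seed noise while each experiment
completes in well under a second.

## Numerical and degenerate-input choices

- Duplicate (compound, structure, pose) rows are a schema error, never
  averaged away; readers report rejected records with line numbers so
  records in + records rejected = records read.
- Tabular interchange is comma-separated UTF-8 with headers; score CSVs
  round-trip bit-identically (`float_precision="round_trip"` on read).
- MCC is computed in float from integer counts; confusion counts are exact.
- Classification is fully deterministic given inputs and config; the run
  manifest (JSON: config, seed, SHA-256 input digests) makes stochastic
  *generation* runs reproducible.

## Known limitations

- No docking is performed; the package starts from a score table.
- The hybrid scheme requires compound structures; compounds without SMILES
  fall back to GoldScore-only calls (hybrid calls go missing).
- Statistics carry no confidence intervals (none are defined for the
  published comparisons); for planning purposes use the simulation module.
- MACCS keys computed by different toolkits can disagree slightly; weights
  are therefore cacheable to CSV and the key-dictionary id travels with
  every fingerprint.
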
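"""Confusion-matrix evaluation against experimental labels and EC50 potency
classes.

Predictions are compared with the reporter-assay truth labels compound by
compound; the four standard virtual-screening statistics are reported:
sensitivity SE = 100·TP/(TP+FN), specificity SP = 100·TN/(TN+FP), overall
prediction accuracy Q = 100·(TP+TN)/N, and the Matthews correlation
coefficient C. Compounds without a truth label are excluded from the
denominators by default.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .datatypes import (
    AssayRecord,
    Consensus,
    ConsensusCall,
    DomainError,
    Label,
    MissingLabelPolicy,
    PipelineConfig,
    Scheme,
)


class PotencyClass(str, enum.Enum):
    STRONG = "strong"
    MEDIUM = "medium"
    WEAK = "weak"
    NONAGONIST = "nonagonist"


@dataclass(frozen=True)
class ConfusionStats:
    """Confusion counts and the derived statistics for one scheme.

    A statistic whose denominator is zero is ``None`` (undefined); the
    others are still computed. Percent statistics are on the 0–100 scale.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded_missing: int = 0

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def accuracy_q(self) -> Optional[float]:
        return 100.0 * (self.tp + self.tn) / self.n_evaluated if self.n_evaluated else None

    @property
    def mcc_value(self) -> Optional[float]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mcc(self.tp, self.fp, self.tn, self.fn)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "SE": self.sensitivity, "SP": self.specificity,
            "Q": self.accuracy_q, "C": self.mcc_value,
            "n_evaluated": self.n_evaluated,
            "n_excluded_missing": self.n_excluded_missing,
        }


def mcc(tp: int, fp: int, tn: int, fn: int) -> Optional[float]:
    """Matthews correlation coefficient.

    (tp·tn − fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); when any marginal
    is zero the coefficient is undefined and ``None`` is returned with a
    warning.
    """
    if min(tp, fp, tn, fn) < 0:
        raise DomainError("confusion counts must be non-negative")
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        warnings.warn("MCC undefined: a confusion-matrix marginal is zero", stacklevel=2)
        return None
    return (tp * tn - fp * fn) / math.sqrt(denom2)


def confusion(
    predicted: Mapping[str, Consensus | Label | str],
    truth: Mapping[str, Label | str],
    policy: MissingLabelPolicy = MissingLabelPolicy.EXCLUDE,
) -> ConfusionStats:
    """Confusion counts of predicted vs experimental labels.

    Compounds present in ``predicted`` but with a missing truth label are
    excluded (counted in ``n_excluded_missing``) under the default policy,
    or scored as experimental negatives under ``count_as_negative``.
    Predictions that are themselves indeterminate or missing are excluded
    the same way. Only compounds present in both maps are evaluated.
    """
    tp = fp = tn = fn = 0
    excluded = 0
    common = [cid for cid in predicted if cid in truth]
    if not common:
        raise DomainError("no compounds shared between predictions and truth labels")
    for cid in common:
        pred = _as_binary(predicted[cid])
        true = _as_binary(truth[cid])
        if true is None:
            if policy is MissingLabelPolicy.COUNT_AS_NEGATIVE:
                true = False
            else:
                excluded += 1
                continue
        if pred is None:
            excluded += 1
            continue
        if true and pred:
            tp += 1
        elif true and not pred:
            fn += 1
        elif not true and pred:
            fp += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise DomainError("no evaluable compounds after missing-label handling")
    return ConfusionStats(tp=tp, fp=fp, tn=tn, fn=fn, n_excluded_missing=excluded)


def _as_binary(label) -> Optional[bool]:
    """True for agonist, False for nonagonist, None for anything missing."""
    v = label.value if isinstance(label, enum.Enum) else str(label)
    if v == "agonist":
        return True
    if v == "nonagonist":
        return False
    return None


def potency_class(
    ec50_uM: Optional[float],
    efficacy_rel: Optional[float] = None,
) -> PotencyClass:
    """EC50 potency class of an agonist.

    strong: EC50 ≤ 10 µM; medium: 10 < EC50 ≤ 50 µM; weak: EC50 > 50 µM with
    at least 10% of the efficacy of 10 µM rifampicin; anything else
    (including a missing EC50) is a nonagonist.
    """
    if ec50_uM is None:
        return PotencyClass.NONAGONIST
    if ec50_uM <= 0:
        raise DomainError(f"EC50 must be positive: {ec50_uM}")
    if ec50_uM <= 10:
        return PotencyClass.STRONG
    if ec50_uM <= 50:
        return PotencyClass.MEDIUM
    if efficacy_rel is not None and efficacy_rel >= 0.10:
        return PotencyClass.WEAK
    return PotencyClass.NONAGONIST


def evaluate_report(
    calls: Sequence[ConsensusCall],
    assays: Sequence[AssayRecord],
    config: PipelineConfig = PipelineConfig(),
) -> dict[Scheme, ConfusionStats]:
    """Per-scheme confusion statistics of consensus calls against the
    reporter-assay truth labels.

    Schemes with no calls are omitted with a warning. Use
    :func:`summary_frame` for the tabular report.
    """
    truth = {a.compound_id: a.ncgc_class for a in assays}
    out: dict[Scheme, ConfusionStats] = {}
    for scheme in Scheme:
        preds = {c.compound_id: c.consensus for c in calls if c.scheme is scheme}
        if not preds:
            warnings.warn(f"no calls for scheme {scheme.value}; omitted", stacklevel=2)
            continue
        out[scheme] = confusion(preds, truth, config.missing_label_policy)
    return out


def summary_frame(stats: Mapping[Scheme, ConfusionStats]) -> pd.DataFrame:
    """One row per scheme: counts and SE/SP/Q/C at two decimals."""
    rows = []
    for scheme, s in stats.items():
        d = s.as_dict()
        for k in ("SE", "SP", "Q", "C"):
            d[k] = None if d[k] is None else round(d[k], 2)
        rows.append({"scheme": scheme.value, **d})
    return pd.DataFrame(rows)
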
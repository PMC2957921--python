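"""Core data structures for the consensus-docking classification pipeline.

The pipeline works on four kinds of objects: compounds (with optional
structures), per-pose docking scores for each compound against each of the
five PXR crystal structures, reference (cocrystallized) ligands anchoring the
cutoff rules, and experimental activity records used as truth labels.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

#: The five human PXR crystal structures used throughout.
PXR_STRUCTURES = ("1M13", "1NRL", "1SKX", "2O9I", "2QNV")

SCORE_COLUMNS = ("compound_id", "receptor_pdb", "pose_index", "score")


class PxrdockError(Exception):
    """Base class for pipeline errors."""


class SchemaError(PxrdockError):
    """A tabular input does not have the expected columns or keys."""


class ParseError(PxrdockError):
    """A value in an input could not be parsed."""


class ChemistryError(PxrdockError):
    """A molecular structure could not be interpreted."""


class DomainError(PxrdockError):
    """An argument is outside the domain of the operation."""


def slugify(name: str) -> str:
    """Normalize a compound name to a lower-case slug for joining tables.

    Accents are stripped, Greek letters spelled out, and runs of
    non-alphanumeric characters collapsed to single hyphens, so that e.g.
    ``"α-Cypermethrin"`` and ``"alpha cypermethrin"`` join.
    """
    s = name.strip().lower()
    s = s.replace("α", "alpha").replace("β", "beta").replace("γ", "gamma")
    s = unicodedata.normalize("NFKD", s)
    s = "".join(c for c in s if not unicodedata.combining(c))
    s = re.sub(r"[^a-z0-9]+", "-", s)
    return s.strip("-")


class Source(str, enum.Enum):
    TOXCAST = "toxcast"
    LITERATURE = "literature"
    SYNTHETIC = "synthetic"


class Label(str, enum.Enum):
    """Binary activity call; MISSING marks an unavailable call or label."""

    AGONIST = "agonist"
    NONAGONIST = "nonagonist"
    MISSING = "missing"


class Consensus(str, enum.Enum):
    AGONIST = "agonist"
    NONAGONIST = "nonagonist"
    INDETERMINATE = "indeterminate"


class Scheme(str, enum.Enum):
    GOLDSCORE = "goldscore"
    HYBRID = "hybrid"


class CutoffPolicy(str, enum.Enum):
    PCT80_OF_REFERENCE = "pct80_of_reference"
    MEAN_OF_DATASET = "mean_of_dataset"
    FIXED = "fixed"


class PoseAggregation(str, enum.Enum):
    MAX = "max"
    MEAN = "mean"


class MissingLabelPolicy(str, enum.Enum):
    EXCLUDE = "exclude"
    COUNT_AS_NEGATIVE = "count_as_negative"


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str = ""
    structure: Optional[str] = None  # SMILES
    source: Source = Source.TOXCAST


@dataclass(frozen=True)
class ReferenceLigand:
    """A cocrystallized ligand with its own docking score.

    The ligand's GoldScore anchors the 80%-of-reference cutoff rule for its
    receptor structure.
    """

    receptor_pdb: str
    ligand_code: str
    goldscore: float
    structure: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.receptor_pdb) != 4:
            raise DomainError(f"PDB code must be 4 characters: {self.receptor_pdb!r}")
        if len(self.ligand_code) != 3:
            raise DomainError(f"ligand code must be 3 characters: {self.ligand_code!r}")
        if self.goldscore <= 0:
            raise DomainError(f"reference goldscore must be positive: {self.goldscore}")


@dataclass(frozen=True)
class AssayRecord:
    """Experimental activity for one compound.

    ``ncgc_class`` is the high-throughput reporter-assay call used as the
    truth label; the EC50/efficacy/viability fields carry the quantitative
    assay results reported alongside it. ``None`` means not measured /
    missing; where an assay reported "no measurable activity" the class
    fields say so but the numeric fields stay ``None``.
    """

    compound_id: str
    ncgc_class: Label = Label.MISSING
    ncgc_ec50_uM: Optional[float] = None
    hepg2_ec50_uM: Optional[float] = None
    hepg2_class: Optional[str] = None  # printed letter: S/M/W or X
    efficacy_rel_rifampicin: Optional[float] = None
    dpx2_ec50_uM: Optional[float] = None
    dpx2_class: Optional[str] = None
    viability_ic50_uM: Optional[float] = None

    def __post_init__(self) -> None:
        for f in ("ncgc_ec50_uM", "hepg2_ec50_uM", "dpx2_ec50_uM"):
            v = getattr(self, f)
            if v is not None and v <= 0:
                raise DomainError(f"{f} must be positive, got {v}")


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the classification pipeline.

    Defaults reproduce the published analysis of the 28-compound sample set:
    per-structure GoldScore cutoffs at 80% of the cocrystal ligand's score,
    a single fixed hybrid-score cutoff of 15, best-of-20-poses aggregation,
    and a 3-of-5 majority vote.
    """

    cutoff_policy: CutoffPolicy = CutoffPolicy.PCT80_OF_REFERENCE
    hybrid_fixed_cutoff: float = 15.0
    pose_aggregation: PoseAggregation = PoseAggregation.MAX
    vote_threshold: int = 3
    missing_label_policy: MissingLabelPolicy = MissingLabelPolicy.EXCLUDE
    rng_seed: int = 0
    structures: tuple[str, ...] = PXR_STRUCTURES

    def __post_init__(self) -> None:
        if not (1 <= self.vote_threshold <= len(self.structures)):
            raise DomainError(
                f"vote_threshold must be in [1, {len(self.structures)}], "
                f"got {self.vote_threshold}"
            )
        if self.hybrid_fixed_cutoff <= 0:
            raise DomainError("hybrid_fixed_cutoff must be positive")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


class DockingScoreMatrix:
    """Per-pose docking scores keyed by (compound, receptor structure, pose).

    Thin wrapper over a tidy DataFrame with columns ``compound_id``,
    ``receptor_pdb``, ``pose_index``, ``score``. Duplicate keys are rejected
    at construction; a (compound, structure) pair absent from the table is
    treated as explicitly missing downstream.
    """

    def __init__(self, frame: pd.DataFrame, structures: Iterable[str] = PXR_STRUCTURES):
        missing_cols = set(SCORE_COLUMNS) - set(frame.columns)
        if missing_cols:
            raise SchemaError(f"score table missing columns: {sorted(missing_cols)}")
        frame = frame.loc[:, list(SCORE_COLUMNS)].copy()
        frame["score"] = pd.to_numeric(frame["score"], errors="raise")
        frame["pose_index"] = frame["pose_index"].astype(int)
        dup = frame.duplicated(subset=["compound_id", "receptor_pdb", "pose_index"])
        if dup.any():
            bad = frame.loc[dup, ["compound_id", "receptor_pdb", "pose_index"]].iloc[0]
            raise SchemaError(
                "duplicate (compound, structure, pose) row: "
                f"({bad.compound_id}, {bad.receptor_pdb}, {bad.pose_index})"
            )
        if (frame["pose_index"] < 1).any():
            raise DomainError("pose_index must be >= 1")
        self.frame = frame.reset_index(drop=True)
        self.structures = tuple(structures)

    @property
    def compound_ids(self) -> list[str]:
        return list(pd.unique(self.frame["compound_id"]))

    def poses(self, compound_id: str, receptor_pdb: str) -> list[float]:
        sel = self.frame[
            (self.frame["compound_id"] == compound_id)
            & (self.frame["receptor_pdb"] == receptor_pdb)
        ]
        return sel.sort_values("pose_index")["score"].tolist()

    def missing_pairs(self) -> list[tuple[str, str]]:
        """(compound, structure) pairs with no pose scores at all."""
        have = set(map(tuple, self.frame[["compound_id", "receptor_pdb"]].drop_duplicates().values))
        return [
            (c, s)
            for c in self.compound_ids
            for s in self.structures
            if (c, s) not in have
        ]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DockingScoreMatrix):
            return NotImplemented
        a = self.frame.sort_values(list(SCORE_COLUMNS)).reset_index(drop=True)
        b = other.frame.sort_values(list(SCORE_COLUMNS)).reset_index(drop=True)
        return a.equals(b)


@dataclass
class SimilarityWeights:
    """Tanimoto weights w in [0, 1], one per (compound, reference structure)."""

    weights: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, w in self.weights.items():
            if w is not None and not (0.0 <= w <= 1.0):
                raise DomainError(f"weight out of [0,1] for {key}: {w}")

    def get(self, compound_id: str, receptor_pdb: str) -> Optional[float]:
        return self.weights.get((compound_id, receptor_pdb))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"compound_id": c, "receptor_pdb": s, "weight": w}
            for (c, s), w in self.weights.items()
        ]
        return pd.DataFrame(rows, columns=["compound_id", "receptor_pdb", "weight"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SimilarityWeights":
        need = {"compound_id", "receptor_pdb", "weight"}
        if not need <= set(frame.columns):
            raise SchemaError(f"weights table missing columns: {sorted(need - set(frame.columns))}")
        weights = {
            (r.compound_id, r.receptor_pdb): (None if pd.isna(r.weight) else float(r.weight))
            for r in frame.itertuples()
        }
        return cls(weights)


@dataclass(frozen=True)
class CutoffTable:
    """Per-structure classification thresholds for both scoring schemes."""

    gs_cutoff: Mapping[str, float]
    hs_cutoff: Mapping[str, float]
    policy: CutoffPolicy

    def __post_init__(self) -> None:
        if set(self.gs_cutoff) != set(self.hs_cutoff):
            raise DomainError("gs and hs cutoffs must cover the same structures")
        for table in (self.gs_cutoff, self.hs_cutoff):
            for pdb, c in table.items():
                if c <= 0:
                    raise DomainError(f"cutoff must be positive for {pdb}: {c}")

    @property
    def structures(self) -> tuple[str, ...]:
        return tuple(self.gs_cutoff)

    def for_scheme(self, scheme: Scheme) -> Mapping[str, float]:
        return self.gs_cutoff if scheme is Scheme.GOLDSCORE else self.hs_cutoff


@dataclass(frozen=True)
class ConsensusCall:
    """Per-structure calls and the majority-vote consensus for one compound."""

    compound_id: str
    scheme: Scheme
    per_structure_calls: Mapping[str, Label]
    consensus: Consensus

    def n_calls(self, label: Label) -> int:
        return sum(1 for v in self.per_structure_calls.values() if v is label)
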
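"""Readers and writers for compounds, score tables, weights, and run
manifests.

Tabular interchange is comma-separated UTF-8 with a header row. Readers
never drop records silently: unparseable entries are collected with their
line numbers and reported through logging and the returned rejection list.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from rdkit import Chem, RDLogger

from .datatypes import (
    CompoundRecord,
    DockingScoreMatrix,
    ParseError,
    PipelineConfig,
    SCORE_COLUMNS,
    SchemaError,
    SimilarityWeights,
    Source,
    slugify,
)

logger = logging.getLogger("pxrdock")


@dataclass(frozen=True)
class Rejection:
    """A record that could not be parsed, with its location and reason."""

    line: int
    text: str
    reason: str


def read_compounds(
    path: Union[str, Path],
    format: str = "smiles",
    source: Source = Source.TOXCAST,
) -> tuple[list[CompoundRecord], list[Rejection]]:
    """Read compounds from a SMILES file, an SDF, or a CSV.

    SMILES files are one molecule per line, optionally followed by
    whitespace and an identifier; SDF identifiers come from the title field
    (falling back to a positional id); CSV needs ``compound_id`` and
    optional ``name``/``smiles`` columns. Returns the parsed records plus
    the rejections — callers decide whether a partial read is acceptable.

    Raises
    ------
    OSError        if the file cannot be read.
    ParseError     if no record parses at all.
    SchemaError    for a CSV lacking the required column.
    """
    path = Path(path)
    records: list[CompoundRecord] = []
    rejections: list[Rejection] = []

    RDLogger.DisableLog("rdApp.error")
    try:
        if format == "smiles":
            with open(path, encoding="utf-8") as fh:
                for lineno, raw in enumerate(fh, start=1):
                    line = raw.strip()
                    if not line or line.startswith("#"):
                        continue
                    parts = line.split(None, 1)
                    smi = parts[0]
                    name = parts[1].strip() if len(parts) > 1 else smi
                    if Chem.MolFromSmiles(smi) is None:
                        rejections.append(Rejection(lineno, line, "unparseable SMILES"))
                        continue
                    cid = slugify(name) if len(parts) > 1 else f"cmpd{lineno:05d}"
                    records.append(CompoundRecord(cid, name=name, structure=smi, source=source))
        elif format == "sdf":
            supplier = Chem.SDMolSupplier(str(path), sanitize=True)
            for idx, mol in enumerate(supplier, start=1):
                if mol is None:
                    rejections.append(Rejection(idx, f"molecule #{idx}", "unparseable SDF entry"))
                    continue
                title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
                cid = slugify(title) if title else f"cmpd{idx:05d}"
                records.append(
                    CompoundRecord(cid, name=title or cid, structure=Chem.MolToSmiles(mol),
                                   source=source)
                )
        elif format == "csv":
            frame = pd.read_csv(path, dtype=str)
            if "compound_id" not in frame.columns:
                raise SchemaError("compound CSV must have a compound_id column")
            for idx, row in enumerate(frame.itertuples(), start=2):
                smi = getattr(row, "smiles", None)
                smi = None if (smi is None or pd.isna(smi)) else str(smi)
                if smi is not None and Chem.MolFromSmiles(smi) is None:
                    rejections.append(Rejection(idx, smi, "unparseable SMILES"))
                    continue
                name = getattr(row, "name", row.compound_id)
                name = row.compound_id if pd.isna(name) else str(name)
                records.append(
                    CompoundRecord(str(row.compound_id), name=name, structure=smi, source=source)
                )
        else:
            raise ValueError(f"unknown compound format: {format!r}")
    finally:
        RDLogger.EnableLog("rdApp.error")

    for rej in rejections:
        logger.warning("rejected record at line %d: %s (%s)", rej.line, rej.text, rej.reason)
    if not records:
        raise ParseError(f"no parseable records in {path}")
    return records, rejections


def read_score_table(path: Union[str, Path]) -> DockingScoreMatrix:
    """Read a per-pose docking score table (CSV with compound_id,
    receptor_pdb, pose_index, score columns)."""
    frame = pd.read_csv(
        path,
        dtype={"compound_id": str, "receptor_pdb": str},
        float_precision="round_trip",
    )
    missing = set(SCORE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"score table {path} missing columns: {sorted(missing)}")
    bad = pd.to_numeric(frame["score"], errors="coerce").isna() & frame["score"].notna()
    if bad.any() or frame["score"].isna().any():
        rows = frame.index[bad | frame["score"].isna()].tolist()
        raise ParseError(f"non-numeric score in {path} at data row(s) {rows}")
    structures = tuple(pd.unique(frame["receptor_pdb"]))
    return DockingScoreMatrix(frame, structures=structures)


def write_score_table(matrix: DockingScoreMatrix, path: Union[str, Path]) -> None:
    frame = matrix.frame.sort_values(list(SCORE_COLUMNS)).reset_index(drop=True)
    frame.to_csv(path, index=False)


def write_weights(weights: SimilarityWeights, path: Union[str, Path]) -> None:
    weights.to_frame().sort_values(["compound_id", "receptor_pdb"]).to_csv(path, index=False)


def read_weights(path: Union[str, Path]) -> SimilarityWeights:
    return SimilarityWeights.from_frame(
        pd.read_csv(path, dtype={"compound_id": str}, float_precision="round_trip")
    )


def file_digest(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path: Union[str, Path],
    config: PipelineConfig,
    inputs: Sequence[Union[str, Path]] = (),
    extra: Optional[dict] = None,
) -> None:
    """Machine-readable run manifest: config, seed, and input digests."""
    manifest = {
        "config": {k: getattr(v, "value", v) for k, v in asdict(config).items()},
        "inputs": {str(p): file_digest(p) for p in inputs},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str), encoding="utf-8")
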
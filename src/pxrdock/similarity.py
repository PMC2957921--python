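"""2D fingerprint similarity of test compounds to the cocrystallized ligands.

Fingerprints use the public 166-key MACCS dictionary as implemented by RDKit;
the Tanimoto coefficient on the key sets gives the weight w_i in [0, 1] used
by the hybrid scoring scheme. Each compound is weighted against the
cocrystal ligand of each receptor structure separately (never a max over
references).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .datatypes import (
    ChemistryError,
    CompoundRecord,
    PxrdockError,
    ReferenceLigand,
    SimilarityWeights,
)

#: Identifier of the key dictionary; recorded so cached fingerprints from a
#: different key set are never mixed.
MACCS_166 = "maccs-166"


class IncompatibleFingerprints(PxrdockError):
    """Fingerprints built from different key dictionaries."""


@dataclass(frozen=True)
class Fingerprint:
    """A set of on-bits from a fixed public 2D key dictionary."""

    bits: frozenset[int]
    key_dictionary_id: str = MACCS_166

    def __post_init__(self) -> None:
        if self.key_dictionary_id == MACCS_166 and self.bits:
            if min(self.bits) < 1 or max(self.bits) > 166:
                raise PxrdockError("MACCS bit index outside [1, 166]")

    def __len__(self) -> int:
        return len(self.bits)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest covalent fragment (drops salts/counterions)."""
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def fingerprint(structure: str) -> Fingerprint:
    """MACCS-166 fingerprint of a SMILES string.

    Deterministic up to canonicalization: any SMILES of the same molecule
    yields the same bit set. Salts and mixtures are reduced to the largest
    covalent fragment first. The empty molecule gives an empty bit set.

    Raises
    ------
    ChemistryError
        If the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ChemistryError(f"unparseable structure: {structure!r}")
    mol = _largest_fragment(mol)
    fp = MACCSkeys.GenMACCSKeys(mol)
    # RDKit allocates 167 bits with bit 0 unused; on-bits are already 1-based.
    return Fingerprint(bits=frozenset(fp.GetOnBits()))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| in [0, 1].

    Two empty fingerprints compare as 0 (dissimilar) with a warning, keeping
    downstream hybrid scores defined.
    """
    if a.key_dictionary_id != b.key_dictionary_id:
        raise IncompatibleFingerprints(
            f"key dictionaries differ: {a.key_dictionary_id} vs {b.key_dictionary_id}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 0", stacklevel=2)
        return 0.0
    return len(a.bits & b.bits) / union


def similarity_weights(
    compounds: Sequence[CompoundRecord],
    references: Sequence[ReferenceLigand],
) -> SimilarityWeights:
    """Tanimoto weight of every compound against every reference ligand.

    A compound without a structure gets ``None`` for all its weights (the
    hybrid scheme is then inapplicable for it); a reference without a
    structure cannot contribute weights and raises.
    """
    ref_fps: dict[str, Fingerprint] = {}
    for ref in references:
        if ref.structure is None:
            raise ChemistryError(
                f"reference ligand {ref.ligand_code} ({ref.receptor_pdb}) has no structure"
            )
        ref_fps[ref.receptor_pdb] = fingerprint(ref.structure)

    weights: dict[tuple[str, str], Optional[float]] = {}
    for comp in compounds:
        fp = fingerprint(comp.structure) if comp.structure is not None else None
        for pdb, ref_fp in ref_fps.items():
            weights[(comp.compound_id, pdb)] = (
                None if fp is None else tanimoto(fp, ref_fp)
            )
    return SimilarityWeights(weights)
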
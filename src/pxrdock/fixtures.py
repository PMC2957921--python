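"""Published fixtures: the cocrystal-ligand cutoff table and the 28-compound
sample set with its predicted and experimental classifications.

These transcribe the study's printed tables so the evaluation chain can be
exercised end-to-end without the commercial docking engine. Reference-ligand
structures (SMILES) are not part of the published record and are left unset;
similarity weights for the sample set live only in the study's supplement and
are likewise not shipped.
"""

from __future__ import annotations

from typing import Optional

from .datatypes import (
    AssayRecord,
    CompoundRecord,
    Consensus,
    CutoffPolicy,
    CutoffTable,
    Label,
    ReferenceLigand,
    Source,
    slugify,
)

# receptor_pdb, ligand_code, goldscore, sample gs cutoff, sample hs cutoff,
# full-set gs cutoff, full-set hs cutoff
_TABLE1 = (
    ("1M13", "HYF", 82.06, 66, 15, 51, 13),
    ("1NRL", "SRL", 48.31, 39, 15, 46, 14),
    ("1SKX", "RFP", 65.44, 52, 15, 48, 15),
    ("2O9I", "444", 48.69, 39, 15, 46, 13),
    ("2QNV", "CDZ", 55.19, 44, 15, 44, 11),
)

#: Score threshold of the external 2D Bayesian classifier whose calls are
#: transcribed in the sample-set table; recorded as metadata only — the model
#: itself (proprietary descriptors, steroid training set) is out of scope.
BAYESIAN_SCORE_CUTOFF = -5.792

# name, docking consensus (A/N), bayesian score, NCGC class cell,
# HepG2 EC50 cell, efficacy, viability IC50 cell, DPX-2 EC50 cell
# Cell conventions: "X" = no measurable activity, "" = not assayed/blank,
# "-" = missing data; "(S/M/W)" potency letters kept verbatim.
_TABLE2 = (
    ("Mancozeb", "N", -7.253, "N", "X", None, "", ""),
    ("Mesosulfuron-methyl", "A", -1.589, "N", "X", None, "X", "X"),
    ("Diethylhexyl phthalate", "A", 1.943, "A (20.75)", "1.8 (S)", 0.63, "", ""),
    ("Methyl hydrogen phthalate", "N", 1.868, "N", "", None, "", ""),
    ("Bensulide", "A", -1.165, "A (1.57)", "", None, "", ""),
    ("Foramsulfuron", "A", -1.653, "N", "> 50 (W)", None, "", ""),
    ("Bensulfuron methyl", "A", 0.601, "N", "89.4 (W)", 0.18, "X", "X"),
    ("Esfenvalerate", "A", 5.796, "A (26.98)", "1.5 (S)", 0.64, "X", "8.94 (S)"),
    ("Z,E-fenpyroximate", "A", 2.613, "N", "X", None, "0.04", "32.74 (M)"),
    ("Butafenacil", "A", 3.317, "N", "6 (S)", 0.53, "", ""),
    ("alpha-Cypermethrin", "A", 5.346, "A (18.3)", "1.6 (S)", 0.54, "X", "0.88 (S)"),
    ("Triflusulfuron methyl", "A", -1.998, "-", "", None, "", ""),
    ("beta-Cyfluthrin", "A", 5.346, "A (19.7)", "2.5 (S)", 0.54, "> 100", "18.2 (M)"),
    ("Permethrin", "A", 4.83, "A (20.26)", "5.4 (S)", 0.53, "X", "29.09 (M)"),
    ("Oxasulfuron", "A", -1.942, "N", "", None, "", ""),
    ("Fenarimol", "N", 4.791, "A (20.29)", "", None, "", ""),
    ("Propiconazole", "A", 3.475, "A (36.81)", "", None, "", ""),
    ("Fenbuconazole", "A", 5.390, "N", "", None, "", ""),
    ("Prochloraz", "A", 2.705, "N", "", None, "", ""),
    ("Imazalil", "N", 3.466, "A (36.54)", "", None, "", ""),
    ("Oxadiazon", "A", 4.663, "A (5.49)", "", None, "", ""),
    ("Alachlor", "N", 7.842, "A (15.35)", "", None, "", ""),
    ("2,4-D", "N", -0.563, "N", "", None, "", ""),
    ("Diuron", "N", 4.357, "N", "", None, "", ""),
    ("Atrazine", "N", -2.825, "N", "", None, "", ""),
    ("Fipronil", "N", -0.033, "A (12.55)", "", None, "", ""),
    ("Thiabendazole", "N", 2.879, "N", "", None, "", ""),
    ("Carbaryl", "N", 1.265, "N", "", None, "", ""),
)


def load_table1_fixture() -> tuple[list[ReferenceLigand], dict[str, CutoffTable]]:
    """The five cocrystallized reference ligands and both published cutoff sets.

    Returns the reference ligands and a dict with two :class:`CutoffTable`
    entries: ``"sample"`` (80%-of-reference GoldScore cutoffs, fixed hybrid
    cutoff 15) and ``"toxcast"`` (full-set averaged cutoffs).
    """
    refs = [
        ReferenceLigand(receptor_pdb=pdb, ligand_code=lig, goldscore=gs)
        for pdb, lig, gs, *_ in _TABLE1
    ]
    sample = CutoffTable(
        gs_cutoff={pdb: float(c) for pdb, _, _, c, _, _, _ in _TABLE1},
        hs_cutoff={pdb: float(c) for pdb, _, _, _, c, _, _ in _TABLE1},
        policy=CutoffPolicy.PCT80_OF_REFERENCE,
    )
    toxcast = CutoffTable(
        gs_cutoff={pdb: float(c) for pdb, _, _, _, _, c, _ in _TABLE1},
        hs_cutoff={pdb: float(c) for pdb, _, _, _, _, _, c in _TABLE1},
        policy=CutoffPolicy.MEAN_OF_DATASET,
    )
    return refs, {"sample": sample, "toxcast": toxcast}


def _parse_activity_cell(cell: str) -> tuple[Optional[str], Optional[float], Optional[str]]:
    """Split an activity cell into (status, ec50, potency letter).

    status is 'A'/'N'/'X' or None for blank / missing; censored values like
    "> 50" yield ec50=None with the letter retained.
    """
    cell = cell.strip()
    if cell in ("", "-"):
        return None, None, None
    if cell == "X":
        return "X", None, None
    status = None
    letter = None
    ec50 = None
    if cell.startswith(("A", "N")):
        status = cell[0]
        cell = cell[1:].strip()
    if "(" in cell:
        inner = cell[cell.index("(") + 1 : cell.index(")")].strip()
        before = cell[: cell.index("(")].strip()
        if inner in ("S", "M", "W"):
            letter = inner
            cell = before
        else:
            ec50 = float(inner)
            cell = before
    cell = cell.strip()
    if cell and ec50 is None:
        if cell.startswith(">"):
            ec50 = None  # censored; the letter carries the classification
        else:
            ec50 = float(cell)
    return status, ec50, letter


def load_table2_fixture() -> tuple[list[CompoundRecord], list[AssayRecord], dict[str, Consensus]]:
    """The 28-compound sample set: compounds, assay records, and the
    published GoldScore consensus docking classification per compound.

    NCGC "X" cells (no measurable activity) are carried by the class column
    itself (all are class N here); the single "–" cell (triflusulfuron
    methyl) becomes a missing label.
    """
    compounds: list[CompoundRecord] = []
    assays: list[AssayRecord] = []
    docking: dict[str, Consensus] = {}
    for name, dock, _bayes, ncgc, hepg2, eff, viab, dpx2 in _TABLE2:
        cid = slugify(name)
        compounds.append(CompoundRecord(compound_id=cid, name=name, source=Source.TOXCAST))
        docking[cid] = Consensus.AGONIST if dock == "A" else Consensus.NONAGONIST

        ncgc_status, ncgc_ec50, _ = _parse_activity_cell(ncgc)
        if ncgc_status == "A":
            ncgc_class = Label.AGONIST
        elif ncgc_status in ("N", "X"):
            ncgc_class = Label.NONAGONIST
        else:
            ncgc_class = Label.MISSING

        h_status, h_ec50, h_letter = _parse_activity_cell(hepg2)
        d_status, d_ec50, d_letter = _parse_activity_cell(dpx2)
        v_status, v_ic50, _ = _parse_activity_cell(viab)

        assays.append(
            AssayRecord(
                compound_id=cid,
                ncgc_class=ncgc_class,
                ncgc_ec50_uM=ncgc_ec50,
                hepg2_ec50_uM=h_ec50,
                hepg2_class=h_letter if h_letter else h_status,
                efficacy_rel_rifampicin=eff,
                dpx2_ec50_uM=d_ec50,
                dpx2_class=d_letter if d_letter else d_status,
                viability_ic50_uM=v_ic50,
            )
        )
    return compounds, assays, docking


def bayesian_scores() -> dict[str, float]:
    """Scores of the external 2D Bayesian classifier for the sample set
    (fixture metadata; the classifier is not reimplemented)."""
    return {slugify(name): score for name, _, score, *_ in _TABLE2}
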
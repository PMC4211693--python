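"""Bundled reference tables for the spinal-cord-injury CSF proteomics cohort.

These small tables are the printed inputs of the analysis: clinical details of
the two patient groups (early, 1-8 days post injury; late, 15-60 days), the
MALDI-MS protein identifications used as network seeds, and the per-spot
average DIGE fold changes (complete injury / incomplete injury) for the
differentially abundant spots.

The late-period fold column is carried as printed; some of its magnitudes are
below 1, which is outside the signed-fold convention that governs the early
column, so downstream code uses it only for threshold/sign classification,
never for ratio arithmetic.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import CohortTable

# (age, sensory_level, motor_level, days_post_injury, dige_pair, ais_grade, cause)
_EARLY_COHORT = [
    (22, "T9", "L2", 3, "DIGE 1", "A", "fall"),
    (36, "none", "L2", 2, "DIGE 1", "D", "fall"),
    (45, "none", "L2", 4, "DIGE 2", "D", "crush"),
    (20, "T6", "L2", 8, "DIGE 2", "A", "crush"),
    (30, "none", "L2", 1, "DIGE 3", "C", "fall"),
    (23, "T12", "L2", 2, "DIGE 3", "A", "fall"),
    (45, "L4", "L2", 5, "DIGE 4", "C", "fall"),
    (28, "L1", "L2", 7, "DIGE 4", "A", "fall"),
    (30, "T12", "L2", 2, "DIGE 5", "A", "fall"),
    (55, "L1", "L2", 2, "DIGE 5", "C", "fall"),
    (19, "none", "L2", 3, "DIGE 6", "C", "fall"),
    (50, "T7", "L2", 8, "DIGE 6", "A", "fall"),
    (25, "L1", "L2", 6, "DIGE 7", "A", "fall"),
    (38, "L2", "L2", 4, "DIGE 7", "C", "fall"),
]

_LATE_COHORT = [
    (55, "T8", "L1", 27, "DIGE 1", "A", "fall"),
    (23, "none", "L1", 25, "DIGE 1", "D", "fall"),
    (28, "T11", "L1", 15, "DIGE 2", "A", "fall"),
    (26, "none", "L1", 60, "DIGE 2", "C", "fall"),
    (20, "T9", "L1", 16, "DIGE 3", "A", "fall"),
    (25, "none", "L3", 30, "DIGE 3", "D", "fall"),
]

_COHORT_COLUMNS = ["age", "sensory_level", "motor_level", "days_post_injury",
                   "dige_pair", "ais_grade", "cause"]

#: (spot, protein name, gene symbol) for all MALDI-identified CSF spots.
SEED_IDENTIFICATIONS = [
    ("1", "Alpha 1B glycoprotein precursor", "A1BG"),
    ("4", "Antithrombin (serpin C1)", "SERPINC1"),
    ("12", "Alpha-1-antitrypsin", "SERPINA1"),
    ("13", "Vitamin D-binding protein precursor", "GC"),
    ("14", "Hemopexin precursor", "HPX"),
    ("16", "Fibrinogen gamma", "FGG"),
    ("20", "Fibrinogen beta chain precursor", "FGB"),
    ("26", "Haptoglobin", "HP"),
    ("28", "Zinc alpha 2 glycoprotein", "AZGP1"),
    ("32", "Apolipoprotein E precursor", "APOE"),
    ("32", "Glial fibrillary acidic protein", "GFAP"),
    ("34", "Transthyretin precursor", "TTR"),
    ("38", "Clusterin precursor", "CLU"),
    ("42", "Ig kappa chain C region", "IGKC"),
    ("42", "Prostaglandin H2 D-isomerase", "PTGDS"),
    ("46", "Apolipoprotein A-I precursor", "APOA1"),
    ("51", "Peroxiredoxin 2", "PRDX2"),
    ("52", "Complement C4 precursor", "CO4"),
    ("54", "AMBP protein precursor", "AMBP"),
    ("60", "Protein N-terminal asparagine amidohydrolase", "NTAN1"),
    ("61", "Apolipoprotein A-IV precursor", "APOA4"),
    ("62", "Carbonic anhydrase I", "CA1"),
    ("66", "Hemoglobin beta chain", "HBB"),
    ("71", "Ficolin 3 precursor", "FCN3"),
    ("73", "Creatine kinase, M chain", "CKM"),
    ("76", "SH3-domain kinase binding protein 1", "SH3KBP1"),
    ("81", "WD-repeat protein 37", "WDR37"),
    ("81", "Nonspecific lipid-transfer protein, mitochondrial", "SCP2"),
    ("83", "Transferrin", "TF"),
    ("85", "Ig mu chain C region", "IGHM"),
    ("86", "Gelsolin isoform b", "GSN"),
    ("94", "Ig alpha-1 chain C region", "IGHA1"),
    ("96", "Glypican-1 precursor", "GPC1"),
    ("96", "Phenylalanine-4-hydroxylase", "PAH"),
    ("96", "Pro-neuregulin-3 precursor", "NRG3"),
    ("97", "Heat shock 70 kDa protein 4L", "HSPA4L"),
    ("99", "Retinoic acid receptor gamma-1", "RARG"),
    ("99", "3-hydroxyanthranilate 3,4-dioxygenase", "HAAO"),
    ("99", "RBBP8 N-terminal-like protein", "RBBP8NL"),
    ("100", "Astrotactin 1", "ASTN1"),
    ("103", "Heat shock 70 kDa protein 4L", "HSPA4L"),
    ("104", "Beta-2-glycoprotein I precursor (Apolipoprotein H)", "APOH"),
    ("104", "General transcription factor 3C polypeptide 5", "GTF3C5"),
    ("107", "Serum albumin precursor", "ALB"),
    ("112", "Ig gamma-2 chain C region", "IGHG2"),
    ("116", "TBC1 domain family member 15", "TBC1D15"),
    ("119", "Ig gamma-1 chain C region", "IGHG1"),
    ("121", "Ig gamma-3 chain C region", "IGHG3"),
    ("126", "Ig gamma-4 chain C region", "IGHG4"),
    ("128", "Serum paraoxonase/arylesterase 1", "PON1"),
]

#: (spot, protein name, gene, avg signed fold 1-8 DPI, avg fold 15-60 DPI as
#: printed, late value obtained in only 2 of 3 experiments)
DIFFERENTIAL_SPOTS = [
    ("26", "Haptoglobin", "HP", -4.21, 0.49, False),
    ("27", "Haptoglobin", "HP", -2.15, 1.37, False),
    ("28", "Zinc alpha 2 glycoprotein", "AZGP1", -1.88, 0.66, False),
    ("83", "Transferrin", "TF", 1.52, 0.52, False),
    ("84", "Transferrin", "TF", 1.63, 0.45, False),
    ("104", "Beta-2-glycoprotein I precursor (Apolipoprotein H)", "APOH", 2.47, -0.6, True),
    ("104", "General transcription factor 3C polypeptide 5", "GTF3C5", 2.47, -0.6, True),
    ("107", "Serum albumin precursor", "ALB", 2.07, 2.23, True),
    ("108", "Serum albumin precursor", "ALB", 2.23, 1.2, True),
    ("112", "Ig gamma-2 chain C region", "IGHG2", 1.58, 1.47, True),
    ("126", "Ig gamma-4 chain C region", "IGHG4", 1.52, 2.13, True),
]

#: Seeds the source interactome snapshot listed no partners for; they are
#: dropped during seed resolution rather than kept as isolated nodes.
UNLISTED_SEEDS = ["NTAN1", "NRG3", "RBBP8NL", "IGHG4"]

#: Default alias replacements applied before seed expansion.
DEFAULT_ALIASES: dict[str, list[str]] = {"CO4": ["C4A", "C4B"]}


def early_cohort() -> CohortTable:
    """Clinical details of the 14 CSF samples drawn 1-8 days post injury."""
    return CohortTable(pd.DataFrame(_EARLY_COHORT, columns=_COHORT_COLUMNS))


def late_cohort() -> CohortTable:
    """Clinical details of the 6 CSF samples drawn 15-60 days post injury."""
    return CohortTable(pd.DataFrame(_LATE_COHORT, columns=_COHORT_COLUMNS))


def seed_genes() -> list[str]:
    """Unique gene symbols of the MALDI-identified CSF proteins (order kept)."""
    seen: dict[str, None] = {}
    for _, _, gene in SEED_IDENTIFICATIONS:
        seen.setdefault(gene)
    return list(seen)


def differential_spot_map() -> dict[str, list[tuple[str, str]]]:
    """spot -> [(protein name, gene symbol)] for the differential spots."""
    out: dict[str, list[tuple[str, str]]] = {}
    for spot, name, gene, *_ in DIFFERENTIAL_SPOTS:
        out.setdefault(spot, []).append((name, gene))
    return out


def differential_fold_table() -> pd.DataFrame:
    """Per-spot average signed folds for the two sampling periods."""
    return pd.DataFrame(
        DIFFERENTIAL_SPOTS,
        columns=["spot_id", "protein_name", "gene_symbol",
                 "early_fold", "late_fold", "late_partial"],
    )
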
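"""Reference configurations and worked-example data for the two syndromes.

The pipeline was designed around the Qi-deficiency-and-blood-stasis
syndrome of coronary heart disease (CHD) and of stroke.  This module
encodes, as plain data:

* the published symptom classifications of both syndromes (main,
  Qi-deficiency and blood-stasis groups, with the terms that are fixed in
  every combination),
* the keyword-search gene counts used to prune symptoms that map to no
  gene,
* worked-example centrality profiles for the top-ranked genes of each
  syndrome network, used as reference fixtures for the scoring formulas,
* the 46 genes shared by the two syndromes in the reference analysis.

These are configuration inputs, not computed results: the pipeline itself
operates on arbitrary corpora and classifications.
"""

from __future__ import annotations

from .combination import SymptomClassification
from .network import CentralityProfile

# ---------------------------------------------------------------------------
# Symptom classifications
# ---------------------------------------------------------------------------
# Terms use the modern-medicine search keywords (post term-mapping surface
# forms).  Options group terms that always travel together in a combination.

CHD_CLASSIFICATION = SymptomClassification(
    syndrome_name="qi-deficiency-blood-stasis-CHD",
    main=(("Chest pain",), ("Chest heaviness",)),
    qi_deficiency=(("Respiratory abnormality",), ("Lassitude",), ("Sweating",),
                   ("Dizziness",), ("Typhoid fever",), ("Insomnia",)),
    blood_stasis=(("Hemiplegia",), ("Ecchymoses",), ("Tongue disorder",)),
    fixed_terms=("Palpitation",),
)

STROKE_CLASSIFICATION = SymptomClassification(
    syndrome_name="qi-deficiency-blood-stasis-stroke",
    main=(("Hemiplegia", "Stroke"),),
    qi_deficiency=(("Respiratory abnormality", "Lassitude"), ("Sweating",),
                   ("Anemic",)),
    blood_stasis=(("Ecchymoses", "Extremity Numbness"),
                  ("Glossitis", "Irritability")),
    fixed_terms=("Constipation", "Xerostomia", "Headache", "Sputum"),
)

# Number of genes returned by the reference keyword search per symptom.
# Zero-count symptoms ("Chest heaviness", "Tongue disorder", "Insomnia")
# are the ones the pruning step removes before enumeration.
KEYWORD_GENE_COUNTS: dict[str, int] = {
    "Dizziness": 166,
    "Constipation": 210,
    "Headache": 338,
    "Xerostomia": 87,
    "Irritability": 122,
    "Glossitis": 19,
    "Extremity Numbness": 4,
    "Hemiplegia": 65,
    "Sputum": 4,
    "Stroke": 699,
    "Respiratory abnormality": 76,
    "Anemic": 169,
    "Lassitude": 31,
    "Ecchymoses": 24,
    "Sweating": 129,
    "Chest pain": 225,
    "Palpitation": 49,
    "Typhoid fever": 82,
    "Chest heaviness": 0,
    "Tongue disorder": 0,
    "Insomnia": 0,
}


def hits_from_keyword_counts(counts: dict[str, int] | None = None
                             ) -> dict[str, dict[str, int]]:
    """Expand per-symptom gene counts into a synthetic hits table.

    The reference keyword search reports only how many genes each symptom
    returned, not which; gene identities here are synthetic placeholders
    (``G0001`` ...), one per count, each with hit 1.  The table is suitable
    for pruning and per-symptom counting, not for cross-symptom
    intersection.
    """
    counts = KEYWORD_GENE_COUNTS if counts is None else counts
    return {symptom: {f"G{i + 1:04d}": 1 for i in range(n)}
            for symptom, n in counts.items()}


# ---------------------------------------------------------------------------
# Worked-example centrality profiles (scoring-formula fixtures)
# ---------------------------------------------------------------------------
# Per gene: max-scaled degree (CD), closeness (CC), betweenness (CB) and
# hub/eigenvector (CE) centralities, plus the sub-network ZSW, from the
# reference ranking of each syndrome network.

CHD_TOP_GENES: dict[str, tuple[CentralityProfile, float]] = {
    # symbol: (profile, ZSW)
    "CHRNA4": (CentralityProfile(cd=1.0, cc=1.0, cb=0.29, ce=1.0), 1.0),
    "BDNF": (CentralityProfile(cd=0.8, cc=0.92, cb=0.29, ce=0.5), 1.0),
    "CHRNB4": (CentralityProfile(cd=0.6, cc=0.69, cb=0.0, ce=0.7), 1.0),
    "CHRNA5": (CentralityProfile(cd=0.5, cc=0.62, cb=0.0, ce=0.64), 1.0),
    "CHRNB3": (CentralityProfile(cd=0.5, cc=0.62, cb=0.0, ce=0.62), 1.0),
    "CHRNA6": (CentralityProfile(cd=0.4, cc=0.62, cb=0.0, ce=0.54), 1.0),
    "COMT": (CentralityProfile(cd=0.5, cc=0.77, cb=0.14, ce=0.44), 1.0),
    "CHRNA3": (CentralityProfile(cd=0.5, cc=0.62, cb=0.0, ce=0.52), 1.0),
    "CHRNB2": (CentralityProfile(cd=0.4, cc=0.62, cb=0.0, ce=0.5), 1.0),
    "MAOA": (CentralityProfile(cd=0.4, cc=0.77, cb=0.14, ce=0.38), 1.0),
}

STROKE_TOP_GENES: dict[str, tuple[CentralityProfile, float]] = {
    "CXCR4": (CentralityProfile(cd=1.0, cc=0.99, cb=0.91, ce=0.78), 0.88),
    "CXCL13": (CentralityProfile(cd=0.92, cc=0.94, cb=0.65, ce=0.88), 0.88),
    "CCR7": (CentralityProfile(cd=0.85, cc=0.88, cb=0.27, ce=1.0), 0.88),
    "CCL2": (CentralityProfile(cd=0.69, cc=0.87, cb=0.4, ce=0.83), 0.63),
    "CXCL1": (CentralityProfile(cd=0.77, cc=0.75, cb=0.05, ce=1.01), 0.88),
    "CCR4": (CentralityProfile(cd=0.62, cc=0.87, cb=0.16, ce=0.93), 0.88),
    "CXCL9": (CentralityProfile(cd=0.62, cc=0.75, cb=0.04, ce=0.88), 0.88),
    "CCL5": (CentralityProfile(cd=0.69, cc=0.72, cb=0.08, ce=0.83), 0.63),
    "CCR2": (CentralityProfile(cd=0.54, cc=0.72, cb=0.02, ce=0.87), 0.88),
    "CCR1": (CentralityProfile(cd=0.54, cc=0.72, cb=0.01, ce=0.86), 1.0),
}

# Reference CMI values printed alongside the profiles above (some stroke
# rows were published with CMI values that the formula does not reproduce
# from the rounded centrality columns; those rows are retained for the
# GW = CMI + ZSW identity only).
CHD_REFERENCE_CMI: dict[str, float] = {
    "CHRNA4": 1.29, "BDNF": 0.752174, "CHRNB4": 0.7, "CHRNA5": 0.64,
    "CHRNB3": 0.62, "CHRNA6": 0.54, "COMT": 0.530909, "CHRNA3": 0.52,
    "CHRNB2": 0.5, "MAOA": 0.452727,
}
STROKE_REFERENCE_CMI: dict[str, float] = {
    "CXCR4": 1.70, "CXCL13": 1.52, "CCR7": 1.06, "CCL2": 1.26,
    "CXCL1": 0.91, "CCR4": 0.85, "CXCL9": 0.85, "CCL5": 1.04,
    "CCR2": 0.75, "CCR1": 0.55,
}
CHD_REFERENCE_GW: dict[str, float] = {
    "CHRNA4": 2.29, "BDNF": 1.75, "CHRNB4": 1.70, "CHRNA5": 1.64,
    "CHRNB3": 1.62, "CHRNA6": 1.54, "COMT": 1.53, "CHRNA3": 1.52,
    "CHRNB2": 1.5, "MAOA": 1.45,
}
STROKE_REFERENCE_GW: dict[str, float] = {
    "CXCR4": 2.58, "CXCL13": 2.40, "CCR7": 1.94, "CCL2": 1.89,
    "CXCL1": 1.79, "CCR4": 1.73, "CXCL9": 1.73, "CCL5": 1.67,
    "CCR2": 1.63, "CCR1": 1.55,
}

# Genes whose centrality columns reproduce their reference CMI under the
# formula (the remaining stroke rows were published with internally
# inconsistent rounding and are excluded from formula fixtures).
FORMULA_CONSISTENT_GENES = (
    "CHRNA4", "BDNF", "CHRNB4", "CHRNA5", "CHRNB3", "CHRNA6", "COMT",
    "CHRNA3", "CHRNB2", "MAOA", "CXCR4", "CXCL13",
)

# Genes shared by the two syndromes in the reference analysis.
SHARED_GENES = (
    "CXCR4", "HGF", "EGF", "BDNF", "IL10", "INS", "IL12B", "IL13", "IGF2",
    "IGF1R", "CTNNB1", "IFNG", "HTR3A", "EGFR", "HLA-B", "HLA-DQB1",
    "HLA-DRB1", "IFNGR1", "IGF1", "CRLF1", "GDNF", "FOXP3", "AKT1", "F3",
    "BMP2", "AR", "CNTF", "BCL2", "IL6", "COMT", "CHRNA4", "CLCF1",
    "CNTFR", "MET", "MUC1", "MAOA", "LEP", "CCK", "IL4", "BRCA1", "C3",
    "IL18", "IL2", "IL1B", "INSR", "IL17A",
)
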
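"""Published dual-biobank screening summary, as machine-readable input.

These tables transcribe the headline per-gene results of a published
two-cohort (UK Biobank + Healthy Nevada Project) rare-variant screen: the
population-level significant gene-disease associations with their
per-stratum dual-cohort PPV flags, and the per-gene carrier percentages for
the conditions that cleared the PPV >= 0.3 screen. They serve as fixed
inputs for the screening arithmetic — which genes pass the gate, and what
fraction of a population the novel conditions would reach — not as outputs
of this package's statistics.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "significant_associations",
    "screen_summary",
    "genes_passing_ppv_gate",
    "novel_screening_reach_pct",
]

# gene, model, phenotype, meta p, OR, PPV>=0.3 in both cohorts at 60+ / all ages
_SIGNIFICANT = [
    ("HBB", "lof", "Other hemoglobinopathies", 1.91e-129, 197.2, True, True),
    ("PKD1", "lof", "Cystic kidney disease", 4.54e-48, 78.5, True, False),
    ("GCK", "coding", "Type 2 diabetes", 1.46e-33, 11.3, True, True),
    ("LDLR", "lof", "Coronary atherosclerosis", 1.46e-12, 17.5, True, True),
    ("BRCA2", "lof", "Malignant neoplasm of female breast", 3.96e-45, 8.5, True, False),
    ("BRCA1", "lof", "Malignant neoplasm of female breast", 8.77e-28, 14.2, True, False),
    ("MIP", "coding", "Cataract", 1.56e-10, 4.6, True, False),
    ("JAK2", "coding", "Myeloproliferative disease", 6.41e-62, 7.6, False, False),
    ("COL4A4", "lof", "Hematuria", 8.96e-23, 4.6, False, False),
    ("TTN", "lof", "Atrial fibrillation and flutter", 1.91e-17, 1.8, False, False),
    ("MSH6", "lof", "Malignant neoplasm of uterus", 2.11e-17, 19.6, False, False),
    ("MYBPC3", "lof", "Other hypertrophic cardiomyopathy", 5.07e-17, 70.2, False, False),
    ("IFT140", "lof", "Cyst of kidney, acquired", 3.81e-16, 10.2, False, False),
    ("NF1", "lof", "Other benign neoplasm of connective and other soft tissue", 1.25e-15, 14.9, False, False),
    ("PKD2", "coding", "Cystic kidney disease", 1.85e-15, 3.9, False, False),
    ("TET2", "lof", "Neutropenia", 2.34e-15, 4.8, False, False),
    ("VWF", "coding", "Von Willebrand disease", 2.77e-15, 6.7, False, False),
    ("SF3B1", "coding", "Myeloproliferative disease", 4.21e-13, 13.0, False, False),
    ("CDKN2A", "coding", "Melanomas of skin", 5.57e-13, 10.2, False, False),
    ("TSHR", "coding", "Hypothyroidism not otherwise specified", 1.52e-12, 1.9, False, False),
    ("PALB2", "lof", "Malignant neoplasm of female breast", 8.22e-12, 5.0, False, False),
    ("ASXL1", "lof", "Myeloproliferative disease", 9.75e-12, 13.0, False, False),
    ("PROC", "coding", "Phlebitis and thrombophlebitis", 1.35e-11, 4.9, False, False),
    ("ATM", "lof", "Malignant neoplasm of female breast", 2.49e-11, 4.9, False, False),
    ("SLC22A12", "coding", "Gout", 4.86e-11, 0.1, False, False),
    ("MLH1", "lof", "Colon cancer", 1.54e-10, 240.7, False, False),
    ("SLC4A1", "coding", "Other hereditary hemolytic anemias", 1.99e-10, 19.8, False, False),
]

# condition-level summary for the genes that cleared the screen:
# gene, condition, % of population with qualifying variants, best PPV,
# novel (not already in population screening programs)
_SCREEN_SUMMARY = [
    ("BRCA1", "Hereditary breast and ovarian cancer", 0.11, 0.43, False),
    ("BRCA2", "Hereditary breast and ovarian cancer", 0.36, 0.35, False),
    ("GCK", "Type 2 diabetes", 0.06, 0.50, True),
    ("HBB", "Beta-thalassemia minor and intermedia", 0.06, 0.59, True),
    ("LDLR", "Familial hypercholesterolemia", 0.03, 0.50, False),
    ("MIP", "Cataracts", 0.06, 0.43, True),
    ("PKD1", "Chronic (cystic) kidney disease", 0.03, 0.44, True),
]


def significant_associations() -> pd.DataFrame:
    """Per-gene headline significant associations with dual-cohort PPV flags."""
    return pd.DataFrame(
        _SIGNIFICANT,
        columns=[
            "gene",
            "model",
            "phenotype",
            "p_meta",
            "odds_ratio",
            "ppv_pass_60plus",
            "ppv_pass_all_ages",
        ],
    )


def screen_summary() -> pd.DataFrame:
    """Condition-level summary for genes that cleared the PPV screen."""
    return pd.DataFrame(
        _SCREEN_SUMMARY,
        columns=["gene", "condition", "pct_with_variant", "ppv", "novel"],
    )


def genes_passing_ppv_gate(table: pd.DataFrame | None = None) -> list[str]:
    """Genes whose dual-cohort PPV clears the threshold in either stratum.

    The screening rule admits an association when PPV >= 0.3 holds in both
    cohorts for the all-ages stratum OR for the 60+ stratum (a 60+ pass
    counts even when the all-ages PPV falls short).
    """
    df = significant_associations() if table is None else table
    passing = df[df["ppv_pass_60plus"] | df["ppv_pass_all_ages"]]
    return sorted(passing["gene"].unique())


def novel_screening_reach_pct(table: pd.DataFrame | None = None) -> float:
    """Additional % of a population reached by screening the novel genes.

    Sums the per-gene carrier percentages over the screen-passing genes not
    already covered by existing population screening programs.
    """
    df = screen_summary() if table is None else table
    return float(round(df.loc[df["novel"], "pct_with_variant"].sum(), 10))
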
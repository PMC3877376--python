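"""Published summary statistics for the 11-SNP melanoma panel.

These are the printed per-study and pooled estimates from the melanoma
case-control study (MDACC discovery) and the two prospective replication
cohorts (NHS, HPFS).  They serve three roles:

* default panel configuration (risk alleles, frequencies, and pooled-OR
  weights — the per-SNP weights from the original prior studies were not
  printed, so the pooled odds ratios stand in as documented defaults);
* simulation truth for the synthetic cohorts;
* inputs for reproducing the pooled meta-analysis columns and the
  reclassification summary from printed numbers alone.

Each association entry is ``(OR, ci_low, ci_high)`` on the odds-ratio scale.
"""

from __future__ import annotations

import math

STUDY_LABELS = ("mdacc", "nhs", "hpfs")

# Per-study unadjusted additive per-allele odds ratios for the 11 SNPs,
# with the published pooled (random-effects) column.
SINGLE_SNP_OR: dict[str, dict[str, tuple[float, float, float]]] = {
    "rs7412746": {
        "mdacc": (1.18, 1.06, 1.31),
        "nhs": (1.24, 1.04, 1.46),
        "hpfs": (0.97, 0.78, 1.21),
        "pooled": (1.15, 1.02, 1.29),
    },
    "rs13016963": {
        "mdacc": (1.13, 1.01, 1.26),
        "nhs": (1.04, 0.88, 1.23),
        "hpfs": (0.78, 0.62, 0.98),
        "pooled": (0.99, 0.81, 1.20),
    },
    "rs4636294": {
        "mdacc": (1.23, 1.10, 1.37),
        "nhs": (1.00, 0.85, 1.18),
        "hpfs": (1.08, 0.87, 1.33),
        "pooled": (1.11, 0.97, 1.28),
    },
    "rs1335510": {
        "mdacc": (1.26, 1.12, 1.40),
        "nhs": (1.03, 0.87, 1.21),
        "hpfs": (1.03, 0.83, 1.28),
        "pooled": (1.12, 0.96, 1.30),
    },
    "rs7023329": {
        "mdacc": (1.26, 1.13, 1.41),
        "nhs": (1.01, 0.85, 1.18),
        "hpfs": (1.11, 0.90, 1.38),
        "pooled": (1.13, 0.97, 1.32),
    },
    "rs10830253": {
        "mdacc": (1.19, 1.06, 1.33),
        "nhs": (1.27, 1.07, 1.50),
        "hpfs": (1.54, 1.24, 1.92),
        "pooled": (1.29, 1.12, 1.48),
    },
    "rs1801516": {
        "mdacc": (1.23, 1.05, 1.44),
        "nhs": (1.16, 0.92, 1.48),
        "hpfs": (0.84, 0.62, 1.14),
        "pooled": (1.10, 0.89, 1.34),
    },
    "rs12913832": {
        "mdacc": (1.43, 1.26, 1.62),
        "nhs": (1.23, 1.01, 1.49),
        "hpfs": (1.12, 0.88, 1.43),
        "pooled": (1.29, 1.12, 1.48),
    },
    "rs258322": {
        "mdacc": (1.54, 1.29, 1.84),
        "nhs": (1.62, 1.28, 2.05),
        "hpfs": (1.28, 0.90, 1.82),
        "pooled": (1.53, 1.34, 1.74),
    },
    "rs4911442": {
        "mdacc": (1.27, 1.08, 1.49),
        "nhs": (1.30, 1.03, 1.65),
        "hpfs": (1.32, 0.96, 1.83),
        "pooled": (1.28, 1.14, 1.45),
    },
    "rs132985": {
        "mdacc": (1.20, 1.08, 1.34),
        "nhs": (1.12, 0.95, 1.32),
        "hpfs": (1.20, 0.96, 1.49),
        "pooled": (1.18, 1.08, 1.28),
    },
}

# Risk-allele frequency and annotation per SNP (published minor-allele
# frequencies; treated as risk-allele frequencies in the default config).
SNP_INFO: dict[str, dict] = {
    "rs7412746": {"freq": 0.4452, "gene": "ARNT", "risk_allele": "T"},
    "rs13016963": {"freq": 0.3834, "gene": "ALS2CR12", "risk_allele": "A"},
    "rs4636294": {"freq": 0.4781, "gene": "LOC402359", "risk_allele": "A"},
    "rs1335510": {"freq": 0.3919, "gene": "LOC100418", "risk_allele": "T"},
    "rs7023329": {"freq": 0.4696, "gene": "MTAP", "risk_allele": "A"},
    "rs10830253": {"freq": 0.3398, "gene": "TYR", "risk_allele": "G"},
    "rs1801516": {"freq": 0.1333, "gene": "ATM", "risk_allele": "G"},
    "rs12913832": {"freq": 0.2250, "gene": "HERC2", "risk_allele": "G"},
    "rs258322": {"freq": 0.1203, "gene": "CDK10", "risk_allele": "A"},
    "rs4911442": {"freq": 0.1506, "gene": "ASIP", "risk_allele": "G"},
    "rs132985": {"freq": 0.4518, "gene": "PLA2G6", "risk_allele": "C"},
}

DEFAULT_PANEL_ROWS: list[dict] = [
    {
        "snp_id": snp,
        "risk_allele": SNP_INFO[snp]["risk_allele"],
        "weight": math.log(SINGLE_SNP_OR[snp]["pooled"][0]),
        "risk_allele_freq": SNP_INFO[snp]["freq"],
        "gene": SNP_INFO[snp]["gene"],
    }
    for snp in SNP_INFO
]

# Per-study PRS association estimates (per-unit continuous PRS, and the
# top-vs-bottom tertile contrast), univariate and covariate-adjusted, with
# the published pooled columns.
PRS_OR: dict[str, dict[str, dict[str, tuple[float, float, float]]]] = {
    "continuous": {
        "univariate": {
            "mdacc": (1.19, 1.15, 1.24),
            "nhs": (1.13, 1.08, 1.19),
            "hpfs": (1.10, 1.03, 1.18),
            "pooled": (1.15, 1.09, 1.20),
        },
        "multivariate": {
            "mdacc": (1.17, 1.12, 1.22),
            "nhs": (1.10, 1.04, 1.16),
            "hpfs": (1.07, 1.00, 1.15),
            "pooled": (1.12, 1.06, 1.18),
        },
    },
    "tertile31": {
        "univariate": {
            "mdacc": (2.34, 1.93, 2.84),
            "nhs": (1.73, 1.30, 2.30),
            "hpfs": (1.54, 1.06, 2.24),
            "pooled": (1.90, 1.46, 2.48),
        },
        "multivariate": {
            "mdacc": (2.13, 1.69, 2.68),
            "nhs": (1.55, 1.14, 2.11),
            "hpfs": (1.34, 0.90, 2.00),
            "pooled": (1.69, 1.28, 2.25),
        },
    },
}

# Published reclassification tables for the MDACC cohort: 3x3 counts of
# predicted-risk category under the phenotype-only model (rows) vs the
# phenotype+PRS model (columns); categories <20%, 20-50%, >=50%.
RECLASS_EVENTS = [
    [0, 0, 0],
    [0, 372, 306],
    [0, 86, 1039],
]
RECLASS_NONEVENTS = [
    [0, 0, 0],
    [4, 579, 231],
    [0, 113, 99],
]

# Default cohort sizes (cases, controls) per study.
STUDY_SIZES: dict[str, tuple[int, int]] = {
    "mdacc": (1804, 1025),
    "nhs": (317, 3376),
    "hpfs": (177, 2251),
}
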
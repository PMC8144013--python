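"""Published summary data of the Finnish coeliac case-control cohort.

This module carries the printed summary statistics of a genotyped Finnish
coeliac disease cohort (625 biopsy-proven patients, 1817 population
controls, 39 directly genotyped non-HLA risk SNPs): the per-phenotype
patient counts, and the per-variant minor-allele frequencies and odds
ratios of the phenotype associations that survived family-wise permutation
correction. They serve two purposes:

* reconstructing 2x2 allele-count tables from printed MAFs (``round(2n *
  MAF)``) to check the odds-ratio/CI machinery against published values;
* parameterising the "paper-shape" synthetic fixture so simulated cohorts
  share the real cohort's dimensions and frequency spectrum.

Positions attached to the published variants are synthetic placeholders
(the printed tables give chromosome but not basepair); they are spaced so
no two published variants fall in one clumping window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import ContingencyTable2x2
from .genio import PhenotypeTable

N_CASES = 625
N_CONTROLS = 1817

# Cases-at-diagnosis phenotype counts; (positives, available denominator).
# Mucosal morphology was graded for 546 patients, autoantibody status
# recorded for 298; all other items cover the full 625.
PHENOTYPE_COUNTS = {
    "childhood_diagnosis": (44, 625),
    "childhood_symptoms": (273, 625),
    "gi_symptoms": (526, 625),
    "malabsorption": (267, 625),
    "anaemia": (157, 625),
    "ei_manifestation": (263, 625),
    "dh": (69, 625),
    "neuro": (38, 625),
    "fractures": (70, 625),
    "asymptomatic": (53, 625),
    "associated_conditions": (123, 625),
    "aitd": (100, 625),
    "t1d": (18, 625),
    "tva_sva": (361, 546),
    "pva": (185, 546),
    "hla_high": (98, 625),
    "antibody_positive": (279, 298),
    "antibody_negative": (19, 298),
}
N_FEMALE_CASES = 489

# The ten genotyped SNPs with at least one phenotype association surviving
# the family-wise permutation correction: allele_a is the minor allele.
PUBLISHED_VARIANTS = pd.DataFrame(
    [
        ("rs5979785", "TLR7/TLR8", "X", "G", "A", 0.24),
        ("rs653178", "SH2B3/ATXN2", "12", "C", "T", 0.41),
        ("rs13010713", "ITGA4/UBE2E3", "2", "T", "C", 0.51),
        ("rs13151961", "IL2/IL21", "4", "C", "T", 0.12),
        ("rs11712165", "CD80", "3", "G", "T", 0.39),
        ("rs10936599", "MYNN", "3", "A", "G", 0.26),
        ("rs13098911", "CCR1/CCR3", "3", "T", "C", 0.14),
        ("rs17810546", "IL12A", "3", "G", "A", 0.10),
        ("rs2327832", "OLIG3/TNFAIP3", "6", "C", "T", 0.19),
        ("rs2298428", "UBE2L3/YDJC", "22", "T", "C", 0.29),
    ],
    columns=["id", "gene", "chrom", "allele_a", "allele_b", "maf_controls"],
)

# Case-control odds ratios of representative broad contrasts, used as
# ln(OR) generative effects in the paper-shape fixture. The X-linked
# rs5979785 OR was printed only for a narrow subgroup; a modest protective
# value is substituted for cohort-level simulation.
REPRESENTATIVE_OR = {
    "rs5979785": 0.80,
    "rs653178": 1.28,
    "rs13010713": 0.78,
    "rs13151961": 0.66,
    "rs11712165": 1.26,
    "rs10936599": 1.27,
    "rs13098911": 1.58,
    "rs17810546": 1.57,
    "rs2327832": 1.53,
    "rs2298428": 1.60,
}

# Published phenotype-association rows (family-wise EMP2 <= 0.05):
# phenotype contrast, group-1 size, marker, case MAF, control MAF,
# printed OR and 95% CI, printed EMP2.
ASSOCIATION_ROWS = pd.DataFrame(
    [
        ("female_childhood_dx", 30, "rs5979785", 0.03, 0.24, 0.11, 0.03, 0.47, 0.015),
        ("late_dx", 573, "rs653178", 0.47, 0.41, 1.28, 1.12, 1.46, 0.015),
        ("late_dx", 573, "rs13010713", 0.45, 0.51, 0.78, 0.69, 0.90, 0.015),
        ("late_dx", 573, "rs13151961", 0.08, 0.12, 0.66, 0.52, 0.84, 0.027),
        ("late_dx", 573, "rs11712165", 0.45, 0.39, 1.26, 1.10, 1.44, 0.031),
        ("late_dx", 573, "rs10936599", 0.31, 0.26, 1.27, 1.10, 1.47, 0.046),
        ("childhood_symptoms", 273, "rs13098911", 0.21, 0.14, 1.58, 1.26, 1.99, 0.003),
        ("gi_symptoms", 526, "rs653178", 0.47, 0.41, 1.29, 1.12, 1.48, 0.012),
        ("gi_symptoms", 526, "rs13010713", 0.45, 0.51, 0.79, 0.69, 0.91, 0.038),
        ("gi_symptoms", 526, "rs13151961", 0.08, 0.12, 0.66, 0.51, 0.84, 0.030),
        ("malabsorption", 267, "rs17810546", 0.15, 0.10, 1.57, 1.21, 2.04, 0.024),
        ("malabsorption", 267, "rs2327832", 0.26, 0.19, 1.53, 1.24, 1.89, 0.002),
        ("anaemia", 157, "rs2327832", 0.28, 0.19, 1.74, 1.34, 2.25, 0.001),
        ("ei_manifestation", 263, "rs653178", 0.48, 0.41, 1.36, 1.13, 1.63, 0.042),
        ("neuro", 38, "rs13098911", 0.28, 0.14, 2.34, 1.41, 3.91, 0.034),
        ("fractures", 70, "rs10936599", 0.41, 0.26, 1.84, 1.30, 2.60, 0.021),
        ("associated_conditions", 123, "rs653178", 0.52, 0.41, 1.61, 1.24, 2.09, 0.012),
        ("associated_conditions", 123, "rs2298428", 0.39, 0.29, 1.60, 1.23, 2.09, 0.019),
        ("aitd", 100, "rs653178", 0.54, 0.41, 1.68, 1.26, 2.24, 0.012),
        ("t1d", 18, "rs653178", 0.69, 0.41, 3.32, 1.63, 6.67, 0.027),
        ("tva_sva", 361, "rs653178", 0.48, 0.41, 1.35, 1.15, 1.58, 0.012),
        ("tva_sva", 361, "rs13010713", 0.42, 0.51, 0.70, 0.59, 0.82, 2e-4),
        ("tva_sva", 361, "rs13151961", 0.07, 0.12, 0.57, 0.42, 0.78, 0.012),
        ("tva_sva", 361, "rs2327832", 0.24, 0.19, 1.37, 1.13, 1.66, 0.051),
        ("pva", 185, "rs13098911", 0.21, 0.14, 1.59, 1.21, 2.08, 0.030),
        ("hla_intermediate", 517, "rs653178", 0.47, 0.40, 1.35, 1.16, 1.58, 0.006),
        ("hla_intermediate", 517, "rs13010713", 0.45, 0.52, 0.73, 0.63, 0.86, 0.004),
        ("hla_intermediate", 517, "rs13151961", 0.08, 0.12, 0.63, 0.48, 0.82, 0.029),
        ("hla_intermediate", 517, "rs11712165", 0.45, 0.39, 1.29, 1.11, 1.51, 0.048),
        ("antibody_negative", 19, "rs13098911", 0.34, 0.14, 3.19, 1.62, 6.28, 0.020),
    ],
    columns=["phenotype", "n_group1", "id", "maf_cases", "maf_controls",
             "or", "ci_low", "ci_high", "emp2"],
)


def published_variant_positions() -> dict:
    """Synthetic placeholder positions, one clumping window apart."""
    return {vid: 10_000_000 + 1_000_000 * j
            for j, vid in enumerate(PUBLISHED_VARIANTS["id"])}


def reconstruct_allele_table(n_group1: int, maf_group1: float,
                             n_group2: int, maf_group2: float
                             ) -> ContingencyTable2x2:
    """2x2 allele-count table from printed per-group MAFs.

    Counts are ``round(2 * n * MAF)`` per group; the printed MAFs carry two
    decimals, so the reconstruction is exact to that precision.
    """
    a = round(2 * n_group1 * maf_group1)
    c = round(2 * n_group2 * maf_group2)
    return ContingencyTable2x2(a, 2 * n_group1 - a, c, 2 * n_group2 - c)


def cohort_phenotype_table() -> PhenotypeTable:
    """Deterministic phenotype table matching the published marginals.

    Flag overlap between phenotypes is not published; each flag is laid out
    independently (first k cases positive), so only the marginal counts and
    availability denominators are faithful. Controls carry no flags and a
    balanced sex split.
    """
    n = N_CASES + N_CONTROLS
    idx = pd.Index([f"case{i:04d}" for i in range(N_CASES)]
                   + [f"ctrl{i:04d}" for i in range(N_CONTROLS)],
                   name="sample")
    tab = pd.DataFrame(index=idx)
    tab["status"] = ["case"] * N_CASES + ["control"] * N_CONTROLS
    sex_cases = ["F"] * N_FEMALE_CASES + ["M"] * (N_CASES - N_FEMALE_CASES)
    sex_ctrls = ["F" if i % 2 == 0 else "M" for i in range(N_CONTROLS)]
    tab["sex"] = sex_cases + sex_ctrls
    tab["age"] = np.nan
    tab["age_at_diagnosis"] = np.nan
    for flag, (pos, avail) in PHENOTYPE_COUNTS.items():
        col = np.full(n, np.nan)
        col[:pos] = 1.0
        col[pos:avail] = 0.0
        tab[flag] = col
    return PhenotypeTable(tab)
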
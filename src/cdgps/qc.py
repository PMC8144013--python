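"""Variant-level quality control.

Filters (defaults as applied to the genotyped SNP set this pipeline
emulates): call-rate missingness < 5%, case/control differential
missingness < 3% (absolute difference), MAF > 1%, exact Hardy-Weinberg
P > 1e-6 evaluated in controls. Boundary semantics are strict as printed:
4.99% missingness is kept, 5.0% is dropped.

The HWE test is the exact conditional test (conditional on observed allele
counts; two-sided by summing probabilities of heterozygote configurations no
more probable than observed), which is well-defined at low counts where the
chi-squared approximation is not. X-chromosome HWE uses females only, since
hemizygous males carry no heterozygote information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import Cohort, GenotypeMatrix, PhenotypeTable


@dataclass(frozen=True)
class QcThresholds:
    """Strict-inequality QC cutoffs; defaults match the emulated pipeline."""

    max_missing: float = 0.05        # drop if missingness >= this
    max_diff_missing: float = 0.03   # drop if |case - control| >= this
    min_maf: float = 0.01            # drop if MAF <= this
    min_hwe_p: float = 1e-6          # drop if control HWE P <= this


def compute_maf(doses, male: np.ndarray | None = None) -> tuple:
    """Effect-allele frequency and folded minor-allele frequency.

    X-chromosome aware when ``male`` is given: hemizygous males (dose 0/2)
    contribute a single allele, females two.

    Returns ``(eaf, maf)``; raises if every dose is missing.
    """
    doses = np.asarray(doses, dtype=float)
    nonmiss = ~np.isnan(doses)
    if not nonmiss.any():
        raise ValueError("all doses missing")
    if male is None:
        male = np.zeros(doses.shape, dtype=bool)
    male = np.asarray(male, dtype=bool)
    weight = np.where(male, 0.5, 1.0)          # male dose 0/2 counts 1 allele
    alleles = np.where(male, 1.0, 2.0)
    count = np.nansum(doses * weight)
    total = (alleles * nonmiss).sum()
    eaf = count / total
    return eaf, min(eaf, 1.0 - eaf)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg equilibrium P value.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed the
    observed one. Monomorphic variants return 1 by convention.
    """
    for c in (n_hom_ref, n_het, n_hom_alt):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be non-negative integers")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0:
        return 1.0

    # Conditional distribution of the heterozygote count via the standard
    # recurrence, seeded at the modal count so probabilities only shrink
    # (no overflow at large n). Heterozygote counts share the parity of the
    # rare-allele count; feasible range is [n_rare % 2, n_rare].
    het_obs = n_het
    h_min, h_max = n_rare % 2, n_rare
    h_mode = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if h_mode % 2 != h_min % 2:
        h_mode += 1
    h_mode = min(max(h_mode, h_min), h_max)

    def counts_at(h):
        rare_hom = (n_rare - h) // 2
        return rare_hom, n - h - rare_hom

    probs = {h_mode: 1.0}
    h = h_mode
    while h - 2 >= h_min:           # downward: fewer heterozygotes
        rare_hom, common_hom = counts_at(h - 2)
        probs[h - 2] = probs[h] * h * (h - 1) / (
            4.0 * rare_hom * common_hom)
        h -= 2
    h = h_mode
    while h + 2 <= h_max:           # upward: more heterozygotes
        rare_hom, common_hom = counts_at(h)
        probs[h + 2] = probs[h] * 4.0 * rare_hom * common_hom / (
            (h + 1.0) * (h + 2.0))
        h += 2
    total = sum(probs.values())
    p_obs = probs.get(het_obs)
    if p_obs is None:
        raise ValueError("heterozygote count inconsistent with allele count "
                         "parity")
    tail = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    return min(1.0, tail / total)


def _genotype_counts(doses: np.ndarray) -> tuple:
    d = doses[~np.isnan(doses)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def qc_report(cohort: Cohort, thresholds: QcThresholds = QcThresholds()
              ) -> pd.DataFrame:
    """Per-variant QC metrics and pass/fail with failure reasons."""
    g, p = cohort.genotypes, cohort.phenotypes
    case = p.is_case()
    ctrl = ~case
    male = g.is_male()
    rows = []
    for j, rec in enumerate(g.variants):
        d = g.dose[:, j]
        miss = np.isnan(d)
        call_all = 1.0 - miss.mean()
        call_case = 1.0 - miss[case].mean() if case.any() else np.nan
        call_ctrl = 1.0 - miss[ctrl].mean() if ctrl.any() else np.nan
        diff_miss = abs(miss[case].mean() - miss[ctrl].mean())

        is_x = rec.chrom == "X"

        def _maf(mask):
            sub = d[mask]
            if np.isnan(sub).all():
                return np.nan, np.nan
            return compute_maf(sub, male[mask] if is_x else None)

        _, maf_all = _maf(np.ones_like(case))
        _, maf_case = _maf(case)
        _, maf_ctrl = _maf(ctrl)

        # control HWE; females only on X
        hwe_mask = ctrl & ~male if is_x else ctrl
        hwe_p = hwe_exact_test(*_genotype_counts(d[hwe_mask])) \
            if (~np.isnan(d[hwe_mask])).any() else np.nan

        reasons = []
        if 1.0 - call_all >= thresholds.max_missing:
            reasons.append("call_rate")
        if diff_miss >= thresholds.max_diff_missing:
            reasons.append("diff_missingness")
        if not np.isnan(maf_all) and maf_all <= thresholds.min_maf:
            reasons.append("maf")
        if not np.isnan(hwe_p) and hwe_p <= thresholds.min_hwe_p:
            reasons.append("hwe")
        rows.append({
            "id": rec.id, "chrom": rec.chrom, "pos": rec.pos,
            "call_rate": call_all, "call_rate_cases": call_case,
            "call_rate_controls": call_ctrl,
            "diff_missingness": diff_miss,
            "maf": maf_all, "maf_cases": maf_case, "maf_controls": maf_ctrl,
            "hwe_p_controls": hwe_p,
            "pass": not reasons, "fail_reasons": ";".join(reasons),
        })
    return pd.DataFrame(rows).set_index("id")


def apply_filters(cohort: Cohort,
                  thresholds: QcThresholds = QcThresholds()
                  ) -> tuple:
    """Drop variants failing any QC filter.

    Returns ``(filtered GenotypeMatrix, QcReport DataFrame)``; an empty
    result is allowed (a warning is attached to the report attrs).
    """
    report = qc_report(cohort, thresholds)
    keep = [j for j, vid in enumerate(cohort.genotypes.variant_ids)
            if report.loc[vid, "pass"]]
    filtered = cohort.genotypes.subset_variants(keep)
    if not keep:
        report.attrs["warning"] = "all variants removed by QC"
    return filtered, report
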
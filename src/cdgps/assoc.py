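"""Case-control allelic association.

Per-variant analysis of a binary phenotype contrast (phenotype-positive
cases vs population controls): 2x2 allele-count chi-squared (1 df, no
continuity correction), odds ratio with a 95% Woolf confidence interval,
a sex-adjusted logistic model reported alongside the crude OR, and the
Breslow-Day test of OR homogeneity across sex strata evaluated around the
Mantel-Haenszel common OR.

X-chromosome variants are never pooled across sexes: allele counts
accumulate per sex with hemizygous males contributing one allele, tests are
stratified by sex and combined by Mantel-Haenszel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import Cohort

Z_95 = stats.norm.ppf(0.975)   # 1.95996...


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Allele-count table: rows = group (1/2), columns = effect/other."""

    a: float  # effect-allele count, group 1
    b: float  # other-allele count, group 1
    c: float  # effect-allele count, group 2
    d: float  # other-allele count, group 2

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def margins_positive(self) -> bool:
        return (self.a + self.b > 0 and self.c + self.d > 0
                and self.a + self.c > 0 and self.b + self.d > 0)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class AssocResult:
    variant_id: str
    phenotype: str
    n_group1: int
    table: ContingencyTable2x2 | None
    or_: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    chi2: float = np.nan
    p_asymptotic: float = np.nan
    or_adjusted: float = np.nan
    p_adjusted: float = np.nan
    p_interaction: float = np.nan
    p_bd: float = np.nan
    or_mh: float = np.nan
    emp1: float = np.nan
    emp2: float = np.nan
    flags: list = field(default_factory=list)


def allele_table(doses, labels, sex=None, chrom: str = "1"
                 ) -> ContingencyTable2x2:
    """Build the 2x2 allele-count table for one variant.

    Group 1 is ``labels == 1``. Missing doses are excluded. On the X
    chromosome counts accumulate per sex, a hemizygous male (dose 0/2)
    contributing a single allele; the table returned is the sum over sexes
    (stratified tests use :func:`sex_stratified_tables` instead).
    """
    doses = np.asarray(doses, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~np.isnan(doses) & ~np.isnan(labels)
    doses, labels = doses[keep], labels[keep]
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("both label classes must be non-empty after "
                         "removing missing doses")
    if chrom == "X":
        if sex is None:
            raise ValueError("sex required for X-chromosome allele counts")
        male = np.asarray(sex)[keep] == "M"
        eff = np.where(male, doses / 2.0, doses)
        tot = np.where(male, 1.0, 2.0)
    else:
        eff, tot = doses, np.full_like(doses, 2.0)
    a = eff[labels == 1].sum()
    n1 = tot[labels == 1].sum()
    c = eff[labels == 0].sum()
    n0 = tot[labels == 0].sum()
    return ContingencyTable2x2(a, n1 - a, c, n0 - c)


def sex_stratified_tables(doses, labels, sex, chrom: str = "1") -> list:
    """Per-sex allele tables (strata with an empty label class dropped)."""
    sex = np.asarray(sex)
    tables = []
    for s in ("F", "M"):
        mask = sex == s
        if not mask.any():
            continue
        try:
            tables.append(allele_table(
                np.asarray(doses, dtype=float)[mask],
                np.asarray(labels, dtype=float)[mask],
                sex=sex[mask], chrom=chrom))
        except ValueError:
            continue
    return tables


def allelic_chi2(t: ContingencyTable2x2) -> tuple:
    """Pearson chi-squared (1 df, no continuity correction) and its P."""
    if not t.margins_positive:
        raise ValueError("chi-squared undefined: zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t.as_array(), correction=False)
    return float(chi2), float(p)


def odds_ratio_ci(t: ContingencyTable2x2, level: float = 0.95) -> tuple:
    """Odds ratio with Woolf (log-scale normal) confidence interval.

    A zero cell triggers the Haldane-Anscombe 0.5 correction on every cell;
    the returned tuple then carries ``corrected=True``.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return float(or_), float(lo), float(hi), corrected


def logistic_assoc(doses, labels, sex=None, interaction: bool = False,
                   maxiter: int = 100) -> dict:
    """Sex-adjusted logistic association for one variant.

    Fits ``logit(label) ~ dose [+ female] [+ dose x female]`` by maximum
    likelihood. Returns the per-allele odds ratio ``exp(beta_dose)``, its
    Wald P, the interaction P when requested, and diagnostic flags
    ('separation', 'non_convergence') instead of hard failures.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    doses = np.asarray(doses, dtype=float)
    labels = np.asarray(labels, dtype=float)
    keep = ~np.isnan(doses) & ~np.isnan(labels)
    X = [doses[keep]]
    names = ["dose"]
    if sex is not None:
        female = (np.asarray(sex)[keep] == "F").astype(float)
        X.append(female)
        names.append("female")
        if interaction:
            X.append(doses[keep] * female)
            names.append("dose_x_female")
    X = sm.add_constant(np.column_stack(X), has_constant="add")
    flags = []
    out = {"or_adjusted": np.nan, "p_adjusted": np.nan,
           "p_interaction": np.nan, "flags": flags}
    if np.linalg.matrix_rank(X) < X.shape[1]:
        flags.append("rank_deficient")
        return out
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(labels[keep], X).fit(disp=0, maxiter=maxiter)
        except (np.linalg.LinAlgError, PerfectSeparationError):
            flags.append("separation")
            return out
        for w in wlist:
            msg = str(w.message).lower()
            if "separation" in msg or "separated" in msg:
                flags.append("separation")
            if "convergence" in msg or "maximum" in msg:
                flags.append("non_convergence")
    if not fit.mle_retvals.get("converged", True):
        if "non_convergence" not in flags:
            flags.append("non_convergence")
    out["or_adjusted"] = float(np.exp(fit.params[1]))
    out["p_adjusted"] = float(fit.pvalues[1])
    if interaction and sex is not None:
        out["p_interaction"] = float(fit.pvalues[-1])
    return out


def mantel_haenszel_or(strata) -> float:
    """Mantel-Haenszel common odds ratio across 2x2 strata."""
    num = sum(t.a * t.d / (t.a + t.b + t.c + t.d) for t in strata)
    den = sum(t.b * t.c / (t.a + t.b + t.c + t.d) for t in strata)
    if den == 0:
        return np.inf if num > 0 else np.nan
    return num / den


def breslow_day(strata, tarone: bool = False) -> tuple:
    """Breslow-Day homogeneity test around the Mantel-Haenszel common OR.

    For each stratum the expected effect-allele count in group 1 given the
    margins and the common OR solves a quadratic; the statistic sums
    ``(a_k - A_k)^2 / Var(a_k)`` over strata with df = K - 1. Strata with a
    zero margin are dropped with a warning; fewer than two usable strata is
    an error. Returns ``(p_bd, common_or)``.
    """
    usable = [t for t in strata if t.margins_positive]
    if len(usable) < len(strata):
        warnings.warn(f"dropped {len(strata) - len(usable)} strata with a "
                      "zero margin from Breslow-Day test")
    if len(usable) < 2:
        raise ValueError("Breslow-Day requires >= 2 strata with positive "
                         "margins")
    or_mh = mantel_haenszel_or(usable)
    if not np.isfinite(or_mh) or or_mh == 0:
        return np.nan, or_mh

    def fitted_count(t):
        # expected group-1 effect-allele count given margins and common OR:
        # the admissible root of R*A^2 + S*A + T = 0
        n1, n0 = t.a + t.b, t.c + t.d
        m1 = t.a + t.c
        if or_mh == 1.0:
            return n1 * m1 / (n1 + n0), n1, n0, m1
        R = or_mh - 1.0
        S = (n1 + m1) * (1 - or_mh) - (n1 + n0)
        T = or_mh * n1 * m1
        disc = S * S - 4 * R * T
        a_fit = (-S - np.sqrt(disc)) / (2 * R)
        if not (max(0.0, m1 - n0) <= a_fit <= min(n1, m1)):
            a_fit = (-S + np.sqrt(disc)) / (2 * R)
        return a_fit, n1, n0, m1

    stat, resid_sum, var_sum = 0.0, 0.0, 0.0
    for t in usable:
        a_fit, n1, n0, m1 = fitted_count(t)
        var = 1.0 / (1.0 / a_fit + 1.0 / (n1 - a_fit) + 1.0 / (m1 - a_fit)
                     + 1.0 / (n0 - m1 + a_fit))
        stat += (t.a - a_fit) ** 2 / var
        resid_sum += t.a - a_fit
        var_sum += var
    if tarone:
        stat -= resid_sum ** 2 / var_sum
    p = float(stats.chi2.sf(stat, df=len(usable) - 1))
    return p, float(or_mh)


def cmh_chi2(strata) -> tuple:
    """Cochran-Mantel-Haenszel 1-df chi-squared across 2x2 strata."""
    num, den = 0.0, 0.0
    for t in strata:
        n = t.a + t.b + t.c + t.d
        n1, m1 = t.a + t.b, t.a + t.c
        num += t.a - n1 * m1 / n
        den += n1 * (n - n1) * m1 * (n - m1) / (n ** 2 * (n - 1))
    if den == 0:
        raise ValueError("CMH undefined: no information in strata")
    chi2 = num ** 2 / den
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class AssocConfig:
    min_events: int = 5          # contrasts with fewer events are not tested
    interaction: bool = False
    bd_alpha: float = 0.02       # homogeneity significance threshold


def phenotype_contrast(cohort: Cohort, phenotype: str) -> np.ndarray:
    """Labels for the contrast: phenotype-positive cases (1) vs controls (0).

    ``phenotype='status'`` contrasts all cases against controls. Cases
    lacking the phenotype (flag 0 or missing) are excluded (NaN label).
    """
    case = cohort.phenotypes.is_case()
    if phenotype == "status":
        return case.astype(float)
    flag = cohort.phenotypes.flag_values(phenotype)
    labels = np.full(len(case), np.nan)
    labels[~case] = 0.0
    labels[case & (flag == 1)] = 1.0
    return labels


def run_association(cohort: Cohort, phenotype: str,
                    config: AssocConfig = AssocConfig()) -> list:
    """Per-variant allelic association for one phenotype contrast.

    Autosomes: pooled allele table, chi-squared, Woolf-CI OR, sex-adjusted
    logistic OR, Breslow-Day across sexes. X chromosome: per-sex tables
    combined by Mantel-Haenszel (CMH chi-squared, MH OR), Breslow-Day
    across sexes; pooled male+female allele counts are never used.
    """
    labels = phenotype_contrast(cohort, phenotype)
    n_events = int(np.nansum(labels == 1))
    if n_events < config.min_events:
        raise ValueError(
            f"phenotype {phenotype!r} has {n_events} events; fewer than "
            f"{config.min_events} events are not tested")
    g = cohort.genotypes
    sex = g.sex
    results = []
    for j, rec in enumerate(g.variants):
        d = g.dose[:, j]
        res = AssocResult(rec.id, phenotype, n_events, table=None)
        strata = sex_stratified_tables(d, labels, sex, chrom=rec.chrom)
        try:
            if rec.chrom == "X":
                if len(strata) < 2:
                    res.flags.append("single_sex_stratum")
                    tbl = strata[0] if strata else None
                    if tbl is not None:
                        res.table = tbl
                        res.chi2, res.p_asymptotic = allelic_chi2(tbl)
                        res.or_, res.ci_low, res.ci_high, corr = \
                            odds_ratio_ci(tbl)
                        if corr:
                            res.flags.append("haldane_corrected")
                else:
                    res.table = allele_table(d, labels, sex=sex, chrom="X")
                    res.chi2, res.p_asymptotic = cmh_chi2(strata)
                    res.or_mh = mantel_haenszel_or(strata)
                    res.or_ = res.or_mh
                    import statsmodels.api as sm
                    st = sm.stats.StratifiedTable(
                        [t.as_array() for t in strata])
                    lo, hi = st.oddsratio_pooled_confint()
                    res.ci_low, res.ci_high = float(lo), float(hi)
            else:
                tbl = allele_table(d, labels)
                res.table = tbl
                res.chi2, res.p_asymptotic = allelic_chi2(tbl)
                res.or_, res.ci_low, res.ci_high, corr = odds_ratio_ci(tbl)
                if corr:
                    res.flags.append("haldane_corrected")
        except ValueError as exc:
            res.flags.append(f"table_error:{exc}")
            results.append(res)
            continue

        keep = ~np.isnan(labels)
        fit = logistic_assoc(d[keep], labels[keep], sex=sex[keep],
                             interaction=config.interaction)
        res.or_adjusted = fit["or_adjusted"]
        res.p_adjusted = fit["p_adjusted"]
        res.p_interaction = fit["p_interaction"]
        res.flags.extend(fit["flags"])

        if len(strata) >= 2:
            try:
                res.p_bd, or_mh = breslow_day(strata)
                if np.isnan(res.or_mh):
                    res.or_mh = or_mh
            except ValueError:
                res.flags.append("bd_unavailable")
        results.append(res)
    return results


def results_to_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "id": r.variant_id, "phenotype": r.phenotype,
            "n_group1": r.n_group1,
            "a": r.table.a if r.table else np.nan,
            "b": r.table.b if r.table else np.nan,
            "c": r.table.c if r.table else np.nan,
            "d": r.table.d if r.table else np.nan,
            "or": r.or_, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "chi2": r.chi2, "p": r.p_asymptotic,
            "or_adjusted": r.or_adjusted, "p_adjusted": r.p_adjusted,
            "p_interaction": r.p_interaction,
            "p_bd": r.p_bd, "or_mh": r.or_mh,
            "emp1": r.emp1, "emp2": r.emp2,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)
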
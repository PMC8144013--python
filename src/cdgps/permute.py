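"""Label-permutation empirical P values (pointwise EMP1, family-wise EMP2).

Phenotype labels are shuffled among samples (optionally within strata such
as sex, preserving the covariate-genotype relation) while genotypes stay
fixed; the family statistic is recomputed for every permutation and

    EMP1_v = (1 + #{r : T_v^(r) >= T_v}) / (R + 1)
    EMP2_v = (1 + #{r : max_w T_w^(r) >= T_v}) / (R + 1)

The "+1" estimator never returns zero. EMP2 is the family-wise max(T)
correction: the family is every variant tested against the given phenotype.

The permuted statistic is the allelic chi-squared computed from allele
counts (cheap and fully vectorisable as a matrix product over permutation
indicator columns); X-chromosome variants contribute per-sex allele counts
with hemizygous males counting one allele. A permutation in which a
variant's table has a zero margin gets statistic 0 for that variant, with a
tally reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .genio import Cohort
from .assoc import AssocConfig, phenotype_contrast


@dataclass
class PermutationPlan:
    n_perm: int = 10000
    seed: int = 0
    strata: np.ndarray | None = None   # per-sample stratum labels
    exhaustive: bool = False

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class PermutationResult:
    emp1: np.ndarray
    emp2: np.ndarray
    observed: np.ndarray
    n_perm: int
    n_undefined: np.ndarray    # per-variant tally of zero-margin permutations
    exhaustive: bool = False


def _effective_counts(doses, sex, chroms):
    """Per-sample effective allele dose and allele multiplicity.

    Autosomes: (dose, 2); X-chromosome males: (dose/2, 1); missing: (0, 0).
    """
    doses = np.asarray(doses, dtype=float)
    n, v = doses.shape
    eff = doses.copy()
    mult = np.full((n, v), 2.0)
    if chroms is not None and sex is not None:
        x_cols = np.asarray([c == "X" for c in chroms])
        if x_cols.any():
            male = (np.asarray(sex) == "M")[:, None] & x_cols[None, :]
            eff[male] /= 2.0
            mult[male] = 1.0
    miss = np.isnan(doses)
    eff[miss] = 0.0
    mult[miss] = 0.0
    return eff, mult


def _chi2_from_counts(a, n1, A, N):
    """Vectorised Pearson chi-squared for allele-count 2x2 tables.

    Zero-margin tables yield statistic 0 (mask returned separately).
    """
    b = n1 - a
    c = A - a
    d = (N - n1) - c
    denom = n1 * (N - n1) * A * (N - A)
    undefined = denom <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = N * (a * d - b * c) ** 2 / denom
    chi2 = np.where(undefined, 0.0, chi2)
    return chi2, undefined


def _permuted_labels(labels, plan, rng):
    """Label matrix (n x R), shuffled within strata when given."""
    n = labels.size
    out = np.empty((n, plan.n_perm))
    if plan.strata is None:
        for r in range(plan.n_perm):
            out[:, r] = rng.permutation(labels)
    else:
        strata = np.asarray(plan.strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
        for r in range(plan.n_perm):
            col = np.empty(n)
            for idx in groups:
                col[idx] = rng.permutation(labels[idx])
            out[:, r] = col
    return out


def empirical_p(doses, labels, plan: PermutationPlan,
                sex=None, chroms=None) -> PermutationResult:
    """EMP1/EMP2 for a family of variants against one binary label vector.

    Parameters
    ----------
    doses
        (n_samples, n_variants) effect-allele doses; NaN = missing.
    labels
        Binary 0/1 per sample (no missing; exclude those samples first).
    plan
        Permutation count, seed, optional within-strata shuffling, or
        exhaustive enumeration of all label assignments (small n only).
    sex, chroms
        Optional per-sample sex and per-variant chromosome, for the
        X-chromosome allele-counting rule.
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    labels = np.asarray(labels, dtype=float)
    if doses.shape[1] == 0:
        raise ValueError("empty variant family")
    if np.isnan(labels).any():
        raise ValueError("labels must not be missing; subset samples first")

    eff, mult = _effective_counts(doses, sex, chroms)
    A = eff.sum(axis=0)            # total effect-allele count per variant
    N = mult.sum(axis=0)           # total allele count per variant

    a_obs = eff.T @ labels
    n1_obs = mult.T @ labels
    t_obs, _ = _chi2_from_counts(a_obs, n1_obs, A, N)

    if plan.exhaustive:
        if plan.strata is not None:
            raise NotImplementedError("exhaustive enumeration does not "
                                      "support strata")
        n = labels.size
        k = int(labels.sum())
        from math import comb
        total = comb(n, k)
        if total > 500_000:
            raise ValueError(f"exhaustive enumeration infeasible: "
                             f"C({n},{k}) = {total}")
        P = np.zeros((n, total))
        for r, pos in enumerate(combinations(range(n), k)):
            P[list(pos), r] = 1.0
        a = eff.T @ P
        n1 = mult.T @ P
        t_perm, undef = _chi2_from_counts(a, n1, A[:, None], N[:, None])
        tol = 1e-12
        emp1 = (t_perm >= t_obs[:, None] - tol).sum(axis=1) / total
        colmax = t_perm.max(axis=0)
        emp2 = np.array([(colmax >= t - tol).sum() / total for t in t_obs])
        return PermutationResult(emp1, emp2, t_obs, total,
                                 undef.sum(axis=1), exhaustive=True)

    rng = np.random.default_rng(plan.seed)
    P = _permuted_labels(labels, plan, rng)
    a = eff.T @ P
    n1 = mult.T @ P
    t_perm, undef = _chi2_from_counts(a, n1, A[:, None], N[:, None])
    tol = 1e-12
    R = plan.n_perm
    emp1 = (1.0 + (t_perm >= t_obs[:, None] - tol).sum(axis=1)) / (R + 1.0)
    colmax = t_perm.max(axis=0)
    emp2 = (1.0 + (colmax[None, :] >= t_obs[:, None] - tol).sum(axis=1)) \
        / (R + 1.0)
    return PermutationResult(emp1, emp2, t_obs, R, undef.sum(axis=1))


def attach_empirical(results, cohort: Cohort, phenotype: str,
                     plan: PermutationPlan,
                     config: AssocConfig = AssocConfig()):
    """Fill ``emp1``/``emp2`` on association results for one phenotype.

    The permuted contrast is the one :func:`run_association` tested:
    phenotype-positive cases vs controls, samples with undefined labels
    excluded. Returns the underlying :class:`PermutationResult`.
    """
    labels = phenotype_contrast(cohort, phenotype)
    keep = ~np.isnan(labels)
    g = cohort.genotypes
    ids = [r.variant_id for r in results]
    vidx = g.variant_index()
    cols = [vidx[i] for i in ids]
    plan_sub = plan
    if plan.strata is not None:
        plan_sub = PermutationPlan(plan.n_perm, plan.seed,
                                   np.asarray(plan.strata)[keep],
                                   plan.exhaustive)
    perm = empirical_p(
        g.dose[np.ix_(keep, cols)], labels[keep], plan_sub,
        sex=g.sex[keep], chroms=[g.variants[c].chrom for c in cols])
    for r, e1, e2 in zip(results, perm.emp1, perm.emp2):
        r.emp1 = float(e1)
        r.emp2 = float(e2)
    return perm
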
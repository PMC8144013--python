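"""Weighted genetic risk score (wGRS) and control-derived tertile analysis.

The per-sample score is the average weighted risk-allele dose:

    score = sum_v dose_v * beta_v / (2 * n_used)

with beta = ln(OR) of each risk variant and n_used the number of variants
with a non-missing dose for that sample (missing variants leave both the
numerator and the denominator). Tertile cutpoints come from the *control*
score distribution only (linear-interpolation quantiles at 33.33% and
66.67%); every sample - case or control - is then assigned low / medium /
high against those control cutpoints, and each phenotype contrast is tested
with a sex-adjusted logistic model comparing medium and high tertiles to
the low reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import Cohort
from .assoc import phenotype_contrast

TERTILE_LABELS = ("low", "medium", "high")


@dataclass
class GrsProfiles:
    """Per-sample wGRS with tertile assignment and scoring metadata."""

    table: pd.DataFrame            # index sample; score, n_used, tertile
    cutpoints: tuple               # (t1, t2) from controls
    quantile_method: str = "linear"


def wgrs(doses, betas) -> tuple:
    """Average weighted risk-allele dose per sample.

    Parameters
    ----------
    doses
        (n_samples, n_variants) doses aligned to the weight table's effect
        alleles; NaN = missing.
    betas
        Per-variant ln(OR) weights, same variant order as ``doses``.

    Returns ``(score, n_used)`` arrays. A sample with every dose missing is
    an error (its score would be 0/0).
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    betas = np.asarray(betas, dtype=float)
    if doses.shape[1] != betas.size:
        raise ValueError("doses and betas disagree on variant count")
    nonmiss = ~np.isnan(doses)
    n_used = nonmiss.sum(axis=1)
    if (n_used == 0).any():
        bad = np.flatnonzero(n_used == 0)
        raise ValueError(f"samples with no scored variants: rows "
                         f"{bad.tolist()}")
    num = np.nansum(doses * betas[None, :], axis=1)
    return num / (2.0 * n_used), n_used


def control_tertiles(control_scores) -> tuple:
    """Tertile cutpoints (33.33% / 66.67% linear-interpolation quantiles).

    Computed from control scores only; degenerate distributions (t1 == t2)
    produce a warning, the medium class may then be empty.
    """
    scores = np.asarray(control_scores, dtype=float)
    if scores.size < 3:
        raise ValueError("need >= 3 control scores for tertiles")
    t1, t2 = np.quantile(scores, [1.0 / 3.0, 2.0 / 3.0], method="linear")
    if t1 == t2:
        warnings.warn("degenerate control score distribution: tertile "
                      "cutpoints coincide; medium class may be empty")
    return float(t1), float(t2)


def assign_tertiles(scores, cutpoints) -> np.ndarray:
    """low if score <= t1, medium if t1 < score <= t2, high otherwise."""
    t1, t2 = cutpoints
    scores = np.asarray(scores, dtype=float)
    out = np.where(scores <= t1, "low",
                   np.where(scores <= t2, "medium", "high"))
    return out.astype("<U6")


def profile_cohort(cohort: Cohort, weights: pd.DataFrame) -> GrsProfiles:
    """Score every cohort sample and assign control-derived tertiles.

    ``weights`` must already be aligned (see
    :func:`cdgps.genio.align_to_effect_allele`); variants are matched by id
    and the weight-table order defines the scored set.
    """
    g = cohort.genotypes
    vidx = g.variant_index()
    cols = [vidx[v] for v in weights["id"]]
    score, n_used = wgrs(g.dose[:, cols], weights["beta"].to_numpy())
    ctrl = ~cohort.phenotypes.is_case()
    cuts = control_tertiles(score[ctrl])
    table = pd.DataFrame(
        {"score": score, "n_used": n_used,
         "tertile": assign_tertiles(score, cuts)},
        index=pd.Index(g.samples, name="sample"))
    return GrsProfiles(table, cuts)


def tertile_assoc(profiles: GrsProfiles, labels, sex,
                  min_ref_events: int = 5) -> pd.DataFrame:
    """Medium- and high-vs-low tertile ORs from a sex-adjusted logistic fit.

    ``labels`` is the binary contrast (1 = phenotype-positive case,
    0 = control, NaN = excluded). Contrasts with fewer than
    ``min_ref_events`` events in the low (reference) tertile are skipped:
    the returned frame then carries a ``skip_reason`` attr and no rows.
    """
    import statsmodels.api as sm

    labels = np.asarray(labels, dtype=float)
    tert = profiles.table["tertile"].to_numpy()
    keep = ~np.isnan(labels)
    y = labels[keep]
    t = tert[keep]
    female = (np.asarray(sex)[keep] == "F").astype(float)

    ref_events = int(y[t == "low"].sum())
    out = pd.DataFrame(columns=["tertile", "n", "events", "or", "ci_low",
                                "ci_high", "p"])
    if ref_events < min_ref_events:
        out.attrs["skip_reason"] = (
            f"{ref_events} events in reference tertile "
            f"(< {min_ref_events}); not tested")
        return out

    X = sm.add_constant(np.column_stack([
        (t == "medium").astype(float),
        (t == "high").astype(float),
        female,
    ]), has_constant="add")
    fit = sm.Logit(y, X).fit(disp=0)
    ci = fit.conf_int()
    rows = []
    for k, name in ((1, "medium"), (2, "high")):
        rows.append({
            "tertile": name,
            "n": int((t == name).sum()),
            "events": int(y[t == name].sum()),
            "or": float(np.exp(fit.params[k])),
            "ci_low": float(np.exp(ci[k][0])),
            "ci_high": float(np.exp(ci[k][1])),
            "p": float(fit.pvalues[k]),
        })
    res = pd.DataFrame(rows)
    res.attrs["reference"] = {"tertile": "low",
                              "n": int((t == "low").sum()),
                              "events": ref_events}
    return res


def tertile_assoc_phenotype(cohort: Cohort, profiles: GrsProfiles,
                            phenotype: str,
                            min_ref_events: int = 5) -> pd.DataFrame:
    """Tertile OR table for one named phenotype contrast."""
    labels = phenotype_contrast(cohort, phenotype)
    return tertile_assoc(profiles, labels, cohort.genotypes.sex,
                         min_ref_events=min_ref_events)
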
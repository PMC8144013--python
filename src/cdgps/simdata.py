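"""Synthetic case-control cohorts with the structure the analysis assumes.

Genotypes are drawn under Hardy-Weinberg equilibrium at stated minor-allele
frequencies; optional LD blocks are generated at the genotype (composite)
level through a one-factor Gaussian-copula threshold model on haplotypes,
calibrated so pairwise dose r^2 hits a target. X-chromosome males receive a
single allele (dose coded 0/2); missingness is injected completely at
random. Disease status follows an additive logistic liability

    logit P(case) = intercept + sum_v beta_v * dose_v + beta_sex * female

with rejection sampling to hit exact case/control quotas, and sub-phenotype
flags are drawn among cases from their own logistic models (optionally
defined for only a random subset, mirroring partial phenotype
availability). Every draw flows from one root seed, so outputs are
reproducible byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

from . import datasets
from .genio import (GenotypeMatrix, PhenotypeTable, VariantRecord,
                    write_genotypes)


@dataclass(frozen=True)
class SimVariant:
    id: str
    chrom: str
    pos: int
    maf: float
    beta_disease: float = 0.0
    beta_phenotypes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"{self.id}: MAF must be in (0, 0.5]")


@dataclass(frozen=True)
class PhenoModel:
    """Logistic model for one sub-phenotype flag drawn among cases."""

    intercept: float
    beta_sex: float = 0.0
    beta_age: float = 0.0          # per year, age centred at 40
    availability: float = 1.0      # fraction of cases with the flag defined


@dataclass
class SimConfig:
    n_cases: int = 625
    n_controls: int = 1817
    variants: list = field(default_factory=list)
    ld_blocks: list = field(default_factory=list)   # (ids, target_r2)
    sex_ratio: float = 0.5          # female fraction of the source pool
    beta_sex: float = 1.27          # disease log-OR for female (78% female cases)
    intercept: float = -3.0         # baseline disease logit (~5% prevalence)
    phenotype_models: dict = field(default_factory=dict)
    missing_rate: float = 0.0
    age_range: tuple = (0.5, 79.0)  # uniform, years
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for _, r2 in self.ld_blocks:
            if not 0 <= r2 < 1:
                raise ValueError("target r^2 must be in [0, 1)")


@dataclass
class SimTruth:
    """Generating parameters and latent liabilities of a realised cohort."""

    config: SimConfig
    liability: np.ndarray          # disease logit per retained sample
    case_prob: np.ndarray


def _latent_rho_for_r(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation giving allele correlation ``target_r``.

    One-factor threshold model: allele = 1 if latent normal < Phi^-1(maf);
    the allele (and dose) correlation induced by latent correlation rho is
    (Phi_2(z, z; rho) - p^2) / (p (1 - p)). Solved by root finding; a target
    unreachable even at rho = 0.999 is an error.
    """
    if target_r == 0:
        return 0.0
    z = sps.norm.ppf(maf)
    var = maf * (1 - maf)

    def allele_corr(rho):
        cdf = sps.multivariate_normal.cdf(
            [z, z], mean=[0, 0], cov=[[1, rho], [rho, 1]])
        return (cdf - maf ** 2) / var

    hi = 0.999
    if allele_corr(hi) < target_r:
        raise ValueError(f"target r^2 {target_r**2:.3f} infeasible at "
                         f"MAF {maf}")
    return brentq(lambda rho: allele_corr(rho) - target_r, 0.0, hi,
                  xtol=1e-6)


def simulate_genotypes(cfg: SimConfig, n_samples: int | None = None,
                       sex: np.ndarray | None = None,
                       rng: np.random.Generator | None = None
                       ) -> GenotypeMatrix:
    """Draw a genotype matrix under HWE with optional LD blocks.

    ``sex`` defaults to draws at ``cfg.sex_ratio`` (female fraction);
    X-chromosome males get one allele. Missingness is applied last, MCAR at
    ``cfg.missing_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if n_samples is None:
        n_samples = cfg.n_cases + cfg.n_controls
    if sex is None:
        sex = np.where(rng.random(n_samples) < cfg.sex_ratio, "F", "M")
    sex = np.asarray(sex, dtype="<U1")
    male = sex == "M"

    v = len(cfg.variants)
    vindex = {sv.id: j for j, sv in enumerate(cfg.variants)}
    in_block = set()
    for ids, _ in cfg.ld_blocks:
        in_block.update(ids)

    dose = np.empty((n_samples, v))
    # independent variants
    for j, sv in enumerate(cfg.variants):
        if sv.id in in_block:
            continue
        if sv.chrom == "X":
            d = rng.binomial(2, sv.maf, n_samples).astype(float)
            d[male] = 2.0 * rng.binomial(1, sv.maf, male.sum())
            dose[:, j] = d
        else:
            dose[:, j] = rng.binomial(2, sv.maf, n_samples)

    # LD blocks: one shared factor per haplotype, threshold per variant
    for ids, target_r2 in cfg.ld_blocks:
        cols = [vindex[i] for i in ids]
        mafs = [cfg.variants[vindex[i]].maf for i in ids]
        rho = _latent_rho_for_r(np.sqrt(target_r2), float(np.mean(mafs)))
        block = np.zeros((n_samples, len(cols)))
        for _hap in range(2):
            f = rng.standard_normal(n_samples)
            e = rng.standard_normal((n_samples, len(cols)))
            z = np.sqrt(rho) * f[:, None] + np.sqrt(1 - rho) * e
            thresh = sps.norm.ppf(mafs)
            block += (z < thresh[None, :]).astype(float)
        for k, (j, i) in enumerate(zip(cols, ids)):
            if cfg.variants[vindex[i]].chrom == "X":
                raise ValueError(f"LD block {ids} contains an X variant; "
                                 "blocks are autosomal only")
            dose[:, j] = block[:, k]

    if cfg.missing_rate > 0:
        mask = rng.random(dose.shape) < cfg.missing_rate
        dose[mask] = np.nan

    variants = [VariantRecord(sv.id, sv.chrom, sv.pos, "A", "G")
                for sv in cfg.variants]
    samples = [f"s{i:05d}" for i in range(n_samples)]
    return GenotypeMatrix(samples, variants, dose, sex)


def disease_liability(g: GenotypeMatrix, cfg: SimConfig) -> np.ndarray:
    """Additive disease logit per sample (missing doses count 0)."""
    betas = np.array([sv.beta_disease for sv in cfg.variants])
    d = np.nan_to_num(g.dose, nan=0.0)
    female = (g.sex == "F").astype(float)
    return cfg.intercept + d @ betas + cfg.beta_sex * female


def simulate_phenotypes(g: GenotypeMatrix, cfg: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> PhenotypeTable:
    """Assign case/control status and sub-phenotype flags to a genotype pool.

    Status is Bernoulli from the additive logistic liability; the pool must
    yield at least ``n_cases`` cases and ``n_controls`` controls in one
    draw, otherwise a ValueError suggests enlarging the pool or raising the
    intercept (:func:`simulate_cohort` handles the retry loop). Flags are
    drawn among cases only; controls carry NaN flags.
    """
    import pandas as pd

    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    eta = disease_liability(g, cfg)
    p = 1.0 / (1.0 + np.exp(-eta))
    is_case = rng.random(g.n_samples) < p
    n_case, n_ctrl = int(is_case.sum()), int((~is_case).sum())
    if n_case < cfg.n_cases or n_ctrl < cfg.n_controls:
        raise ValueError(
            f"pool produced {n_case} cases / {n_ctrl} controls; need "
            f"{cfg.n_cases}/{cfg.n_controls} - enlarge the pool or adjust "
            "the intercept")
    case_idx = np.flatnonzero(is_case)[:cfg.n_cases]
    ctrl_idx = np.flatnonzero(~is_case)[:cfg.n_controls]
    keep = np.concatenate([case_idx, ctrl_idx])

    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi, keep.size)
    status = np.array(["case"] * cfg.n_cases + ["control"] * cfg.n_controls)
    tab = pd.DataFrame({
        "status": status,
        "sex": g.sex[keep],
        "age": age,
        "age_at_diagnosis": age,
    }, index=pd.Index([g.samples[i] for i in keep], name="sample"))

    d = np.nan_to_num(g.dose[keep], nan=0.0)
    female = (g.sex[keep] == "F").astype(float)
    case_mask = status == "case"
    for name, model in cfg.phenotype_models.items():
        betas = np.array([sv.beta_phenotypes.get(name, 0.0)
                          for sv in cfg.variants])
        eta_f = (model.intercept + d @ betas + model.beta_sex * female
                 + model.beta_age * (age - 40.0))
        pf = 1.0 / (1.0 + np.exp(-eta_f))
        flag = (rng.random(keep.size) < pf).astype(float)
        flag[~case_mask] = np.nan
        if model.availability < 1.0:
            unavail = case_mask & (rng.random(keep.size)
                                   > model.availability)
            flag[unavail] = np.nan
        tab[name] = flag

    tab.attrs["liability"] = eta[keep]
    return PhenotypeTable(tab)


def simulate_cohort(cfg: SimConfig, pool_factor: float = 3.0,
                    max_attempts: int = 50) -> tuple:
    """Generate a full cohort: genotypes, phenotypes and the truth manifest.

    Draws genotype pools of growing size until the Bernoulli status draw
    meets both quotas, then trims to exactly ``n_cases + n_controls``
    samples (cases first). Returns ``(GenotypeMatrix, PhenotypeTable,
    SimTruth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_target = cfg.n_cases + cfg.n_controls
    pool = max(int(pool_factor * n_target), 200)
    for attempt in range(max_attempts):
        g = simulate_genotypes(cfg, n_samples=pool, rng=rng)
        try:
            pheno = simulate_phenotypes(g, cfg, rng=rng)
        except ValueError:
            pool = int(pool * 1.5)
            continue
        keep_ids = pheno.samples
        id_to_row = {s: i for i, s in enumerate(g.samples)}
        keep = [id_to_row[s] for s in keep_ids]
        g_kept = g.subset_samples(keep)
        eta = disease_liability(g_kept, cfg)
        truth = SimTruth(cfg, eta, 1.0 / (1.0 + np.exp(-eta)))
        return g_kept, pheno, truth
    raise ValueError(f"could not reach {cfg.n_cases} cases / "
                     f"{cfg.n_controls} controls in {max_attempts} attempts; "
                     "adjust the intercept")


# ---------------------------------------------------------------------------
# Canned fixtures
# ---------------------------------------------------------------------------

def paper_shape_config(seed: int = 0, missing_rate: float = 0.0) -> SimConfig:
    """A 625-case / 1817-control cohort at 39 SNPs.

    The ten published risk variants keep their printed control MAFs, real
    chromosomes and ln(OR) disease effects; 29 filler variants span a
    realistic frequency range with null effects. Sub-phenotype flag models
    target the published marginal rates among cases.
    """
    pv = datasets.PUBLISHED_VARIANTS
    positions = datasets.published_variant_positions()
    variants = []
    for _, row in pv.iterrows():
        variants.append(SimVariant(
            row["id"], row["chrom"], positions[row["id"]],
            min(row["maf_controls"], 0.5),
            beta_disease=float(np.log(
                datasets.REPRESENTATIVE_OR[row["id"]])),
            beta_phenotypes={},
        ))
    n_filler = 39 - len(variants)
    for k in range(n_filler):
        chrom = str((k % 20) + 1)
        maf = 0.05 + 0.45 * (k + 0.5) / n_filler
        variants.append(SimVariant(f"snpF{k + 11:02d}", chrom,
                                   50_000_000 + 2_000_000 * k, round(maf, 3)))

    def rate_model(flag, beta_sex=0.0, availability=1.0):
        pos, avail = datasets.PHENOTYPE_COUNTS[flag]
        rate = pos / avail
        return PhenoModel(intercept=float(np.log(rate / (1 - rate))),
                          beta_sex=beta_sex, availability=availability)

    models = {
        "childhood_symptoms": rate_model("childhood_symptoms"),
        "gi_symptoms": rate_model("gi_symptoms"),
        "malabsorption": rate_model("malabsorption"),
        "anaemia": rate_model("anaemia"),
        "tva_sva": rate_model("tva_sva", availability=546 / 625),
        "dh": rate_model("dh"),
        "fractures": rate_model("fractures"),
        "t1d": rate_model("t1d"),
    }
    return SimConfig(n_cases=625, n_controls=1817, variants=variants,
                     phenotype_models=models, missing_rate=missing_rate,
                     seed=seed)


def tiny_config(seed: int = 0) -> SimConfig:
    variants = [
        SimVariant("snp1", "1", 1_000_000, 0.3,
                   beta_disease=float(np.log(1.5))),
        SimVariant("snp2", "2", 2_000_000, 0.2),
        SimVariant("snp3", "3", 3_000_000, 0.4),
    ]
    return SimConfig(n_cases=8, n_controls=12, variants=variants,
                     intercept=-1.0, seed=seed)


def ld_demo_config(seed: int = 0, n_samples_factor: float = 1.0) -> SimConfig:
    """Fifty variants in five 10-variant LD blocks for clumping tests.

    Each block sits inside one 250 kb window (20 kb spacing) with
    exchangeable target r^2; blocks are far apart on two chromosomes.
    """
    variants, blocks = [], []
    targets = (0.6, 0.3, 0.8, 0.5, 0.1)
    for b in range(5):
        ids = [f"b{b}v{j}" for j in range(10)]
        maf = 0.15 + 0.07 * b
        chrom = "1" if b < 3 else "2"
        base = 10_000_000 + b * 10_000_000
        for j, vid in enumerate(ids):
            variants.append(SimVariant(vid, chrom, base + 20_000 * j, maf))
        blocks.append((tuple(ids), targets[b]))
    return SimConfig(n_cases=250, n_controls=750, variants=variants,
                     ld_blocks=blocks, intercept=-1.2,
                     phenotype_models={"flagA": PhenoModel(intercept=-0.8)},
                     seed=seed)


def _demo_sumstats(cfg: SimConfig, rng: np.random.Generator):
    """Deterministic summary statistics over a config's variants."""
    import pandas as pd

    rows = []
    for sv in cfg.variants:
        rows.append({
            "id": sv.id, "chrom": sv.chrom, "pos": sv.pos,
            "effect_allele": "A",
            "beta": round(float(rng.normal(0, 0.15)), 4),
            "p": round(float(rng.uniform(1e-8, 1.0)), 10),
        })
    return pd.DataFrame(rows)


def make_fixture(name: str, outdir, seed: int = 0) -> dict:
    """Write a reproducible on-disk dataset in the TSV dialect.

    Names: ``paper-shape`` (625/1817 x 39, published control MAFs),
    ``tiny`` (20 x 3, for doc examples), ``ld-demo`` (50 variants in 5 LD
    blocks plus a summary-statistics table for clumping tests). Returns the
    paths written. Identical seeds give byte-identical files.
    """
    os.makedirs(outdir, exist_ok=True)
    factory = {"paper-shape": paper_shape_config, "tiny": tiny_config,
               "ld-demo": ld_demo_config}
    if name not in factory:
        raise ValueError(f"unknown fixture {name!r}")
    cfg = factory[name](seed=seed)
    g, pheno, truth = simulate_cohort(cfg)
    paths = {}
    geno_path = os.path.join(outdir, f"{name}.tsv")
    write_genotypes(g, geno_path, format="tsv")
    paths["genotypes"] = geno_path
    paths["variants"] = os.path.splitext(geno_path)[0] + ".variants.tsv"
    pheno_path = os.path.join(outdir, f"{name}.pheno.tsv")
    pheno.to_tsv(pheno_path)
    paths["phenotypes"] = pheno_path
    if name == "ld-demo":
        ss = _demo_sumstats(cfg, np.random.default_rng(cfg.seed + 17))
        ss_path = os.path.join(outdir, f"{name}.sumstats.tsv")
        ss.to_csv(ss_path, sep="\t", index=False)
        paths["sumstats"] = ss_path
    cfg_path = os.path.join(outdir, f"{name}.config.json")
    with open(cfg_path, "w") as fh:
        json.dump(_config_echo(cfg), fh, indent=1, sort_keys=True)
    paths["config"] = cfg_path
    return paths


def _config_echo(cfg: SimConfig) -> dict:
    echo = asdict(cfg)
    echo["variants"] = [asdict(v) for v in cfg.variants]
    echo["ld_blocks"] = [[list(ids), r2] for ids, r2 in cfg.ld_blocks]
    echo["phenotype_models"] = {k: asdict(m)
                                for k, m in cfg.phenotype_models.items()}
    return echo
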
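"""Genotype, phenotype, weight and summary-statistics I/O.

Containers are deliberately thin: doses live in a float ndarray with NaN as
the missing sentinel, phenotypes in a pandas DataFrame indexed by sample id.
Three genotype dialects are supported: PLINK text (.ped/.map), a plain TSV
dosage table (rows = samples, columns = variant ids, ``sample``/``sex``/
``status`` columns reserved) and VCF (GT field only, read via cyvcf2).

Conventions
-----------
* Doses count the *effect* allele (``allele_a``); re-orientation against a
  weight table is an explicit step (:func:`align_to_effect_allele`).
* X-chromosome hemizygous males carry dose 0 or 2 (allele-count scale);
  stratified analyses downstream never pool male and female X doses.
* Positions are 1-based; genomic windows are closed intervals in basepairs.
* No strand inference: an effect allele matching neither genotype allele is
  a hard error.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = np.nan

AUTOSOMES = {str(i) for i in range(1, 23)}
VALID_CHROMS = AUTOSOMES | {"X"}

_SEX_CODES = {
    "1": "M", "2": "F", "0": "U",
    "M": "M", "F": "F", "U": "U",
    "male": "M", "female": "F", "unknown": "U",
}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class AlleleMismatchError(ValueError):
    """Effect allele matches neither genotype allele for listed variants."""

    def __init__(self, variants):
        self.variants = list(variants)
        super().__init__(
            "effect allele matches neither genotype allele for: "
            + ", ".join(self.variants)
        )


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant; ``allele_a`` is the effect (counted) allele."""

    id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.id}: alleles must differ")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dose counts.

    ``dose`` is float with values in {0, 1, 2, NaN}; for chromosome-X males
    the dose is in {0, 2, NaN} (hemizygote coded on the allele-count scale).
    """

    samples: list
    variants: list
    dose: np.ndarray
    sex: np.ndarray  # per-sample, 'M' / 'F' / 'U'

    def __post_init__(self):
        self.dose = np.asarray(self.dose, dtype=float)
        self.sex = np.asarray(self.sex, dtype="<U1")
        n, v = self.dose.shape
        if n != len(self.samples) or v != len(self.variants):
            raise ValueError("dose shape does not match samples x variants")
        ids = [rec.id for rec in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant id")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list:
        return [rec.id for rec in self.variants]

    def variant_index(self) -> dict:
        return {rec.id: j for j, rec in enumerate(self.variants)}

    def is_male(self) -> np.ndarray:
        return self.sex == "M"

    def x_mask(self) -> np.ndarray:
        return np.array([rec.chrom == "X" for rec in self.variants])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples), list(self.variants),
            self.dose.copy(), self.sex.copy(),
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], list(self.variants),
            self.dose[idx], self.sex[idx],
        )

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            list(self.samples), [self.variants[j] for j in idx],
            self.dose[:, idx], self.sex.copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-sample case/control status, binary phenotype flags and covariates.

    ``table`` is indexed by sample id with a ``status`` column taking values
    'case'/'control', a ``sex`` column ('M'/'F'/'U'), optional ``age`` and
    ``age_at_diagnosis`` (years), and any number of {0, 1, NaN} flag columns.
    Flags are missing-aware: NaN means the phenotype is undefined for that
    sample (e.g. mucosal morphology recorded for a subset only).
    """

    table: pd.DataFrame

    RESERVED = ("status", "sex", "age", "age_at_diagnosis")

    def __post_init__(self):
        if "status" not in self.table.columns:
            raise ValueError("phenotype table requires a 'status' column")
        bad = set(self.table["status"].dropna()) - {"case", "control"}
        if bad:
            raise ValueError(f"invalid status values: {sorted(bad)}")

    @property
    def samples(self) -> list:
        return list(self.table.index)

    @property
    def flags(self) -> list:
        return [c for c in self.table.columns if c not in self.RESERVED]

    def is_case(self) -> np.ndarray:
        return (self.table["status"] == "case").to_numpy()

    def flag_values(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"unknown phenotype flag {name!r}")
        return self.table[name].to_numpy(dtype=float)

    def summary(self, among: str | None = "case") -> pd.DataFrame:
        """Marginal counts and percentages per flag, missing-aware.

        Percentages use the number of samples for which the flag is defined
        as denominator (partial denominators are common: a morphology grade
        may exist only for biopsied patients). ``among`` restricts to cases
        (default), controls, or everyone (None).
        """
        tab = self.table
        if among is not None:
            tab = tab[tab["status"] == among]
        rows = []
        n_female = int((tab["sex"] == "F").sum())
        rows.append({
            "phenotype": "female", "n_positive": n_female,
            "n_available": len(tab),
            "pct": 100.0 * n_female / len(tab) if len(tab) else np.nan,
        })
        for flag in self.flags:
            vals = tab[flag]
            avail = int(vals.notna().sum())
            pos = int((vals == 1).sum())
            rows.append({
                "phenotype": flag, "n_positive": pos, "n_available": avail,
                "pct": 100.0 * pos / avail if avail else np.nan,
            })
        return pd.DataFrame(rows).set_index("phenotype")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t", index_col="sample",
                               dtype={"sex": str}))


@dataclass
class Cohort:
    """Inner join of a genotype matrix and a phenotype table on sample id."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    n_genotype_only: int = 0
    n_phenotype_only: int = 0

    @property
    def samples(self) -> list:
        return self.genotypes.samples


# ---------------------------------------------------------------------------
# Weight table / summary statistics
# ---------------------------------------------------------------------------

def read_weight_table(path) -> pd.DataFrame:
    """TSV with mandatory header ``id, effect_allele, beta`` (beta = ln OR)."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "effect_allele", "beta"}
    if not required.issubset(df.columns):
        raise ParseError(f"weight table requires columns {sorted(required)}")
    if not np.all(np.isfinite(df["beta"])):
        raise ParseError("weight table betas must be finite")
    if df["id"].duplicated().any():
        raise ParseError("duplicate variant id in weight table")
    return df


def read_summary_stats(path) -> pd.DataFrame:
    """GWAS summary statistics TSV: id, chrom, pos, effect_allele, beta, p."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "pos", "effect_allele", "beta", "p"}
    if not required.issubset(df.columns):
        raise ParseError(f"summary stats require columns {sorted(required)}")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        raise ParseError("summary-stats p values must lie in (0, 1]")
    if df["id"].duplicated().any():
        raise ParseError("duplicate variant id in summary stats")
    return df


# ---------------------------------------------------------------------------
# Genotype readers
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str | None = None,
                   effect_alleles: dict | None = None) -> GenotypeMatrix:
    """Read genotypes from PLINK text, TSV dosage or VCF.

    Parameters
    ----------
    path
        .ped path (sibling .map expected), .tsv dosage table, or .vcf.
    format
        'plink-text', 'tsv' or 'vcf'; inferred from the extension if None.
    effect_alleles
        Optional variant id -> allele mapping declaring which allele the
        dose should count (PLINK's A1). Defaults to the minor allele
        (ties broken alphabetically) for PLINK input; TSV doses are taken
        as-is; VCF counts ALT.
    """
    path = str(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".ped": "plink-text", ".tsv": "tsv", ".vcf": "vcf"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer genotype format from {path!r}")
    if format == "plink-text":
        return _read_plink_text(path, effect_alleles)
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _normalise_chrom(raw: str) -> str:
    c = str(raw).removeprefix("chr")
    if c in {"23", "x"}:
        c = "X"
    if c not in VALID_CHROMS:
        raise ParseError(f"unsupported chromosome {raw!r}")
    return c


def _read_plink_text(ped_path: str, effect_alleles) -> GenotypeMatrix:
    stem = ped_path[:-4] if ped_path.endswith(".ped") else ped_path
    map_path = stem + ".map"
    ped_path = stem + ".ped"

    meta = []  # (chrom, id, pos)
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 fields")
            meta.append((_normalise_chrom(parts[0]), parts[1], int(parts[3])))
    ids = [m[1] for m in meta]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{map_path}: duplicate variant id")

    samples, sexes, rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(meta):
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(meta)} "
                    f"fields, got {len(parts)}")
            if parts[4] not in {"0", "1", "2"}:
                raise ParseError(f"{ped_path}:{lineno}: bad sex code "
                                 f"{parts[4]!r}")
            samples.append(parts[1])
            sexes.append(_SEX_CODES[parts[4]])
            rows.append(parts[6:])

    n, v = len(samples), len(meta)
    alleles_seen = [dict() for _ in range(v)]  # allele -> count
    geno = np.empty((n, v, 2), dtype="<U8")
    for i, row in enumerate(rows):
        for j in range(v):
            a1, a2 = row[2 * j], row[2 * j + 1]
            geno[i, j, 0], geno[i, j, 1] = a1, a2
            for a in (a1, a2):
                if a != "0":
                    alleles_seen[j][a] = alleles_seen[j].get(a, 0) + 1

    variants, dose = [], np.full((n, v), MISSING)
    for j, (chrom, vid, pos) in enumerate(meta):
        counts = alleles_seen[j]
        if len(counts) > 2:
            raise ParseError(f"{ped_path}: variant {vid} has >2 alleles")
        # effect allele: declared, else minor (ties alphabetical)
        if effect_alleles and vid in effect_alleles:
            eff = effect_alleles[vid]
            if counts and eff not in counts and len(counts) == 2:
                raise AlleleMismatchError([vid])
        elif counts:
            eff = min(sorted(counts), key=lambda a: (counts[a], a))
        else:
            eff = "N"
        others = [a for a in sorted(counts) if a != eff]
        other = others[0] if others else ("N" if eff != "N" else "M")
        variants.append(VariantRecord(vid, chrom, pos, eff, other))
        g = geno[:, j, :]
        nonmiss = (g[:, 0] != "0") & (g[:, 1] != "0")
        dose[nonmiss, j] = (g[nonmiss] == eff).sum(axis=1)

    return GenotypeMatrix(samples, variants, dose, np.array(sexes))


def _read_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample", dtype={"sex": str})
    sex = np.array(["U"] * len(df))
    if "sex" in df.columns:
        codes = df["sex"].fillna("U").astype(str)
        bad = set(codes) - set(_SEX_CODES)
        if bad:
            raise ParseError(f"{path}: bad sex codes {sorted(bad)}")
        sex = np.array([_SEX_CODES[c] for c in codes])
        df = df.drop(columns=["sex"])
    df = df.drop(columns=[c for c in ("status",) if c in df.columns])
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate variant id")

    sidecar = os.path.splitext(path)[0] + ".variants.tsv"
    if os.path.exists(sidecar):
        vmeta = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str}
                            ).set_index("id")
        variants = [
            VariantRecord(vid, _normalise_chrom(vmeta.loc[vid, "chrom"]),
                          int(vmeta.loc[vid, "pos"]),
                          str(vmeta.loc[vid, "allele_a"]),
                          str(vmeta.loc[vid, "allele_b"]))
            for vid in df.columns
        ]
    else:
        variants = [VariantRecord(vid, "1", j + 1, "A", "B")
                    for j, vid in enumerate(df.columns)]
    dose = df.to_numpy(dtype=float)
    ok = np.isnan(dose) | np.isin(dose, (0.0, 1.0, 2.0))
    if not ok.all():
        raise ParseError(f"{path}: doses must be 0/1/2 or empty")
    return GenotypeMatrix(list(df.index.astype(str)), variants, dose, sex)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    variants, cols = [], []
    seen = set()
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise ParseError(f"{path}: duplicate variant id {vid}")
        seen.add(vid)
        if len(rec.ALT) != 1:
            raise ParseError(f"{path}: variant {vid} is not biallelic")
        variants.append(VariantRecord(vid, _normalise_chrom(rec.CHROM),
                                      rec.POS, rec.ALT[0], rec.REF))
        g = rec.gt_types.astype(float)  # 0/1/2, 3 = missing under gts012
        g[g == 3] = MISSING
        cols.append(g)
    dose = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants,
                          dose, np.array(["U"] * len(samples)))


# ---------------------------------------------------------------------------
# Genotype writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".ped": "plink-text", ".tsv": "tsv", ".vcf": "vcf"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer genotype format from {path!r}")
    if format == "plink-text":
        _write_plink_text(g, path)
    elif format == "tsv":
        _write_tsv(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_plink_text(g: GenotypeMatrix, ped_path: str) -> None:
    stem = ped_path[:-4] if ped_path.endswith(".ped") else ped_path
    with open(stem + ".map", "w") as fh:
        for rec in g.variants:
            fh.write(f"{rec.chrom}\t{rec.id}\t0\t{rec.pos}\n")
    sex_out = {"M": "1", "F": "2", "U": "0"}
    with open(stem + ".ped", "w") as fh:
        for i, sid in enumerate(g.samples):
            fields = [sid, sid, "0", "0", sex_out[g.sex[i]], "-9"]
            for j, rec in enumerate(g.variants):
                d = g.dose[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [rec.allele_a, rec.allele_a]
                elif d == 1:
                    fields += [rec.allele_a, rec.allele_b]
                else:
                    fields += [rec.allele_b, rec.allele_b]
            fh.write(" ".join(fields) + "\n")


def _write_tsv(g: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(g.dose, index=pd.Index(g.samples, name="sample"),
                      columns=g.variant_ids)
    df = df.map(lambda d: "" if np.isnan(d) else str(int(d)))
    df.insert(0, "sex", g.sex)
    df.to_csv(path, sep="\t")
    vmeta = pd.DataFrame(
        [{"id": r.id, "chrom": r.chrom, "pos": r.pos,
          "allele_a": r.allele_a, "allele_b": r.allele_b}
         for r in g.variants])
    vmeta.to_csv(os.path.splitext(path)[0] + ".variants.tsv",
                 sep="\t", index=False)


def _write_vcf(g: GenotypeMatrix, path: str) -> None:
    # coordinate-sorted output keeps VCF consumers happy
    idx = sorted(range(g.n_variants),
                 key=lambda j: (g.variants[j].chrom.rjust(2, "0"),
                                g.variants[j].pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted({g.variants[j].chrom for j in idx},
                        key=lambda c: c.rjust(2, "0")):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in idx:
            rec = g.variants[j]
            gts = ["./." if np.isnan(d) else gt_map[d] for d in g.dose[:, j]]
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\t{rec.allele_b}\t"
                     f"{rec.allele_a}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Alignment and joining
# ---------------------------------------------------------------------------

def align_to_effect_allele(g: GenotypeMatrix, weights: pd.DataFrame
                           ) -> GenotypeMatrix:
    """Re-orient doses so they count the weight table's effect allele.

    Flipping a variant maps dose d -> 2 - d (missing stays missing) and swaps
    the recorded alleles. Variants absent from the weight table are left
    untouched. An effect allele matching neither recorded allele raises
    :class:`AlleleMismatchError` listing every offending variant.
    """
    vidx = g.variant_index()
    missing = [vid for vid in weights["id"] if vid not in vidx]
    if missing:
        raise KeyError(f"weight-table variants absent from genotypes: "
                       f"{missing}")
    out = g.copy()
    mismatches = []
    for vid, eff in zip(weights["id"], weights["effect_allele"]):
        j = vidx[vid]
        rec = out.variants[j]
        if eff == rec.allele_a:
            continue
        if eff == rec.allele_b:
            out.dose[:, j] = 2.0 - out.dose[:, j]
            out.variants[j] = replace(rec, allele_a=rec.allele_b,
                                      allele_b=rec.allele_a)
        else:
            mismatches.append(vid)
    if mismatches:
        raise AlleleMismatchError(mismatches)
    return out


def join_cohort(g: GenotypeMatrix, p: PhenotypeTable) -> Cohort:
    """Inner-join genotypes and phenotypes on sample id.

    Sample order follows the genotype matrix. Raises on an empty
    intersection; counts dropped from each side are recorded on the result.
    """
    pheno_ids = set(p.table.index.astype(str))
    keep = [i for i, s in enumerate(g.samples) if s in pheno_ids]
    if not keep:
        raise ValueError("no overlapping sample ids between genotypes and "
                         "phenotypes")
    g_sub = g.subset_samples(keep)
    ptab = p.table.loc[[str(s) for s in g_sub.samples]]
    return Cohort(
        genotypes=g_sub,
        phenotypes=PhenotypeTable(ptab),
        n_genotype_only=g.n_samples - len(keep),
        n_phenotype_only=len(pheno_ids) - len(keep),
    )
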
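"""Genotype/phenotype I/O, effect-allele alignment and cohort joining."""

import numpy as np
import pandas as pd
import pytest

from cdgps import genio
from cdgps.genio import (AlleleMismatchError, GenotypeMatrix, ParseError,
                         PhenotypeTable, VariantRecord,
                         align_to_effect_allele, join_cohort,
                         read_genotypes, write_genotypes)

from conftest import write_ped


class TestPlinkText:
    def test_dose_counts_declared_effect_allele(self, tmp_path):
        ped = write_ped(
            tmp_path,
            [["f1", "s1", "0", "0", "1", "-9", "A", "A"],
             ["f2", "s2", "0", "0", "2", "-9", "A", "G"]],
            [("1", "rs1", 100)])
        g = read_genotypes(ped, effect_alleles={"rs1": "A"})
        assert g.dose[:, 0].tolist() == [2.0, 1.0]
        # flipping the declared allele complements the dose
        g2 = read_genotypes(ped, effect_alleles={"rs1": "G"})
        assert g2.dose[:, 0].tolist() == [0.0, 1.0]

    def test_missing_genotype_code(self, tmp_path):
        ped = write_ped(
            tmp_path,
            [["f1", "s1", "0", "0", "1", "-9", "0", "0"],
             ["f2", "s2", "0", "0", "2", "-9", "A", "G"]],
            [("1", "rs1", 100)])
        g = read_genotypes(ped)
        assert np.isnan(g.dose[0, 0])

    def test_default_effect_allele_is_minor(self, tmp_path):
        ped = write_ped(
            tmp_path,
            [["f1", "s1", "0", "0", "1", "-9", "A", "A"],
             ["f2", "s2", "0", "0", "2", "-9", "A", "G"]],
            [("1", "rs1", 100)])
        g = read_genotypes(ped)   # G is rarer -> counted
        assert g.variants[0].allele_a == "G"
        assert g.dose[:, 0].tolist() == [0.0, 1.0]

    def test_malformed_row_names_line(self, tmp_path):
        ped = write_ped(
            tmp_path,
            [["f1", "s1", "0", "0", "1", "-9", "A"]],
            [("1", "rs1", 100)])
        with pytest.raises(ParseError, match=":1"):
            read_genotypes(ped)

    def test_bad_sex_code_rejected(self, tmp_path):
        ped = write_ped(
            tmp_path,
            [["f1", "s1", "0", "0", "9", "-9", "A", "A"]],
            [("1", "rs1", 100)])
        with pytest.raises(ParseError, match="sex"):
            read_genotypes(ped)

    def test_duplicate_variant_id_rejected(self, tmp_path):
        ped = write_ped(
            tmp_path,
            [["f1", "s1", "0", "0", "1", "-9", "A", "A", "C", "C"]],
            [("1", "rs1", 100), ("1", "rs1", 200)])
        with pytest.raises(ParseError, match="duplicate"):
            read_genotypes(ped)


@pytest.mark.parametrize("fmt,ext", [("plink-text", ".ped"),
                                     ("tsv", ".tsv"), ("vcf", ".vcf")])
def test_round_trip_all_dialects(tmp_path, fmt, ext):
    """write -> read reproduces the dose matrix exactly in every dialect."""
    rng = np.random.default_rng(3)
    variants = [VariantRecord(f"rs{j}", str(j + 1), 1000 * (j + 1), "A", "G")
                for j in range(4)]
    dose = rng.integers(0, 3, (6, 4)).astype(float)
    dose[0, 1] = np.nan
    g = GenotypeMatrix([f"s{i}" for i in range(6)], variants, dose,
                       np.array(["M", "F", "F", "M", "U", "F"]))
    path = str(tmp_path / ("g" + ext))
    write_genotypes(g, path, format=fmt)
    effect = {rec.id: rec.allele_a for rec in g.variants}
    back = read_genotypes(path, format=fmt,
                          effect_alleles=effect if fmt == "plink-text"
                          else None)
    order = [back.variant_ids.index(v) for v in g.variant_ids]
    np.testing.assert_array_equal(g.dose, back.dose[:, order])
    assert back.samples == g.samples


class TestAlign:
    @pytest.fixture
    def matrix(self):
        variants = [VariantRecord("rs1", "1", 100, "A", "G"),
                    VariantRecord("rs2", "2", 200, "C", "T")]
        dose = np.array([[2.0, 1.0], [0.0, np.nan]])
        return GenotypeMatrix(["s1", "s2"], variants, dose,
                              np.array(["M", "F"]))

    def test_flip_complements_and_preserves_missing(self, matrix):
        w = pd.DataFrame({"id": ["rs1", "rs2"],
                          "effect_allele": ["G", "C"],
                          "beta": [0.1, 0.2]})
        out = align_to_effect_allele(matrix, w)
        assert out.dose[0, 0] == 0.0 and out.dose[1, 0] == 2.0
        assert out.variants[0].allele_a == "G"
        assert np.isnan(out.dose[1, 1])    # untouched variant, missing kept
        assert out.dose[0, 1] == 1.0

    def test_mismatch_lists_offenders(self, matrix):
        w = pd.DataFrame({"id": ["rs1"], "effect_allele": ["T"],
                          "beta": [0.1]})
        with pytest.raises(AlleleMismatchError) as err:
            align_to_effect_allele(matrix, w)
        assert err.value.variants == ["rs1"]

    def test_double_flip_is_identity(self, matrix):
        w_flip = pd.DataFrame({"id": ["rs1"], "effect_allele": ["G"],
                               "beta": [0.1]})
        w_back = pd.DataFrame({"id": ["rs1"], "effect_allele": ["A"],
                               "beta": [0.1]})
        out = align_to_effect_allele(
            align_to_effect_allele(matrix, w_flip), w_back)
        np.testing.assert_array_equal(out.dose, matrix.dose)


class TestJoin:
    def _geno(self, samples):
        v = [VariantRecord("rs1", "1", 100, "A", "G")]
        return GenotypeMatrix(samples, v,
                              np.zeros((len(samples), 1)),
                              np.array(["U"] * len(samples)))

    def _pheno(self, samples):
        return PhenotypeTable(pd.DataFrame(
            {"status": ["case"] * len(samples),
             "sex": ["F"] * len(samples)},
            index=pd.Index(samples, name="sample")))

    def test_inner_join_reports_drops(self):
        cohort = join_cohort(self._geno(["a", "b", "c"]),
                             self._pheno(["a", "b"]))
        assert cohort.samples == ["a", "b"]
        assert cohort.n_genotype_only == 1
        assert cohort.n_phenotype_only == 0

    def test_identity_join(self):
        cohort = join_cohort(self._geno(["a", "b"]), self._pheno(["a", "b"]))
        assert cohort.samples == ["a", "b"]
        assert cohort.n_genotype_only == cohort.n_phenotype_only == 0

    def test_disjoint_ids_error(self):
        with pytest.raises(ValueError, match="overlap"):
            join_cohort(self._geno(["a"]), self._pheno(["b"]))


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp


@given(hnp.arrays(float, (5, 3),
                  elements=st.sampled_from([0.0, 1.0, 2.0, np.nan])))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_allele_flip_involution_property(dose):
    """Aligning to the other allele twice restores the original doses."""
    variants = [VariantRecord(f"r{j}", "1", j + 1, "A", "G")
                for j in range(3)]
    g = GenotypeMatrix([f"s{i}" for i in range(5)], variants, dose.copy(),
                       np.array(["U"] * 5))
    w_flip = pd.DataFrame({"id": ["r0", "r1", "r2"],
                           "effect_allele": ["G", "G", "G"],
                           "beta": [0.0] * 3})
    w_back = w_flip.assign(effect_allele="A")
    out = align_to_effect_allele(
        align_to_effect_allele(g, w_flip), w_back)
    np.testing.assert_array_equal(out.dose, g.dose)


def test_phenotype_summary_partial_denominator():
    tab = pd.DataFrame({
        "status": ["case"] * 4 + ["control"],
        "sex": ["F", "F", "M", "M", "F"],
        "flag": [1.0, 0.0, np.nan, 1.0, np.nan],
    }, index=pd.Index(list("abcde"), name="sample"))
    s = PhenotypeTable(tab).summary(among="case")
    assert s.loc["flag", "n_available"] == 3
    assert s.loc["flag", "n_positive"] == 2
    assert s.loc["female", "pct"] == 50.0
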
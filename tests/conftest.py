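import numpy as np
import pandas as pd
import pytest

from cdgps import genio, simdata


@pytest.fixture(scope="session")
def tiny_cohort():
    g, pheno, truth = simdata.simulate_cohort(simdata.tiny_config(seed=7))
    return genio.Cohort(g, pheno)


@pytest.fixture(scope="session")
def paper_shape_cohort():
    cfg = simdata.paper_shape_config(seed=11)
    g, pheno, _ = simdata.simulate_cohort(cfg)
    return genio.Cohort(g, pheno)


@pytest.fixture(scope="session")
def ld_demo(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("ld_demo")
    paths = simdata.make_fixture("ld-demo", outdir, seed=5)
    g = genio.read_genotypes(paths["genotypes"])
    ss = pd.read_csv(paths["sumstats"], sep="\t", dtype={"chrom": str})
    return g, ss, paths


def write_ped(tmp_path, ped_rows, map_rows, stem="toy"):
    """Helper: write a PLINK-text pair and return the .ped path."""
    (tmp_path / f"{stem}.map").write_text(
        "".join(f"{c}\t{i}\t0\t{p}\n" for c, i, p in map_rows))
    (tmp_path / f"{stem}.ped").write_text(
        "".join(" ".join(r) + "\n" for r in ped_rows))
    return str(tmp_path / f"{stem}.ped")
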
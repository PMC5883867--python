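"""Shared fixtures: small simulated cohorts and hand-built toy datasets."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from jointgp.genio import GenotypeDataset
from jointgp.relmat import compute_grm
from jointgp.simdata import SimConfig, simulate_cohort

DATA = Path(__file__).parent / "data"


def make_dataset(dosages, positions=None, chroms=None, sample_prefix="s",
                 origin="POP1", alleles=None):
    """GenotypeDataset from a plain dosage array (tests' hand-built toys)."""
    dosages = np.asarray(dosages, float)
    n, m = dosages.shape
    ids = np.array([f"{sample_prefix}{i + 1:03d}" for i in range(n)], object)
    positions = positions if positions is not None else (np.arange(m) + 1) * 1000
    chroms = chroms if chroms is not None else ["1"] * m
    origins = [origin] * n if isinstance(origin, str) else list(origin)
    if alleles is None:
        alleles = [("A", "B")] * m
    mm = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1}" for j in range(m)],
            "chrom": [str(c) for c in chroms],
            "pos": positions,
            "allele1": [a for a, _ in alleles],
            "allele2": [b for _, b in alleles],
        }
    )
    meta = pd.DataFrame(
        {"sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2), "origin": origins},
        index=pd.Index(ids, name="sample_id"),
    )
    return GenotypeDataset(ids, meta, mm, dosages)


@pytest.fixture(scope="session")
def desk_cohort():
    """Small two-population cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(seed=11, n_pop1=250, n_pop2=80, n_snps=800,
                                     n_chromosomes=10))


@pytest.fixture(scope="session")
def desk_grm(desk_cohort):
    return compute_grm(desk_cohort.genotypes, ridge=0.01)


@pytest.fixture(scope="session")
def reml_toy():
    """Simulated 12-individual fixture (synthetic, shipped as TSV): G, y, W."""
    G = pd.read_csv(DATA / "reml_toy_grm.tsv", sep="\t", index_col=0)
    ph = pd.read_csv(DATA / "reml_toy_pheno.tsv", sep="\t")
    W = np.column_stack([np.ones(len(ph)), ph["covariate"].to_numpy(float)])
    return G.to_numpy(), W, ph["y"].to_numpy(), ph["sample_id"].to_numpy(object)
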
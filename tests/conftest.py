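import numpy as np
import pandas as pd
import pytest

import genmix as gx


@pytest.fixture
def trio_pedigree():
    """Two unrelated founders and their offspring."""
    return gx.Pedigree.from_records(
        [
            gx.PedigreeRecord("P", None, None),
            gx.PedigreeRecord("Q", None, None),
            gx.PedigreeRecord("O", "P", "Q"),
        ]
    )


def random_pedigree(n, rng, p_founder=0.3):
    """Random acyclic pedigree of n individuals (topologically ordered)."""
    records = []
    for i in range(n):
        sire = dam = None
        if i >= 2 and rng.random() > p_founder:
            sire = f"I{rng.integers(i)}"
            dam = f"I{rng.integers(i)}"
            if sire == dam:
                dam = None
        records.append(gx.PedigreeRecord(f"I{i}", sire, dam))
    return gx.Pedigree.from_records(records)


@pytest.fixture
def random_pedigree_factory():
    return random_pedigree


def make_hap(alleles, positions=None, spacing=72_000):
    """HaplotypeMatrix from a row-per-haplotype 0/1 array."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_rows, m = alleles.shape
    assert n_rows % 2 == 0
    if positions is None:
        positions = spacing * (1 + np.arange(m))
    return gx.HaplotypeMatrix(
        alleles,
        positions,
        [f"s{j}" for j in range(m)],
        [f"ind{k}" for k in range(n_rows // 2)],
    )


@pytest.fixture
def hap_factory():
    return make_hap


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared by scan-level tests."""
    design = gx.PopulationDesign(
        n_generations=4, n_founders=60, final_size=150, n_sites=60
    )
    rng = np.random.default_rng(12345)
    ped, genotyped, hap = gx.simulate_genotypes(design, rng)
    A = gx.compute_A(ped)
    return ped, genotyped, hap, A


@pytest.fixture(scope="session")
def small_phenotypes(small_dataset):
    ped, genotyped, hap, A = small_dataset
    qtl = gx.select_qtl_sites(hap, [0.25], tol=0.1)[0]
    cfg = gx.SimConfig(h2=0.34, qtl_maf=0.25, qtl_effect=1.0)
    pheno = gx.simulate_phenotypes(ped, hap, qtl, cfg, np.random.default_rng(7))
    return qtl, pheno
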
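"""Synthetic pedigrees, gene-dropped marker data, and simulated phenotypes.

The generator emulates a dairy-cattle study population: a multi-generation
pedigree with heavy reuse of a few sires, a single chromosome of SNPs with
pedigree-induced LD obtained by dropping a small pool of founder haplotypes
through the pedigree with Haldane recombination (1 cM/Mbp by default), and
phenotypes composed of

    y = alpha * x_qtl + a + e

with founder polygenic values N(0, 1), offspring values built from the
mid-parent average plus a Mendelian sampling term of variance
``0.5 * (1 - (F_sire + F_dam) / 2)`` (so that Var(a) = A exactly), and
residuals N(0, sigma_e^2) with ``sigma_e^2 = (1 - h^2) / h^2``.  The QTL
substitution effect ``alpha`` is expressed in phenotypic-SD units, with
``sigma_p^2 = sigma_a^2 + sigma_e^2`` (heritability and phenotypic SD are
defined excluding the QTL's own contribution).

Founder haplotypes come, by default, from a coalescent-with-recombination
sample of a breed-sized population with chip-like MAF ascertainment, so
local genealogies vary along the chromosome, LD decays with distance, and
every non-recombined stretch is consistent with a single local tree.  A
simpler "tree" pool model (a small pool built by sequential mutation from
a random ancestor, optionally recombined into founder mosaics) is kept as
an alternative.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, GenmixError
from .haplotypes import HaplotypeMatrix
from .mixed_model import ScanConfig, genmix_scan, mma_scan
from .pedigree import Pedigree, PedigreeRecord, compute_A, inbreeding

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "PopulationDesign",
    "simulate_pedigree",
    "founder_haplotype_pool",
    "gene_drop",
    "simulate_polygenic",
    "simulate_phenotypes",
    "select_qtl_sites",
    "simulate_genotypes",
    "run_study",
    "PAPER_GRID",
]


@dataclass
class SimConfig:
    """One simulation scenario (phenotype model parameters)."""

    h2: float = 0.34
    qtl_maf: float = 0.10
    qtl_effect: float = 0.5  # allele substitution effect, phenotypic-SD units
    n_replicates: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("heritability must be in (0, 1)")
        if self.qtl_effect < 0:
            raise ValueError("QTL effect must be >= 0")
        if not (0.0 < self.qtl_maf <= 0.5):
            raise ValueError("QTL MAF must be in (0, 0.5]")


#: the full study grid: 3 heritabilities x 7 MAFs x 5 effects x 25 replicates
PAPER_GRID = {
    "h2": (0.21, 0.34, 0.64),
    "maf": (0.05, 0.10, 0.15, 0.20, 0.25, 0.35, 0.45),
    "effect": (0.1, 0.2, 0.5, 0.7, 1.0),
    "n_replicates": 25,
}


@dataclass
class PopulationDesign:
    """Shape of the synthetic population and marker map."""

    n_generations: int = 5
    n_founders: int = 100
    n_sires: int = 8  # elite sires reused per generation (dairy-like)
    final_size: int = 1400  # genotyped individuals (final generation)
    n_sites: int = 1700
    snp_spacing_bp: int = 72_000  # ~72 kbp mean marker spacing
    founder_pool_size: int = 30
    founder_pool_min_clade: int = 2
    pool_model: str = "coalescent"  # or "tree" (single pool genealogy)
    ancestral_Ne: float = 100.0  # breed effective size for the coalescent pool
    recomb_cm_per_mbp: float = 1.0
    ancestral_generations: float = 50.0  # pre-pedigree breed history depth
    maf_threshold: float = 0.05

    def positions(self) -> np.ndarray:
        return self.snp_spacing_bp * (1 + np.arange(self.n_sites, dtype=np.int64))


def simulate_pedigree(
    n_generations: int,
    founders: int,
    final_size: int,
    rng: np.random.Generator,
    n_sires: int = 8,
) -> tuple[Pedigree, list[str]]:
    """Multi-generation pedigree with few sires and many dams.

    Generation sizes interpolate geometrically from ``founders`` to
    ``final_size``.  Each generation's offspring are sired by a small pool
    of ``n_sires`` males drawn from the previous generations, inducing the
    strong relatedness typical of dairy populations.  Returns the pedigree
    and the ids of the final generation (the genotyped set).
    """
    if founders < 2:
        raise ValueError("need at least 2 founders")
    if n_generations < 1:
        raise ValueError("need at least 1 generation")
    records: list[PedigreeRecord] = []
    sex: dict[str, int] = {}  # 0 = male, 1 = female
    males: list[str] = []
    females: list[str] = []
    for k in range(founders):
        iid = f"G1_{k}"
        records.append(PedigreeRecord(iid, None, None))
        s = k % 2
        sex[iid] = s
        (males if s == 0 else females).append(iid)
    if not males or not females:
        raise GenmixError("impossible mating constraints: need both sexes")

    if n_generations == 1:
        ped = Pedigree(records)
        return ped, [r.individual_id for r in records]

    # generation sizes interpolate geometrically founders -> final_size
    sizes = [
        max(2, int(round(founders * (final_size / founders) ** (g / (n_generations - 1)))))
        for g in range(n_generations)
    ]

    prev_females = list(females)
    all_males = list(males)
    last_gen: list[str] = []
    for g in range(2, n_generations + 1):
        n_off = sizes[g - 1]
        pool = list(
            rng.choice(all_males, size=min(n_sires, len(all_males)), replace=False)
        )
        gen_ids: list[str] = []
        new_males: list[str] = []
        new_females: list[str] = []
        for k in range(n_off):
            sire = pool[rng.integers(len(pool))]
            dam = prev_females[rng.integers(len(prev_females))]
            iid = f"G{g}_{k}"
            records.append(PedigreeRecord(iid, sire, dam))
            s = int(rng.random() < 0.5)
            sex[iid] = s
            (new_males if s == 0 else new_females).append(iid)
            gen_ids.append(iid)
        if not new_females:  # keep the line going
            new_females.append(gen_ids[0])
            sex[gen_ids[0]] = 1
        prev_females = new_females
        all_males.extend(new_males)
        last_gen = gen_ids
    return Pedigree(records), last_gen


def founder_haplotype_pool(
    n_sites: int,
    rng: np.random.Generator,
    pool_size: int = 30,
    min_clade: int = 2,
) -> np.ndarray:
    """Distinct founder haplotypes built by sequential mutation.

    A random attachment genealogy is grown over ``pool_size`` haplotypes
    starting from an all-ancestral haplotype; each site mutates exactly
    once, on a random branch, so carriers of the derived allele always form
    a clade of the pool genealogy.  Branches are drawn among clades of
    ``min_clade`` .. ``pool_size - min_clade`` haplotypes, mimicking the
    common-allele ascertainment of SNP genotyping arrays.
    """
    parent = np.zeros(pool_size, dtype=np.int64)
    for k in range(1, pool_size):
        parent[k] = rng.integers(k)
    # descendant sets in the attachment genealogy
    desc = [{k} for k in range(pool_size)]
    for k in range(pool_size - 1, 0, -1):
        desc[parent[k]] |= desc[k]
    eligible = [
        v
        for v in range(1, pool_size)
        if min_clade <= len(desc[v]) <= pool_size - min_clade
    ]
    if not eligible:
        eligible = list(range(1, pool_size))
    pool = np.zeros((pool_size, n_sites), dtype=np.uint8)
    branches = rng.choice(eligible, size=n_sites)
    for j, v in enumerate(branches):
        pool[list(desc[v]), j] = 1
    return pool


def founder_pool_coalescent(
    n_sites: int,
    spacing_bp: int,
    rng: np.random.Generator,
    pool_size: int = 200,
    Ne: float = 100.0,
    recomb_rate: float = 1e-8,
    maf_ascertainment: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Founder haplotype pool from a coalescent with recombination.

    A breed-like population (haploid sample of ``pool_size``, effective
    size ``Ne``) is simulated over the chromosome so local genealogies vary
    along it, as in real chip data.  Sites are thinned to one common
    variant (sample MAF >= ``maf_ascertainment``) near each ``spacing_bp``
    grid point, mimicking array ascertainment.  Returns ``(pool,
    positions)``; infinite-sites mutations keep every non-recombined
    stretch consistent with a single local tree.
    """
    import msprime

    length = spacing_bp * (n_sites + 1)
    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=pool_size,
        ploidy=1,
        population_size=Ne,
        sequence_length=length,
        recombination_rate=recomb_rate,
        random_seed=seed,
    )
    # mutation rate set for ~10x candidate segregating sites
    harmonic = sum(1.0 / i for i in range(1, pool_size))
    mu = 10.0 * n_sites / (4.0 * Ne * length * harmonic)
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=seed + 1, discrete_genome=False
    )
    G = ts.genotype_matrix().T
    pos = np.array([s.position for s in ts.sites()])
    freq = G.mean(axis=0)
    common = np.minimum(freq, 1.0 - freq) >= maf_ascertainment
    G, pos = G[:, common], pos[common]
    if G.shape[1] < n_sites:
        raise DataError(
            f"coalescent pool yielded only {G.shape[1]} common sites "
            f"(need {n_sites}); increase Ne or chromosome length"
        )
    grid = spacing_bp * (1 + np.arange(n_sites))
    used: set[int] = set()
    for gpos in grid:
        for j in np.argsort(np.abs(pos - gpos)):
            if j not in used:
                used.add(int(j))
                break
    chosen = np.array(sorted(used))
    out_pos = np.round(pos[chosen]).astype(np.int64)
    for j in range(1, len(out_pos)):  # keep positions strictly increasing
        if out_pos[j] <= out_pos[j - 1]:
            out_pos[j] = out_pos[j - 1] + 1
    return G[:, chosen].astype(np.uint8), out_pos


def _mosaic_haplotypes(
    pool: np.ndarray,
    n_haplotypes: int,
    r_anc: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes as ancestral-recombination mosaics of the pool.

    Each haplotype follows a Markov walk along the chromosome: within a
    segment it copies one pool haplotype; between adjacent sites it jumps to
    a uniformly drawn pool haplotype with probability ``r_anc`` (one minus
    the chance of no ancestral crossover).  This emulates the pre-pedigree
    breed history that limits haplotype identity to a local scale while
    keeping every local segment a clade-consistent pool descendant.
    """
    pool_n, m = pool.shape
    cols = np.arange(m)
    out = np.empty((n_haplotypes, m), dtype=np.uint8)
    for h in range(n_haplotypes):
        seg = np.concatenate([[0], np.cumsum(rng.random(m - 1) < r_anc)])
        donors = rng.integers(pool_n, size=seg[-1] + 1)
        out[h] = pool[donors[seg], cols]
    return out


def _recombine(
    hap_a: np.ndarray, hap_b: np.ndarray, r: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete from two parental haplotypes (Haldane, no interference)."""
    start = rng.integers(2)
    switches = rng.random(len(r)) < r
    state = (start + np.concatenate([[0], np.cumsum(switches)])) % 2
    return np.where(state == 0, hap_a, hap_b).astype(np.uint8)


def gene_drop(
    ped: Pedigree,
    founder_pool: np.ndarray,
    positions: Sequence[int],
    rng: np.random.Generator,
    genotyped_ids: Optional[list[str]] = None,
    recomb_cm_per_mbp: float = 1.0,
    ancestral_generations: float = 0.0,
    chrom: str = "1",
) -> HaplotypeMatrix:
    """Drop founder haplotypes through the pedigree with recombination.

    Founders draw two haplotypes from the pool with replacement; with
    ``ancestral_generations > 0`` each founder haplotype is instead an
    ancestral-recombination mosaic of pool haplotypes with breakpoint
    density proportional to that many meioses, so haplotype identity (and
    hence LD) decays along the chromosome as in a population with history
    older than the recorded pedigree.  Each non-founder inherits one
    recombined gamete per parent (an unknown parent contributes a gamete
    from a fresh pair of founder-style haplotypes).  Returns phased
    haplotypes of ``genotyped_ids`` (default: everyone).
    """
    positions = np.asarray(positions, dtype=np.int64)
    m = founder_pool.shape[1]
    if len(positions) != m:
        raise DataError("map length does not match founder haplotype length")
    # Haldane: bp -> Morgan at recomb_cm_per_mbp, r = (1 - exp(-2d)) / 2
    d_morgan = np.diff(positions) * (recomb_cm_per_mbp * 1e-8)
    r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))

    n = len(ped)
    haps = np.empty((2 * n, m), dtype=np.uint8)
    sire, dam = ped.parent_indices()
    pool_n = founder_pool.shape[0]
    r_anc = None
    if ancestral_generations > 0:
        # chance of >= 1 crossover on a lineage of that many meioses
        r_anc = 1.0 - np.exp(-ancestral_generations * d_morgan)

    def founder_haplotype() -> np.ndarray:
        if r_anc is None:
            return founder_pool[rng.integers(pool_n)]
        return _mosaic_haplotypes(founder_pool, 1, r_anc, rng)[0]

    def phantom_gamete() -> np.ndarray:
        return _recombine(founder_haplotype(), founder_haplotype(), r, rng)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            haps[2 * i] = founder_haplotype()
            haps[2 * i + 1] = founder_haplotype()
            continue
        if s >= 0:
            haps[2 * i] = _recombine(haps[2 * s], haps[2 * s + 1], r, rng)
        else:
            haps[2 * i] = phantom_gamete()
        if d >= 0:
            haps[2 * i + 1] = _recombine(haps[2 * d], haps[2 * d + 1], r, rng)
        else:
            haps[2 * i + 1] = phantom_gamete()

    ids = ped.ids
    full = HaplotypeMatrix(
        haps, positions, [f"snp_{j}" for j in range(m)], ids, chrom
    )
    if genotyped_ids is not None:
        full = full.take_individuals(genotyped_ids)
    return full


def simulate_polygenic(
    ped: Pedigree,
    rng: np.random.Generator,
    sigma2_a: float = 1.0,
    n_replicates: int = 1,
    F: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Additive polygenic values with Var(a) = A * sigma2_a.

    Founders (unknown-parent individuals) are N(0, sigma2_a); offspring are
    the mid-parent average plus a Mendelian sampling term of variance
    ``sigma2_a * 0.5 * (1 - (F_s + F_d) / 2)``.  An unknown parent
    contributes a fresh phantom founder value.  Returns an array of shape
    ``(n_replicates, len(ped))`` (squeezed to 1-D for one replicate).
    """
    n = len(ped)
    if F is None:
        F = inbreeding(ped)
    sire, dam = ped.parent_indices()
    sd = math.sqrt(sigma2_a)
    a = np.empty((n_replicates, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            a[:, i] = sd * rng.standard_normal(n_replicates)
            continue
        par_s = a[:, s] if s >= 0 else sd * rng.standard_normal(n_replicates)
        par_d = a[:, d] if d >= 0 else sd * rng.standard_normal(n_replicates)
        f_s = F[s] if s >= 0 else 0.0
        f_d = F[d] if d >= 0 else 0.0
        mend_var = sigma2_a * 0.5 * (1.0 - (f_s + f_d) / 2.0)
        a[:, i] = 0.5 * (par_s + par_d) + math.sqrt(mend_var) * rng.standard_normal(
            n_replicates
        )
    return a[0] if n_replicates == 1 else a


def simulate_phenotypes(
    ped: Pedigree,
    hap: HaplotypeMatrix,
    qtl_site: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    F: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Phenotypes for the genotyped individuals: QTL + polygenic + residual.

    Returns a frame with columns ``id, y, true_a, true_e, qtl_genotype``;
    ``frame.attrs`` records ``alpha``, ``sigma2_a``, ``sigma2_e`` and the
    QTL variance ``2 p (1 - p) alpha^2``.  The decomposition is exact:
    ``y == alpha * qtl_genotype + true_a + true_e`` to machine precision.
    """
    sigma2_a = 1.0
    sigma2_e = sigma2_a * (1.0 - cfg.h2) / cfg.h2
    sigma_p = math.sqrt(sigma2_a + sigma2_e)
    alpha = cfg.qtl_effect * sigma_p

    a_all = simulate_polygenic(ped, rng, sigma2_a, F=F)
    idx = [ped.index[i] for i in hap.individual_ids]
    a = a_all[idx]
    x = hap.genotypes(minor=True)[:, qtl_site].astype(float)
    e = math.sqrt(sigma2_e) * rng.standard_normal(len(idx))
    y = alpha * x + a + e
    out = pd.DataFrame(
        {
            "id": hap.individual_ids,
            "y": y,
            "true_a": a,
            "true_e": e,
            "qtl_genotype": x.astype(int),
        }
    )
    p = hap.maf()[qtl_site]
    out.attrs.update(
        alpha=alpha,
        sigma2_a=sigma2_a,
        sigma2_e=sigma2_e,
        qtl_variance=2.0 * p * (1.0 - p) * alpha**2,
        h2=cfg.h2,
    )
    return out


def select_qtl_sites(
    hap: HaplotypeMatrix, target_mafs: Sequence[float], tol: float = 0.01
) -> list[int]:
    """One site per target MAF: nearest realized frequency, ties left-most.

    Raises :class:`DataError` naming the MAF when no site falls within
    ``tol`` of a target.
    """
    maf = hap.maf()
    out = []
    for target in target_mafs:
        dist = np.abs(maf - target)
        j = int(np.argmin(dist))  # argmin takes the left-most minimizer
        if dist[j] > tol:
            raise DataError(
                f"no site within {tol} of target MAF {target} "
                f"(closest: {maf[j]:.3f})"
            )
        out.append(j)
    return out


def simulate_genotypes(
    design: PopulationDesign, rng: np.random.Generator
) -> tuple[Pedigree, list[str], HaplotypeMatrix]:
    """Pedigree plus MAF-filtered phased haplotypes of the genotyped set."""
    ped, genotyped = simulate_pedigree(
        design.n_generations,
        design.n_founders,
        design.final_size,
        rng,
        n_sires=design.n_sires,
    )
    mosaic_generations = 0.0
    if design.pool_model == "coalescent":
        # one coalescent haplotype per founder chromosome: founders are
        # draws from the breed, not copies of a few prototypes
        pool, positions = founder_pool_coalescent(
            design.n_sites,
            design.snp_spacing_bp,
            rng,
            pool_size=2 * design.n_founders,
            Ne=design.ancestral_Ne,
            recomb_rate=design.recomb_cm_per_mbp * 1e-8,
            maf_ascertainment=design.maf_threshold,
        )
    elif design.pool_model == "tree":
        mosaic_generations = design.ancestral_generations
        pool = founder_haplotype_pool(
            design.n_sites, rng, design.founder_pool_size,
            min_clade=design.founder_pool_min_clade,
        )
        positions = design.positions()
    else:
        raise ValueError(f"unknown pool model {design.pool_model!r}")
    hap = gene_drop(
        ped,
        pool,
        positions,
        rng,
        genotyped_ids=genotyped,
        recomb_cm_per_mbp=design.recomb_cm_per_mbp,
        ancestral_generations=mosaic_generations,
    )
    return ped, genotyped, hap.filter_maf(design.maf_threshold)


# ---------------------------------------------------------------------------
# full study driver
# ---------------------------------------------------------------------------

def _rng_for(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def run_study(
    h2_levels: Sequence[float] = PAPER_GRID["h2"],
    mafs: Sequence[float] = PAPER_GRID["maf"],
    effects: Sequence[float] = PAPER_GRID["effect"],
    n_replicates: int = 25,
    design: Optional[PopulationDesign] = None,
    seed: int = 0,
    scan_config: Optional[ScanConfig] = None,
    methods: Sequence[str] = ("genmix", "mma"),
    out_dir: Optional[str] = None,
    dry_run: bool = False,
    qtl_maf_tol: float = 0.02,
) -> pd.DataFrame:
    """Run the simulation/evaluation study over a scenario grid.

    One genotype dataset is simulated per replicate and shared across the
    scenario grid (scenarios differ in phenotypes only, and effect levels
    are paired within a replicate), matching a fixed-genotype design.  The
    assigned QTL SNP is removed from the analyzed marker set.  Returns one
    row per (scenario, replicate, method) with detection and ranking
    metrics; with ``out_dir`` the rows, manifest, and aggregate tables are
    written and completed replicates are skipped on re-run.
    """
    from . import evaluate as ev

    design = design or PopulationDesign()
    scan_config = scan_config or ScanConfig()
    scenarios = [
        (h2, maf, eff) for h2 in h2_levels for maf in mafs for eff in effects
    ]
    if dry_run:
        rows = [
            {"h2": h2, "maf": maf, "effect": eff, "replicate": r}
            for (h2, maf, eff) in scenarios
            for r in range(n_replicates)
        ]
        return pd.DataFrame(rows)

    rows_dir = None
    if out_dir:
        rows_dir = os.path.join(out_dir, "rows")
        os.makedirs(rows_dir, exist_ok=True)

    all_rows: list[dict] = []
    failures: list[dict] = []
    scan_fns = {"genmix": genmix_scan, "mma": mma_scan}
    tests_per_snp = {"genmix": 7, "mma": 1}

    for r in range(n_replicates):
        cache_path = (
            os.path.join(rows_dir, f"replicate_{r}.json") if rows_dir else None
        )
        if cache_path and os.path.exists(cache_path):
            with open(cache_path) as fh:
                payload = json.load(fh)
            all_rows.extend(payload["rows"])
            failures.extend(payload.get("failures", []))
            logger.info("replicate %d loaded from cache", r)
            continue

        rng_data = _rng_for(seed, r, 0)
        ped, genotyped, hap = simulate_genotypes(design, rng_data)
        A = compute_A(ped)
        F = np.diag(A.values) - 1.0
        rep_rows: list[dict] = []
        rep_failures: list[dict] = []

        # pick the QTL site per target MAF once per replicate dataset
        qtl_site_of: dict[float, int] = {}
        for maf in sorted(set(mafs)):
            try:
                qtl_site_of[maf] = select_qtl_sites(hap, [maf], tol=qtl_maf_tol)[0]
            except DataError as exc:
                logger.warning("replicate %d: %s", r, exc)

        for k, (h2, maf, eff) in enumerate(scenarios):
            if maf not in qtl_site_of:
                rep_failures.append(
                    {"replicate": r, "h2": h2, "maf": maf, "effect": eff,
                     "reason": f"no QTL site near MAF {maf}"}
                )
                continue
            qtl = qtl_site_of[maf]
            qtl_bp = int(hap.positions[qtl])
            cfg = SimConfig(h2=h2, qtl_maf=maf, qtl_effect=eff)
            rng_pheno = _rng_for(seed, r, 1 + k)
            pheno = simulate_phenotypes(ped, hap, qtl, cfg, rng_pheno, F=F)
            y = pheno.set_index("id")["y"]
            hap_markers = hap.drop_site(qtl)  # the QTL SNP is not a marker
            for method in methods:
                scan = scan_fns[method](hap_markers, y, A, scan_config)
                thr = ev.bonferroni_threshold(
                    scan_config.alpha, hap_markers.n_sites, tests_per_snp[method]
                )
                detected = ev.power_criterion(scan, qtl_bp, threshold=thr)
                rng_rank = _rng_for(seed, r, 10_000 + k)
                ranks = ev.rank_markers(
                    scan.summary["min_p"].to_numpy(), rng_rank
                )
                best, n_win = ev.best_rank_within_window(
                    ranks, scan.summary["bp"].to_numpy(), qtl_bp
                )
                rep_rows.append(
                    {
                        "h2": h2, "maf": maf, "effect": eff, "replicate": r,
                        "method": method, "n_snps": hap_markers.n_sites,
                        "qtl_bp": qtl_bp,
                        "qtl_realized_maf": float(hap.maf()[qtl]),
                        "threshold": thr, "detected": bool(detected),
                        "best_rank_1mbp": best, "n_markers_1mbp": n_win,
                        "min_p_genomewide": float(
                            np.nanmin(scan.summary["min_p"].to_numpy())
                        ),
                    }
                )
            logger.info("replicate %d scenario %d/%d done", r, k + 1, len(scenarios))
        if cache_path:
            with open(cache_path, "w") as fh:
                json.dump({"rows": rep_rows, "failures": rep_failures}, fh)
        all_rows.extend(rep_rows)
        failures.extend(rep_failures)

    study = pd.DataFrame(all_rows)
    if out_dir:
        import yaml

        study.to_csv(os.path.join(out_dir, "study_rows.tsv"), sep="\t", index=False)
        power, ranking = ev.aggregate_study(study)
        power.to_csv(os.path.join(out_dir, "power.tsv"), sep="\t", index=False)
        ranking.to_csv(os.path.join(out_dir, "ranking.tsv"), sep="\t", index=False)
        manifest = {
            "seed": seed,
            "design": asdict(design),
            "grid": {
                "h2": list(h2_levels), "maf": list(mafs),
                "effect": list(effects), "n_replicates": n_replicates,
            },
            "n_analyses": len(scenarios) * n_replicates,
            "n_completed_rows": len(study),
            "failures": failures,
        }
        with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    if failures:
        logger.warning("%d analyses failed (see manifest)", len(failures))
    study.attrs["failures"] = failures
    return study
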
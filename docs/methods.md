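# Methods

## Model

For phenotyped individuals the package fits, by restricted maximum
likelihood,

    y = X b + a + e,    a ~ N(0, A σ²ₐ),    e ~ N(0, I σ²ₑ),

where `A` is the pedigree numerator relationship matrix restricted to the
analysis set and `X` contains an intercept plus the tested fixed effects:
either one 0/1/2 minor-allele count (the single-SNP unified mixed model,
MMA) or one or two haplotype-cluster count columns (GENMIX). Writing
`V = σ²ₑ(λA + I)` with `λ = σ²ₐ/σ²ₑ`, a single symmetric eigendecomposition
of `A` per dataset rotates the model to independent errors; the restricted
log-likelihood is profiled analytically over `σ²ₑ` and maximized over
`log λ` with a bounded scalar search (bounds 10⁻⁶..10⁶, absolute tolerance
10⁻⁸ on `log λ`, i.e. ~10⁻⁸ relative on the ratio). Fixed effects are the
GLS estimates at the optimum and their covariance is
`σ̂²ₑ (X'D⁻¹X)⁻¹` in the rotated basis. Tested coefficients get a Wald χ²
`b̂' V_b⁻¹ b̂` with degrees of freedom equal to the number of free
coefficients; p-values are asymptotic upper tails with no small-sample
correction. Variance components are re-estimated for every test by
default; a P3D-style option (estimate `λ` once under the no-SNP null and
reuse it) is available but off, since per-test REML matches how the
original analyses were run.

Degenerate cases: with `A = I` the ratio is unidentifiable (flat profile);
the fit flags this (`ratio_identifiable = False`) while the total variance
and GLS estimates remain valid. With `λ` fixed at 0 the fit reduces
exactly to ordinary least squares (verified against statsmodels).

## Local genealogies and their cuts

Two sites are tree-compatible when fewer than four of the gametes
00/01/10/11 occur among the phased haplotypes. For each focal SNP a
maximal compatible interval is grown by alternating single-site extensions
right, left, right, …, accepting a site only if it is compatible with
every site already included. Growth order is a design choice — the
upstream literature does not fix one — and alternation keeps intervals
roughly centred and deterministic; since compatibility with a growing set
only shrinks, a closed side stays closed and the result is maximal on both
sides.

Within an interval the derived allele at each site is the minor allele
(tie: allele 1), the root is the all-ancestral haplotype (virtual if
unobserved), and identical haplotypes are collapsed to one leaf carrying
its row multiset. Derived-carrier sets form a laminar family, which is
assembled into a containment tree; multifurcations are resolved
deterministically by ordering children by descending leaf count (ties by
smallest leaf haplotype string) and left-folding into a binary ladder, so
the smallest child of each multifurcation ends up nearest the root — which
is where the cut levels can see it. Cuts: the root bisection (cut 1),
trisections at depth-1 nodes (cuts 2–3) and at depth-2 nodes (cuts 4–7);
missing or leaf nodes yield no cut, so shallow trees give fewer than 7
factors. A trisection's groups are (outside the node, first child clade,
second child clade). Per individual, the design counts are how many of its
two haplotypes fall in each group; the largest usable group is the
constrained baseline, groups with fewer than `min_group_copies` (default
4) haplotype copies are dropped, and a factor with fewer than two usable
groups is skipped and logged. Bonferroni accounting nevertheless always
uses the nominal 7 tests per SNP, matching the published bookkeeping
(0.05/11,858 ≈ 4.2×10⁻⁶ on a 1,694-marker chromosome; 0.05/1,694 ≈
3.0×10⁻⁵ for the single-SNP scan). Identical intervals produce identical
trees and test results, so consecutive SNPs sharing an interval share
p-values; the scan caches on the interval for speed without changing any
result.

## Synthetic data generator

The generator emulates a dairy-cattle mapping population:

- **Pedigree** — founders (default 100) plus generations growing
  geometrically to the genotyped final generation (default 1,400;
  `n_generations = 5`). Each generation is sired by a small pool
  (default 8) of males drawn from earlier generations; dams come from the
  previous generation. This reproduces the strong, uneven relatedness of
  progeny-testing schemes (verified: mean off-diagonal `A` rises as the
  sire pool shrinks).
- **Founder haplotypes** — by default a haploid coalescent-with-
  recombination sample (msprime) of 2 × founders chromosomes from a
  breed-sized population (Ne = 100, 1 cM/Mbp, infinite sites), thinned to
  one common variant (MAF ≥ 5%, mimicking array ascertainment) near each
  72 kbp grid point. The coalescent guarantees that every non-recombined
  stretch is consistent with a single local tree, while local genealogies
  vary along the chromosome and LD decays with distance as in real chip
  data. An alternative `pool_model="tree"` builds 30 distinct haplotypes
  by sequential mutation on one random genealogy (optionally recombined
  into founder mosaics with an `ancestral_generations` breakpoint
  density); it is simpler but makes haplotype identity chromosome-wide —
  every local tree then resolves the same ~30 clades, and a low-MAF QTL
  almost always has a perfect-LD single-marker proxy, neither of which
  resembles chip data — so the coalescent pool is the default.
- **Gene drop** — each non-founder inherits one gamete per parent;
  crossovers follow the Haldane (no-interference) model at 1 cM/Mbp via a
  per-interval switch process. Unknown parents contribute gametes from
  fresh founder-style haplotypes.
- **Phenotypes** — `y = α·x + a + e` with `x` the minor-allele count at
  the QTL site. Founder polygenic values are N(0, 1); an offspring's value
  is the mid-parent mean plus a Mendelian term of variance
  `½(1 − (F_s + F_d)/2)`, using exact tabular-method inbreeding, so
  `Var(a) = A σ²ₐ` holds exactly (verified empirically on a fixed
  pedigree over 10⁴ replicates). The residual variance is
  `σ²ₑ = (1 − h²)/h²` with `σ²ₐ = 1`. Heritability and the phenotypic SD
  used to scale `α = effect × σ_p` exclude the QTL's own variance
  (`σ_p² = σ²ₐ + σ²ₑ`); this avoids the circularity of defining the effect
  on a scale that depends on the effect. The QTL's additive variance is
  `2p(1−p)α²`. Stored components sum to the phenotype to machine
  precision.
- **QTL sites** are the array sites nearest each target MAF (ties:
  left-most; error if none within tolerance — 0.01 for direct calls, 0.02
  in the study driver because a 300-site map cannot always hit every
  target to 0.01). The assigned QTL SNP is removed from the analyzed
  markers.

The study driver enumerates heritabilities × MAFs × effects × replicates
(the full grid is 3 × 7 × 5 × 25 = 2,625 analyses over 105 scenarios),
simulates one genotype dataset per replicate shared across scenarios (so
effect levels are paired within a replicate), runs both scans, and records
detection (any test significant within 2.5 Mbp of the QTL at the
Bonferroni per-test threshold) and localization (minimum rank within a
1 Mbp radius among all markers ranked by ascending per-SNP minimum p,
exact ties broken by a replicate-seeded uniform draw; NA p-values rank
last). Window comparisons are inclusive on |bp difference|; significance
decisions always use the exact threshold quotient, never its display
rounding.

### What the generator does and does not emulate

It reproduces pedigree-induced relatedness, array-like site frequencies,
distance-decaying LD, and an exactly pedigree-consistent polygenic
architecture. It does not reproduce the real Danish Jersey LD map, its
haplotype diversity, assembly coordinates, selection history, or
genotyping error. Consequently, passing tests demonstrate internal
correctness and qualitative behaviour of the two scans on realistic
synthetic data — not that the published effect sizes of the method
contrast carry over to any particular real dataset.

### The scaled-down comparison study

The acceptance study runs 25 replicates at 500 genotyped individuals and a
300-site map (QTL MAF 0.10, effects 0.2 and 0.5 SD, h² 0.34) — sizes
chosen so the whole study completes in about a minute while keeping the
pedigree depth and marker density of the full design. Two caveats follow
from this scale, and they matter when reading the GENMIX–MMA comparison:

1. With ~270 analyzed markers the local trees are shallow — the median SNP
   yields 3 factors, not 7 — and ranking marker `j` by the minimum p over
   its `k_j` tests multiplies the expected rank of an equal-strength
   signal by roughly `k`. GENMIX therefore needs a substantially stronger
   haplotype signal than the best single marker to out-rank MMA.
2. At n = 500 the prescribed effects sit at the detection edge (even a
   test of the true QTL genotype is marginal against the GENMIX
   threshold), so GENMIX's 7-fold stricter per-test threshold is costly.

Under these conditions the single-SNP scan matches or beats the
haplotype-cluster scan on mean power and mean best rank in our synthetic
data, while GENMIX more often places its single top-ranked marker within
1 Mbp of the QTL; at full scale (1,400 genotyped, 1,700 sites) the two
methods perform comparably. The acceptance suite asserts the directional
properties (GENMIX power ≥ MMA power; one-sided Mann–Whitney dominance of
GENMIX's best-rank distribution) exactly as stated, and those two
assertions fail at the scaled-down conditions; the remaining acceptance
checks (bookkeeping, oracle equivalences, calibration, simulator
self-consistency) pass.

## Numerical choices

- Eigenvalues of `A` are clipped at 0 (tolerance −10⁻⁶ relative before
  rejecting a matrix as non-PSD).
- Singular fixed-effect designs are rejected with the aliased columns
  named; Wald blocks with singular covariance are skipped with a recorded
  reason.
- The four-gamete matrix over all site pairs is computed with four boolean
  matrix products; the scalar test enumerates observed gametes directly.
- All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawn keys (dataset, scenario, tie-break
  streams are separate), so studies are reproducible and resumable
  replicate-by-replicate from the cached JSON rows.

## Known limitations

- REML p-values are asymptotic; at very small n the Wald test can drift
  from nominal size (calibration is verified at n = 500).
- The perfect-phylogeny binarization is one deterministic convention among
  several; cut identities 2–7 depend on it.
- The simulator's coalescent founder stage uses a single panmictic
  population; breed admixture and selection are out of scope.
- Phenotypes are simulated only for genotyped individuals; the scans drop
  phenotyped individuals without genotypes (subsetting `A`, which
  preserves relationships through ungenotyped ancestors).
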
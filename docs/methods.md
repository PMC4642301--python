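# Methods

This note defines the statistical procedures implemented in `rohsurv`, the
default parameters and why they were chosen, and the numerical edge-case
policies. Notation: genotypes are coded x ∈ {0, 1, 2} copies of the A1
(minor) allele, −1 for missing; survival groups are STS (short-time
survivors) and LTS (long-time survivors).

## Data model (io_plink)

Text PED/MAP in the PLINK dialect. A1 is the minor allele recomputed from
the data (lexicographically smaller allele on ties); monomorphic variants
get A1 = "0" and code 0, the PLINK convention. Positions are 1-based
inclusive bp; segment `length_kb = (end − start + 1) / 1000`. An optional
`<prefix>.samples.tsv` sidecar carries population labels; otherwise the PED
phenotype column maps 1 → STS, 2 → LTS. Parse errors report line numbers.
QC (`qc_summary`) flags call rate, MAF and heterozygosity outliers without
removing anything; PCA operates on standardized genotypes
(x − 2p)/√(2pq) with mean imputation, excluding monomorphic sites.

## Per-SNP homozygosity association (snp_assoc)

Each SNP yields the 2×2 table (hom/het × STS/LTS), excluding missing calls.
The test is the Pearson χ² without continuity correction,

χ² = N(ad − bc)² / (r₁ r₂ c₁ c₂),  df = 1.

Degenerate tables (a zero marginal) are flagged and reported as χ² = 0,
p = 1 rather than dropped silently. Benjamini–Hochberg q-values use the
true step-up form q(i) = min_{j ≥ i} p(j)·m/j, with `m_total` overridable so
a printed subset of hits can be adjusted against a genome-wide family of
tests. The cohort-level test compares each sample's proportion of
homozygous calls between groups with a one-sided Student t-test (H1:
STS < LTS by default).

Zero-variance boundary: identical constant groups give t = 0 and p = 0.5
(one-sided) / 1.0 (two-sided) instead of the NaN scipy returns.

## ROH detection (roh_detect)

### Minimum run length

Under independent sites with mean heterozygosity h̄, the expected number of
all-homozygous runs of length L across n_SNPs sites and n_samples
individuals is approximately (1 − h̄)^L · n_SNPs · n_samples.
`min_run_length(h̄, n_snps, n_samples, alpha)` returns the smallest integer
L driving this below α. At h̄ = 0.35, 232 478 SNPs, 675 samples, α = 0.05
this gives L = 51 with 0.045 expected chance runs (≈ 4%).

### Caller

PLINK-style two-stage sliding window:

| parameter | default | rationale |
|---|---|---|
| window_snps | 50 | standard window size for array data |
| window_het_max | 0 | autozygous stretches contain no true heterozygotes |
| window_missing_max | 3 | tolerate sporadic no-calls |
| window_hit_threshold | 0.05 | proportion of spanning windows that must be homozygous |
| min_snps | 75 | > L_min = 51 with margin; chance-run expectation ≈ 1e-8 |
| min_kb | 1000 | excludes short common LD-driven homozygous tracts |
| max_gap_kb | 1000 | splits runs across assay gaps |
| min_density_kb_per_snp | 50 | guards against sparse spurious spans |

A run failing the gap rule is rejected rather than split, matching the
conservative convention. Boundary trimming is inherent to the window rule:
a run's outermost ~2 SNPs may fail the hit-proportion threshold, so a
74-SNP homozygous run does not reach the 75-SNP emission criterion.
`validate_segments` re-checks every emitted segment post hoc. Optional LD
pruning is greedy left-to-right: a variant is dropped when r² > 0.8 with
the nearest kept variant within 250 kb (monomorphic variants are kept — they
carry no LD information).

## Pooling and common regions (roh_pool)

Segments are clustered by transitive physical overlap per chromosome
(sweep over start-sorted intervals). The pool consensus is the intersection
of member intervals and must span ≥ 75 SNPs; undersized consensus regions
are repaired by greedily dropping the member whose removal most enlarges
the consensus SNP count. The greedy repair is a heuristic: an exhaustive
subset search can occasionally retain a pool the greedy path discards, but
every emitted pool is guaranteed valid and pooling is invariant to input
order.

A pool is a *common ROH* when it has ≥ 5 carriers, or ≥ 2 carriers all in
one survival group (group-exclusive). Carrier association is tested three
ways: Pearson χ² (no continuity correction), Monte-Carlo χ² over tables
with both margins fixed (hypergeometric draws, p = (1 + k)/(1 + n_mc)), and
two-sided Fisher's exact. Within-region homozygosity uses the same
one-tailed t-test as the cohort-level scan. The FDR non-inferiority test
compares BH q-values of region-restricted vs genome-wide scans of the same
SNPs with a paired one-sided t-test; identical inputs return the boundary
(p = 0.5, difference 0).

## Burden and inbreeding (burden_inbreeding)

Burden metrics (n_roh, total_kb, mean_kb) are compared with Student
t-tests overall and within each population stratum. Population confounding
is handled by a GLM `n_roh ~ group + population` (Gaussian identity by
default, Poisson log optional; the Wald p is z-based) and the
permutation-of-regressor-residuals test: the 0/1 group indicator is
regressed on the covariates, its residuals are permuted and substituted,
and the permutation p is (1 + #{p* ≤ p_obs})/(1 + n_perm). The Gaussian
path uses a direct OLS kernel for speed. A constant outcome returns
coef 0 / p 1 (statsmodels raises on the nan deviance there).

SNP-based inbreeding estimators, with p the pooled sample frequency and
h = 2p(1 − p), averaged over polymorphic SNPs with non-missing calls:

* F_I = mean[(x − 2p)² / h] − 1 (variance of additive genotype values)
* F_II = mean[1 − x(2 − x) / h] (excess homozygosity)
* F_III = mean[(x² − (1 + 2p)x + 2p²) / h] (correlation of uniting gametes)

F_ROH = Σ L_ROH / L_auto over segments ≥ 1000 kb, with
centromere-overlapping portions subtracted when a centromere table is
given. Consanguinity correlations (n_roh, total_kb, F_II, F_ROH) are
Pearson r with two-sided p; samples with n_roh beyond mean + 6 SD are
excluded from the correlations only (and logged).

## Selection statistics (selection_stats)

Computed from phased binary panels (0 ancestral, 1 derived). The unfolded
SFS ξ_i counts sites with derived-allele count i.

* Tajima's D = (π̂ − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants;
  undefined (None) when S = 0; requires n ≥ 4.
* Fay–Wu's H = π̂ − θ_H with θ_H = Σ ξ_i · 2i²/(n(n−1)) (unnormalized,
  original definition); undefined when S = 0; requires n ≥ 3.
* EHH from a core site: among carriers of a core allele,
  EHH(x) = Σ_k C(c_k, 2)/C(c, 2) over counts of distinct haplotypes
  extended from the core to x (incremental partition refinement);
  monotone non-increasing; undefined with < 2 carriers.
* iHS = ln(iHH_ancestral / iHH_derived), with iHH the trapezoidal integral
  of EHH over physical distance, truncated below EHH = 0.05 (partial
  trapezoid down to the floor crossing) and at inter-site gaps > 200 kb;
  cores with derived frequency outside (0.05, 0.95) or a zero integral are
  skipped. Raw scores are standardized within 20 derived-frequency bins;
  singleton or zero-SD bins are flagged (NaN) rather than forced to 0.

Undefined statistics always propagate as None/NaN markers, never as 0.
Region annotation reports windowed max D, min H (window 100 kb, step
window/2) and max |standardized iHS| over cores inside the region.

## Simulation (simulate)

Cohorts follow the Balding–Nichols model: ancestral frequencies
p ~ U(0.05, 0.5) (giving ≈ 36% mean heterozygosity, typical of common
tagging SNPs), per-population frequencies Beta(p(1−F_ST)/F_ST,
(1−p)(1−F_ST)/F_ST) at F_ST = 0.01. Genotypes with per-individual
inbreeding F use P(2) = p² + Fpq, P(1) = 2pq(1 − F). Defaults mirror a
675-woman, four-subpopulation survival cohort (340 STS / 335 LTS split
77/137, 141/143, 43/41, 79/14): group inbreeding 0.004 (STS) / 0.006
(LTS), implanted autozygous-segment rates 0.95/1.08 per person (the
observed 10.61/12.05 genome-wide ROHs per person scaled to the simulated
genome fraction), segment lengths U(1100, 4100) kb (mean 2600 kb), missing
rate 0.002. Implanted segments set each covered SNP homozygous for an
allele drawn at the local population frequency. Output is deterministic
under a fixed seed and minor-A1 oriented so PED/MAP round-trips are exact.

Haplotype panels draw each site's derived count from a configurable SFS
(neutral 1/i weights by default) and can implant a partial sweep: a carrier
fraction shares an identical haplotype within a flank of the core site.
These are direct-SFS draws, not coalescent simulations: sites are
exchangeable and unlinked outside the implanted sweep block.

## Problem sizes

The package's default simulated genome is desk-sized by choice: 20 000 SNPs
over four 60-Mb chromosomes (≈ 8.6 kb spacing, comparable to a ~230k-SNP
genome-wide array) so a full pipeline run takes seconds. All thresholds are
stated in physical units (kb, SNP counts) and apply unchanged to full-scale
arrays; `m_total` lets the FDR be computed against the full test family
when only a subset is analyzed.

## Limitations

* Genotype simulation has no linkage disequilibrium between SNPs outside
  the implanted autozygous segments; LD-pruning behavior is therefore
  validated on constructed duplicated-column datasets.
* Haplotype panels control the SFS directly rather than via a coalescent;
  absolute selection-statistic calibrations are internal.
* The Monte-Carlo carrier test fixes both table margins (the classical
  conditional convention); an unconditional bootstrap is not implemented.
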
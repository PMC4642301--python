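# rohsurv

Case-only homozygosity and runs-of-homozygosity (ROH) analysis for survival
cohorts, with a synthetic-cohort generator and haplotype-based selection
statistics.

The package implements the analysis chain used in case-only cancer-survival
genetics: compare short-time survivors (STS) against long-time survivors
(LTS) on per-SNP homozygosity, detect ROH segments from genotype arrays,
pool shared ROH regions and test carrier enrichment, estimate genomic
inbreeding, and score candidate regions for signatures of recent positive
selection.

## Methods overview

* **Per-SNP homozygosity association** — each SNP is reduced to a 2×2 table
  of homozygote/heterozygote counts in STS vs LTS and tested with a Pearson
  χ² (1 df, no continuity correction). Multiple testing is handled with
  Benjamini–Hochberg step-up q-values against the genome-wide number of
  tests (`m_total`), and the per-sample overall proportion of homozygous
  calls is compared between groups with a one-sided Student t-test.
* **ROH detection** — a PLINK-style sliding-window caller (window of 50
  SNPs, 0 heterozygotes, ≤ 3 missing; SNP hit proportion ≥ 0.05; emitted
  runs need ≥ 75 SNPs, ≥ 1000 kb, gaps ≤ 1000 kb and ≤ 50 kb/SNP density),
  with optional greedy LD pruning (r² > 0.8 within 250 kb). The minimum
  chance-robust run length is derived from
  (1 − h̄)^L · n_SNPs · n_samples < α.
* **ROH pooling** — segments are pooled by transitive physical overlap; a
  pool's consensus is the intersection of its members (greedy member
  dropping repairs undersized consensus regions). Common ROHs (≥ 5 carriers,
  or group-exclusive with ≥ 2) are tested for carrier–group association with
  Pearson χ², a margin-fixed Monte-Carlo χ² and Fisher's exact test, and for
  within-region homozygosity with a one-tailed t-test.
* **Burden and inbreeding** — ROH count/length burden compared by t-tests
  overall and per population; a GLM (`n_roh ~ group + population`) with a
  permutation-of-regressor-residuals test guards against population
  confounding. Per-individual inbreeding via the three SNP-based estimators
  F_I, F_II (excess homozygosity), F_III, and F_ROH = ΣL_ROH / L_auto.
* **Selection statistics** — Tajima's D, Fay–Wu's H (unfolded SFS), EHH and
  iHS (trapezoid-integrated over physical distance, floor 0.05, gap rule
  200 kb, standardized within derived-frequency bins) from phased haplotype
  panels.
* **Simulation** — Balding–Nichols population structure, per-individual
  inbreeding, implanted autozygous segments with group-specific rates, and
  haplotype panels with controlled SFS and optional partial sweeps.

See `docs/methods.md` for definitions, parameter defaults and their
rationale, and numerical edge-case policies.

## Quick start

Derive the minimum chance-robust run length for a genotyping array:

```pycon
>>> from rohsurv import min_run_length
>>> min_run_length(0.35, 232478, 675, 0.05)
(51, 0.045109376295215206)
```

At 35% mean heterozygosity, 232 478 SNPs and 675 samples, homozygous runs of
51 SNPs or more are expected by chance less than 0.05 times genome-wide
(≈ 0.045 expected runs at L = 51).

Run the full pipeline on a simulated cohort:

```sh
cat > sim.yaml <<'YAML'
pop_sizes: {A: [30, 30], B: [30, 30]}
m_variants: 4000
chrom_lengths: {"1": 24000000, "2": 24000000}
fst: 0.01
inbreeding_f: {STS: 0.004, LTS: 0.006}
roh_rate: [0.8, 0.9]
roh_length_kb: [uniform, 1200.0, 3200.0]
missing_rate: 0.002
YAML
rohsurv report --config sim.yaml --seed 7 --out-dir demo
```

which writes per-stage TSVs plus `demo/summary.json`:

```json
{
 "config_hash": "69fef439721d",
 "seed": 7,
 "n_samples": 120,
 "m_variants": 4000,
 "overall_homozygosity": {
  "mean_STS": 0.6556746811526438,
  "mean_LTS": 0.6560237614364853,
  "t": -0.10434283983682766,
  "p": 0.45853721396379615
 },
 "top_snp_p": 0.000241266230746597,
 "n_segments": 107,
 "n_pools": 3,
 "n_common_rohs": 1,
 "glm_group_p": 0.9199650375264312
}
```

and called segments in `demo/roh_segments.tsv`:

```text
sample_id  chrom  start_bp  end_bp    n_snps  length_kb
A_STS_1    1      5445277   7628185   183     2182.909
A_STS_1    1      7940029   10350824  202     2410.796
A_STS_3    1      13277361  14860569  133     1583.209
```

Re-running with the same config and seed is bit-identical. The stages are
also available individually (`rohsurv simulate / assoc / roh / pool /
inbreeding / selection`); their outputs compose to the monolithic `report`
run.

## Library use

```python
import rohsurv as rs

ds = rs.read_ped_map("cohort.ped", "cohort.map",
                     sidecar_path="cohort.samples.tsv")
scan = rs.snp_homozygosity_scan(ds, m_total=232_478)   # chi2, p, BH q
segments = rs.call_rohs(ds)                            # PLINK-style caller
pools = rs.pool_rohs(segments, ds.variants)
common = rs.select_common_rohs(pools, ds.samples)
froh = rs.f_roh(segments, ds.samples, l_auto=2.67e9)
```

## Testing

```sh
python -m pytest tests/
```

The suite covers parsing round-trips, closed-form and brute-force oracles
for every statistic (independent naive implementations of Tajima's D,
Fay–Wu's H, EHH, BH q-values and pooling), parameter-recovery checks on
simulated cohorts and null-calibration checks of all p-values.

## Layout

```
src/rohsurv/        io_plink, simulate, snp_assoc, roh_detect, roh_pool,
                    burden_inbreeding, selection_stats, cli
tests/              pytest suite (tests/test_acceptance.py holds the
                    end-to-end validation criteria)
scripts/acceptance.py
docs/methods.md     model, parameter and edge-case documentation
```
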
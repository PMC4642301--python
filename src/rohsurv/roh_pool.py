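"""Pooling of overlapping ROH segments into common regions, carrier
association with survival group, region-level homozygosity comparison, and
the FDR non-inferiority test.

Segments are pooled by transitive physical overlap within a chromosome; a
pool's consensus is the intersection of its member intervals.  Pools whose
consensus spans fewer SNPs than required are repaired by greedily dropping
the member whose removal most enlarges the consensus.  A pool becomes a
"common ROH" when it has enough carriers or is exclusive to one survival
group.  Carrier enrichment is tested with a Pearson chi-square, a
margin-fixed Monte-Carlo chi-square and Fisher's exact test; within-region
homozygosity is compared by a one-tailed t-test; and Benjamini-Hochberg
FDRs of ROH-restricted vs genome-wide p-values are compared by a paired
one-sided t-test (non-inferiority of the ROH approach).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_plink import MISSING, Dataset
from .snp_assoc import bh_qvalues, pearson_chi2_2x2

GROUPS = ("STS", "LTS")


@dataclass
class ROHPool:
    """Overlapping ROH segments with their consensus (intersection) region."""

    chrom: object
    consensus_start_bp: int
    consensus_end_bp: int
    consensus_n_snps: int
    members: list  # list of (sample_id, start_bp, end_bp)
    carriers_STS: int = 0
    carriers_LTS: int = 0

    @property
    def n_carriers(self) -> int:
        return len({m[0] for m in self.members})


@dataclass
class CommonROH:
    pool: ROHPool
    is_group_exclusive: bool
    chi2: float | None = None
    p_mc: float | None = None
    p_fisher: float | None = None
    p_hom: float | None = None
    spans_centromere: bool = False


def _count_snps(variants: pd.DataFrame, chrom, start_bp, end_bp) -> int:
    v = variants
    sel = (v["chrom"] == chrom) & (v["bp"] >= start_bp) & (v["bp"] <= end_bp)
    return int(sel.sum())


def _consensus(members) -> tuple[int, int]:
    start = max(m[1] for m in members)
    end = min(m[2] for m in members)
    return start, end


def pool_rohs(segments: pd.DataFrame, variants: pd.DataFrame,
              min_overlap_snps: int = 75) -> list[ROHPool]:
    """Pool segments by transitive overlap; repair undersized consensus.

    Members are (sample_id, start_bp, end_bp) triples.  When the
    intersection of a pool's members spans fewer than ``min_overlap_snps``
    SNPs, the member whose removal most enlarges the consensus SNP count is
    dropped (ties: the member with the latest start, then earliest end)
    until the consensus is large enough or a single member remains (in
    which case no pool is formed).  Pooling is invariant to segment order.
    """
    pools: list[ROHPool] = []
    seg = segments.sort_values(["chrom", "start_bp", "end_bp", "sample_id"],
                               kind="mergesort")
    for chrom, grp in seg.groupby("chrom", sort=False):
        members = list(zip(grp["sample_id"], grp["start_bp"].astype(int),
                           grp["end_bp"].astype(int)))
        # transitive overlap on sorted intervals: sweep by start
        cluster: list = []
        cluster_end = None
        clusters: list[list] = []
        for m in members:
            if cluster and m[1] <= cluster_end:
                cluster.append(m)
                cluster_end = max(cluster_end, m[2])
            else:
                if len(cluster) >= 2:
                    clusters.append(cluster)
                cluster = [m]
                cluster_end = m[2]
        if len(cluster) >= 2:
            clusters.append(cluster)

        for cluster in clusters:
            cluster = list(cluster)
            while len(cluster) >= 2:
                start, end = _consensus(cluster)
                n_snps = _count_snps(variants, chrom, start, end) if start <= end else 0
                if n_snps >= min_overlap_snps:
                    pools.append(ROHPool(chrom, start, end, n_snps, cluster))
                    break
                # drop the member whose removal most enlarges the consensus
                best_i, best_n = None, -1
                for i in range(len(cluster)):
                    rest = cluster[:i] + cluster[i + 1 :]
                    s, e = _consensus(rest)
                    ni = _count_snps(variants, chrom, s, e) if s <= e else 0
                    if ni > best_n:
                        best_i, best_n = i, ni
                cluster.pop(best_i)
    return pools


def annotate_carriers(pools: list[ROHPool], samples: pd.DataFrame) -> None:
    group_of = dict(zip(samples["sample_id"], samples["group"]))
    for pool in pools:
        carriers = {m[0] for m in pool.members}
        pool.carriers_STS = sum(1 for s in carriers if group_of[s] == "STS")
        pool.carriers_LTS = sum(1 for s in carriers if group_of[s] == "LTS")


def select_common_rohs(pools: list[ROHPool], samples: pd.DataFrame,
                       min_carriers: int = 5,
                       centromeres: pd.DataFrame | None = None) -> list[CommonROH]:
    """Common ROHs: pools with >= min_carriers carriers, plus pools (of any
    size >= 2) exclusive to one survival group.  When a centromere table
    (chrom, start_bp, end_bp) is given, consensus regions overlapping a
    centromere are flagged."""
    annotate_carriers(pools, samples)
    out = []
    for pool in pools:
        exclusive = (pool.carriers_STS == 0) != (pool.carriers_LTS == 0)
        if pool.n_carriers >= min_carriers or (exclusive and pool.n_carriers >= 2):
            spans = False
            if centromeres is not None:
                hit = centromeres[
                    (centromeres["chrom"].astype(str) == str(pool.chrom))
                    & (centromeres["start_bp"] <= pool.consensus_end_bp)
                    & (centromeres["end_bp"] >= pool.consensus_start_bp)
                ]
                spans = len(hit) > 0
            out.append(CommonROH(pool, exclusive, spans_centromere=spans))
    return out


def carrier_association(carriers_sts: int, carriers_lts: int,
                        n_sts: int, n_lts: int,
                        n_mc: int = 2000, seed: int = 0):
    """Carrier x group 2x2 test.

    Returns (chi2, p_mc, p_fisher): Pearson chi-square (no continuity
    correction), Monte-Carlo chi-square p over tables with both margins
    fixed (hypergeometric construction, as the R convention), and the
    two-sided Fisher exact p.  A table with zero carriers is degenerate
    (chi2 = 0) and p values are 1.
    """
    a, c = carriers_sts, carriers_lts
    b, d = n_sts - a, n_lts - c
    chi2_obs, _, degenerate = pearson_chi2_2x2(a, b, c, d)
    if degenerate:
        return 0.0, 1.0, 1.0
    rng = np.random.default_rng(seed)
    n_carriers = a + c
    # margin-fixed tables: STS carriers ~ Hypergeometric(N, n_STS, n_carriers)
    a_star = rng.hypergeometric(n_sts, n_lts, n_carriers, size=n_mc)
    chi2_star, _, _ = pearson_chi2_2x2(
        a_star, n_sts - a_star, n_carriers - a_star, n_lts - (n_carriers - a_star)
    )
    p_mc = (1 + np.sum(chi2_star >= chi2_obs - 1e-12)) / (n_mc + 1)
    _, p_fisher = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(chi2_obs), float(p_mc), float(p_fisher)


def region_homozygosity_ttest(ds: Dataset, chrom, start_bp: int, end_bp: int,
                              groups=None, alternative: str = "less") -> float:
    """One-tailed t-test of the per-sample proportion of homozygous calls
    inside a region (default H1: mean STS < mean LTS)."""
    v = ds.variants
    cols = v.index[(v["chrom"] == chrom) & (v["bp"] >= start_bp) & (v["bp"] <= end_bp)].to_numpy()
    if len(cols) == 0:
        raise ValueError(f"region {chrom}:{start_bp}-{end_bp} contains no SNPs")
    if groups is None:
        groups = ds.samples["group"].to_numpy()
    groups = np.asarray(groups)
    codes = ds.codes[:, cols]
    obs = (codes != MISSING).sum(axis=1)
    hom = ((codes == 0) | (codes == 2)).sum(axis=1)
    ok = obs > 0
    prop = hom[ok] / obs[ok]
    g = groups[ok]
    levels = [x for x in GROUPS if x in g]
    if len(levels) != 2:
        levels = sorted(pd.unique(g))
    x = prop[g == levels[0]]
    y = prop[g == levels[1]]
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        # degenerate boundary: no variation and no difference
        return 0.5 if alternative != "two-sided" else 1.0
    _, p = stats.ttest_ind(x, y, equal_var=True, alternative=alternative)
    return float(p)


def fdr_noninferiority(p_roh_by_snp, p_gwas_by_snp):
    """Paired one-sided t-test of BH FDRs: H1 mean(FDR_ROH) < mean(FDR_GWAS).

    Both p-value vectors must cover the same SNPs.  q-values are computed
    within each set; returns (p, mean_difference) where the difference is
    mean(q_ROH) - mean(q_GWAS).
    """
    p_roh = np.asarray(p_roh_by_snp, dtype=float)
    p_gwas = np.asarray(p_gwas_by_snp, dtype=float)
    if p_roh.shape != p_gwas.shape:
        raise ValueError("p-value vectors must have equal length")
    q_roh = bh_qvalues(p_roh)
    q_gwas = bh_qvalues(p_gwas)
    diff = q_roh - q_gwas
    if np.allclose(diff, 0):
        return 0.5, 0.0
    _, p = stats.ttest_rel(q_roh, q_gwas, alternative="less")
    return float(p), float(diff.mean())


def common_roh_table(common: list[CommonROH], ds: Dataset,
                     n_mc: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Full per-region report: carriers by group, chi2 / Monte-Carlo /
    Fisher carrier tests and the one-tailed within-region homozygosity p."""
    groups = ds.samples["group"].to_numpy()
    n_sts = int((groups == "STS").sum())
    n_lts = int((groups == "LTS").sum())
    rows = []
    for k, cr in enumerate(common):
        pool = cr.pool
        chi2, p_mc, p_fisher = carrier_association(
            pool.carriers_STS, pool.carriers_LTS, n_sts, n_lts,
            n_mc=n_mc, seed=seed + k,
        )
        p_hom = region_homozygosity_ttest(
            ds, pool.chrom, pool.consensus_start_bp, pool.consensus_end_bp
        )
        cr.chi2, cr.p_mc, cr.p_fisher, cr.p_hom = chi2, p_mc, p_fisher, p_hom
        rows.append(
            (pool.chrom, pool.consensus_start_bp, pool.consensus_end_bp,
             pool.consensus_n_snps, pool.carriers_STS, pool.carriers_LTS,
             cr.is_group_exclusive, chi2, p_mc, p_fisher, p_hom,
             cr.spans_centromere)
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "consensus_start_bp", "consensus_end_bp",
                 "consensus_n_snps", "carriers_STS", "carriers_LTS",
                 "group_exclusive", "chi2", "p_mc", "p_fisher", "p_hom",
                 "spans_centromere"],
    )
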
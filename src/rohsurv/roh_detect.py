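"""Run-of-homozygosity (ROH) detection.

Implements the PLINK-style sliding-window caller: a window of SNPs moves one
SNP at a time across each individual's chromosome; a window is "homozygous"
when it contains no heterozygous call and at most a few missing calls; a SNP
becomes eligible when a sufficient proportion of the windows covering it are
homozygous; maximal runs of eligible SNPs become segments subject to minimum
SNP-count, minimum length, maximum inter-SNP gap and density constraints.

Also provides the chance-run minimum-length derivation
(the smallest run length L with (1 - het)^L * n_snps * n_samples < alpha),
greedy pairwise LD pruning, and per-person burden summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_plink import MISSING, Dataset

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_kb"]


@dataclass
class ROHParams:
    """Caller parameters (PLINK homozyg-* equivalents).

    window_snps: sliding window size in SNPs.
    window_het_max: heterozygous calls tolerated per window (0: none).
    window_missing_max: missing calls tolerated per window.
    window_hit_threshold: minimum proportion of homozygous windows covering
        a SNP for it to be eligible.
    min_snps: minimum SNPs per emitted segment.
    min_kb: minimum segment length in kb.
    max_gap_kb: maximum inter-SNP gap inside a segment, kb.
    min_density_kb_per_snp: maximum kb per SNP (inverse density).
    """

    window_snps: int = 50
    window_het_max: int = 0
    window_missing_max: int = 3
    window_hit_threshold: float = 0.05
    min_snps: int = 75
    min_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self):
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if not (0 < self.window_hit_threshold <= 1):
            raise ValueError("window_hit_threshold must be in (0, 1]")
        for name in ("window_snps", "window_het_max", "window_missing_max",
                     "min_kb", "max_gap_kb", "min_density_kb_per_snp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def min_run_length(mean_het: float, n_snps: int, n_samples: int, alpha: float = 0.05):
    """Smallest integer run length L such that the expected number of
    chance all-homozygous runs, (1 - mean_het)^L * n_snps * n_samples,
    falls below ``alpha``.

    Returns (L_min, expected_count_at_L_min).
    """
    if not (0 < mean_het < 1):
        raise ValueError("mean_het must be in (0, 1)")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    total = float(n_snps) * float(n_samples)
    p_hom = 1.0 - mean_het
    # L = smallest integer with p_hom^L * total < alpha
    l_min = int(np.ceil(np.log(alpha / total) / np.log(p_hom)))
    while p_hom ** l_min * total >= alpha:  # guard against fp edge
        l_min += 1
    while l_min > 1 and p_hom ** (l_min - 1) * total < alpha:
        l_min -= 1
    return l_min, p_hom ** l_min * total


def ld_prune(ds: Dataset, r2_max: float = 0.8, window_bp: int = 250_000):
    """Greedy left-to-right tag-SNP grouping by pairwise genotype r^2.

    Scanning variants in position order within each chromosome, a variant
    joins the tag group of the nearest previously *kept* variant within
    ``window_bp`` whose squared genotype correlation exceeds ``r2_max``;
    otherwise it starts a new group and is kept as that group's
    representative.  Monomorphic variants have undefined r^2 and are always
    kept as their own group.

    Returns (kept_index, n_tag_groups) where kept_index indexes columns of
    the genotype matrix.
    """
    codes = ds.codes.astype(float)
    codes[ds.codes == MISSING] = np.nan
    variants = ds.variants
    kept: list[int] = []
    n_groups = 0
    for _, grp in variants.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        chrom_kept: list[int] = []  # positions into idx of kept variants
        for j in range(len(idx)):
            x = codes[:, idx[j]]
            tagged = False
            # nearest previously kept first
            for kpos in reversed(chrom_kept):
                if bp[j] - bp[kpos] > window_bp:
                    break
                y = codes[:, idx[kpos]]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2:
                    continue
                xs, ys = x[ok], y[ok]
                sx, sy = xs.std(), ys.std()
                if sx == 0 or sy == 0:
                    continue  # monomorphic: r^2 undefined
                r = np.corrcoef(xs, ys)[0, 1]
                if r * r > r2_max:
                    tagged = True
                    break
            if not tagged:
                chrom_kept.append(j)
                kept.append(int(idx[j]))
                n_groups += 1
    return np.array(kept, dtype=int), n_groups


def _call_one(codes: np.ndarray, bp: np.ndarray, params: ROHParams):
    """Candidate segments for one sample on one chromosome.

    Returns list of (start_idx, end_idx) inclusive index pairs of emitted
    segments within this chromosome's SNP order.
    """
    m = len(codes)
    het = codes == 1
    miss = codes == MISSING
    w = min(params.window_snps, m)
    if w < params.window_snps:
        logger.debug("chromosome with %d SNPs < window %d: whole-chromosome window",
                     m, params.window_snps)
    nwin = m - w + 1
    het_c = np.concatenate([[0], np.cumsum(het)])
    miss_c = np.concatenate([[0], np.cumsum(miss)])
    win_het = het_c[w:] - het_c[:-w]
    win_miss = miss_c[w:] - miss_c[:-w]
    hom_win = (win_het <= params.window_het_max) & (win_miss <= params.window_missing_max)

    pos = np.arange(m)
    lo = np.maximum(0, pos - w + 1)
    hi = np.minimum(pos, nwin - 1)
    hw_c = np.concatenate([[0], np.cumsum(hom_win)])
    n_hom = hw_c[hi + 1] - hw_c[lo]
    n_cov = hi - lo + 1
    eligible = (n_hom / n_cov >= params.window_hit_threshold) & ~het

    # maximal runs of eligible SNPs
    out = []
    e = np.concatenate([[False], eligible, [False]])
    starts = np.flatnonzero(~e[:-1] & e[1:])
    ends = np.flatnonzero(e[:-1] & ~e[1:]) - 1
    for s, t in zip(starts, ends):
        n_snps = t - s + 1
        if n_snps < params.min_snps:
            continue
        length_kb = (bp[t] - bp[s] + 1) / 1000.0
        if length_kb < params.min_kb:
            continue
        if n_snps > 1 and np.max(np.diff(bp[s : t + 1])) > params.max_gap_kb * 1000:
            continue
        if length_kb / n_snps > params.min_density_kb_per_snp:
            continue
        out.append((int(s), int(t)))
    return out


def call_rohs(ds: Dataset, params: ROHParams | None = None) -> pd.DataFrame:
    """Call ROH segments for every sample.

    Returns a DataFrame with columns sample_id, chrom, start_bp, end_bp,
    n_snps, length_kb (1-based inclusive coordinates; length in kb is
    (end - start + 1)/1000).  Boundaries are the outermost eligible SNPs.
    """
    if params is None:
        params = ROHParams()
    rows = []
    sample_ids = ds.samples["sample_id"].to_numpy()
    for chrom, grp in ds.variants.groupby("chrom", sort=False):
        cols = grp.index.to_numpy()
        bp = grp["bp"].to_numpy()
        sub = ds.codes[:, cols]
        for i in range(ds.n_samples):
            for s, t in _call_one(sub[i], bp, params):
                rows.append(
                    (
                        sample_ids[i],
                        chrom,
                        int(bp[s]),
                        int(bp[t]),
                        t - s + 1,
                        (bp[t] - bp[s] + 1) / 1000.0,
                    )
                )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def validate_segments(segments: pd.DataFrame, ds: Dataset, params: ROHParams) -> None:
    """Independent post-hoc re-check of the four emission constraints.

    Raises AssertionError on the first violation; used as a validator in
    tests and after pipeline runs.
    """
    v = ds.variants
    for row in segments.itertuples(index=False):
        snps = v[(v["chrom"] == row.chrom) & (v["bp"] >= row.start_bp) & (v["bp"] <= row.end_bp)]
        bp = snps["bp"].to_numpy()
        assert len(snps) == row.n_snps, f"n_snps mismatch for {row}"
        assert row.n_snps >= params.min_snps
        assert row.length_kb >= params.min_kb
        assert row.length_kb / row.n_snps <= params.min_density_kb_per_snp
        if len(bp) > 1:
            assert np.max(np.diff(bp)) <= params.max_gap_kb * 1000


def burden_per_sample(segments: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-sample ROH burden: count, total kb and mean kb.

    Samples without segments get zeros (mean reported as 0 and flagged via
    ``n_roh == 0``).
    """
    agg = segments.groupby("sample_id")["length_kb"].agg(["count", "sum"])
    out = samples[["sample_id", "population", "group"]].copy()
    out = out.merge(
        agg.rename(columns={"count": "n_roh", "sum": "total_kb"}),
        left_on="sample_id",
        right_index=True,
        how="left",
    )
    out["n_roh"] = out["n_roh"].fillna(0).astype(int)
    out["total_kb"] = out["total_kb"].fillna(0.0)
    out["mean_kb"] = np.where(out["n_roh"] > 0, out["total_kb"] / out["n_roh"].replace(0, 1), 0.0)
    return out
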
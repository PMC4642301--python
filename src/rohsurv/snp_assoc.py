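"""SNP-by-SNP homozygosity association between survival groups.

Each SNP is reduced to a 2x2 table of homozygote/heterozygote counts in
short-time (STS) vs long-time (LTS) survivors and tested with a Pearson
chi-square (1 df, no continuity correction).  Multiple testing is handled
with Benjamini-Hochberg step-up q-values against the genome-wide number of
tests, and the per-sample overall proportion of homozygous calls is
compared between groups with a one-sided Student t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_plink import MISSING, Dataset

GROUPS = ("STS", "LTS")


def pearson_chi2_2x2(a, b, c, d):
    """Pearson chi-square without continuity correction for the table
    [[a, b], [c, d]]: chi2 = N (ad - bc)^2 / (r1 r2 c1 c2).

    Accepts scalars or arrays.  Tables with a zero marginal are degenerate:
    chi2 is returned as 0.0 and flagged.
    Returns (chi2, p, degenerate).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(degenerate, 0.0, n * (a * d - b * c) ** 2 / np.where(denom == 0, 1, denom))
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    if chi2.ndim == 0:
        return float(chi2), float(p), bool(degenerate)
    return chi2, p, degenerate


def chi2_homozygosity_test(counts):
    """Chi-square test on one 2x2 homozygote/heterozygote table.

    Parameters
    ----------
    counts : (hom_g1, het_g1, hom_g2, het_g2)

    Returns (chi2, p); degenerate marginals give chi2 = 0, p = 1 and are
    reported via the third element of :func:`pearson_chi2_2x2`.
    """
    a, b, c, d = counts
    chi2, p, _ = pearson_chi2_2x2(a, b, c, d)
    return chi2, p


def hom_het_counts(ds: Dataset, groups=None) -> pd.DataFrame:
    """Per-SNP homozygote/heterozygote counts by survival group.

    Missing genotypes are excluded per SNP, so the group totals vary from
    SNP to SNP.  SNPs with zero non-missing calls are flagged ``degenerate``.
    """
    if groups is None:
        groups = ds.samples["group"].to_numpy()
    groups = np.asarray(groups)
    levels = [g for g in GROUPS if g in groups]
    if len(levels) != 2:
        levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"expected two group levels, got {levels}")
    g1 = groups == levels[0]
    g2 = groups == levels[1]

    codes = ds.codes
    hom = (codes == 0) | (codes == 2)
    het = codes == 1
    out = pd.DataFrame(
        {
            "variant_id": ds.variants["variant_id"].to_numpy(),
            "chrom": ds.variants["chrom"].to_numpy(),
            "bp": ds.variants["bp"].to_numpy(),
            f"hom_{levels[0]}": hom[g1].sum(axis=0),
            f"het_{levels[0]}": het[g1].sum(axis=0),
            f"hom_{levels[1]}": hom[g2].sum(axis=0),
            f"het_{levels[1]}": het[g2].sum(axis=0),
        }
    )
    out["degenerate"] = (codes != MISSING).sum(axis=0) == 0
    out.attrs["levels"] = tuple(levels)
    return out


def snp_homozygosity_scan(ds: Dataset, m_total: int | None = None) -> pd.DataFrame:
    """Full per-SNP scan: counts, chi2, p and BH q-values.

    ``m_total`` defaults to the number of testable SNPs; it may be set
    larger to compute q-values for a printed subset against a genome-wide
    number of tests.
    """
    tab = hom_het_counts(ds)
    l1, l2 = tab.attrs["levels"]
    chi2, p, degenerate = pearson_chi2_2x2(
        tab[f"hom_{l1}"], tab[f"het_{l1}"], tab[f"hom_{l2}"], tab[f"het_{l2}"]
    )
    tab["chi2"] = chi2
    tab["p"] = p
    tab["degenerate"] |= degenerate
    testable = ~tab["degenerate"]
    if m_total is None:
        m_total = int(testable.sum())
    q = np.full(len(tab), np.nan)
    q[testable.to_numpy()] = bh_qvalues(tab.loc[testable, "p"].to_numpy(), m_total)
    tab["q"] = q
    return tab.sort_values("p", kind="mergesort").reset_index(drop=True)


def bh_qvalues(p_values, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( p_(j) * m_total / j ), capped at 1 and mapped
    back to the input order.  ``m_total`` may exceed ``len(p_values)`` when
    q-values are computed for a subset of a larger family of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m_total is None:
        m_total = k
    if m_total < k:
        raise ValueError(f"m_total ({m_total}) < number of p-values ({k})")
    if k == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m_total / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


def overall_homozygosity_test(
    ds: Dataset, groups=None, alternative: str = "less"
):
    """Compare the per-sample proportion of homozygous calls between groups.

    The proportion is homozygous calls / non-missing calls per sample.  The
    default alternative 'less' tests H1: mean(STS) < mean(LTS).

    Returns a dict with the group means, the t statistic and the p-value.
    """
    if groups is None:
        groups = ds.samples["group"].to_numpy()
    groups = np.asarray(groups)
    levels = [g for g in GROUPS if g in groups]
    if len(levels) != 2:
        levels = sorted(pd.unique(groups))
    codes = ds.codes
    obs = (codes != MISSING).sum(axis=1)
    hom = ((codes == 0) | (codes == 2)).sum(axis=1)
    if np.any(obs == 0):
        raise ValueError("sample with zero non-missing calls")
    prop = hom / obs
    x = prop[groups == levels[0]]
    y = prop[groups == levels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 samples")
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        # degenerate boundary: no variation and no difference
        t, p = 0.0, 0.5 if alternative != "two-sided" else 1.0
    else:
        t, p = stats.ttest_ind(x, y, equal_var=True, alternative=alternative)
    return {
        f"mean_{levels[0]}": float(x.mean()),
        f"mean_{levels[1]}": float(y.mean()),
        "t": float(t),
        "p": float(p),
    }
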
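"""Group comparisons of ROH burden and genomic inbreeding.

Burden metrics (segments per person, total and mean segment length) are
compared between survival groups with Student t-tests, overall and within
each population stratum; population confounding is handled with a
generalized linear model (n_roh ~ group + population) and a permutation
test that permutes the residuals of the group indicator regressed on the
covariates (the glmperm approach).

Inbreeding is estimated per individual three ways (the GCTA-style SNP
estimators):

    F_I   = mean_j[(x_ij - 2 p_j)^2 / h_j] - 1        (variance of additive values)
    F_II  = mean_j[1 - x_ij (2 - x_ij) / h_j]          (excess homozygosity)
    F_III = mean_j[(x_ij^2 - (1 + 2 p_j) x_ij + 2 p_j^2) / h_j]  (uniting gametes)

with h_j = 2 p_j (1 - p_j), plus the ROH-based coefficient
F_ROH = sum(L_ROH) / L_AUTO over segments above a criterion length, with
centromere-overlapping portions removed when a centromere table is given.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_plink import MISSING, Dataset

logger = logging.getLogger(__name__)

BURDEN_METRICS = ("n_roh", "total_kb", "mean_kb")


def burden_group_tests(burden: pd.DataFrame, stratify_by_population: bool = True,
                       welch: bool = False) -> pd.DataFrame:
    """Two-sample t-tests of burden metrics between survival groups,
    overall and per population stratum.  Student (equal-variance) by
    default; set ``welch`` for unequal variances."""
    strata = [("all", burden)]
    if stratify_by_population:
        strata += [(pop, grp) for pop, grp in burden.groupby("population", sort=False)]
    rows = []
    for name, grp in strata:
        g = grp["group"].to_numpy()
        levels = [x for x in ("STS", "LTS") if x in g]
        if len(levels) != 2 or min((g == l).sum() for l in levels) < 2:
            logger.info("burden_group_tests: skipping stratum %r (missing group)", name)
            continue
        for metric in BURDEN_METRICS:
            x = grp.loc[g == "STS", metric].to_numpy(dtype=float)
            y = grp.loc[g == "LTS", metric].to_numpy(dtype=float)
            if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(x, y, equal_var=not welch)
            rows.append((name, metric, x.mean(), y.mean(), float(t), float(p)))
    return pd.DataFrame(rows, columns=["stratum", "metric", "mean_STS", "mean_LTS", "t", "p"])


def _design(group, population):
    """Design matrix [intercept, population dummies, group indicator];
    drops the population term when there is a single level."""
    group = np.asarray(group)
    g01 = (group == "LTS").astype(float) if "LTS" in group else (
        group == sorted(pd.unique(group))[-1]
    ).astype(float)
    population = pd.Series(np.asarray(population, dtype=object))
    levels = list(pd.unique(population))
    if len(levels) > 1:
        dummies = pd.get_dummies(population, drop_first=True, dtype=float).to_numpy()
    else:
        logger.info("single population: covariate dropped from GLM")
        dummies = np.empty((len(group), 0))
    x = np.column_stack([np.ones(len(group)), dummies])
    return x, g01


def glm_burden(n_roh, group, population, family: str = "gaussian"):
    """Fit n_roh ~ group + population and report the Wald p for group.

    family: "gaussian" (identity link, default) or "poisson" (log link).
    Returns a dict with the group coefficient, its standard error and p,
    and the fitted statsmodels results object.
    """
    y = np.asarray(n_roh, dtype=float)
    x_cov, g01 = _design(group, population)
    exog = np.column_stack([x_cov, g01])
    if np.all(y == y[0]):
        # constant outcome: the group effect is exactly zero and untestable
        logger.info("glm_burden: constant outcome; group effect undefined (p = 1)")
        return {"coef_group": 0.0, "se_group": float("nan"), "p_group": 1.0,
                "family": family, "result": None}
    fam = {"gaussian": sm.families.Gaussian(), "poisson": sm.families.Poisson()}[family]
    res = sm.GLM(y, exog, family=fam).fit()
    j = exog.shape[1] - 1
    return {
        "coef_group": float(res.params[j]),
        "se_group": float(res.bse[j]),
        "p_group": float(res.pvalues[j]),
        "family": family,
        "result": res,
    }


def permutation_regressor_residuals(n_roh, group, population,
                                    family: str = "gaussian",
                                    n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation-of-regressor-residuals test for the group term.

    The 0/1 group indicator is regressed on the remaining covariates; its
    residuals are permuted and substituted for the group term, the outcome
    model is refitted, and the permutation p is the proportion of permuted
    fits whose group-term p-value is at most the observed one, with the
    (1 + k) / (1 + n_perm) correction.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: permutation p will be coarse", n_perm)
    y = np.asarray(n_roh, dtype=float)
    x_cov, g01 = _design(group, population)
    # residualize the regressor on the covariates
    beta, *_ = np.linalg.lstsq(x_cov, g01, rcond=None)
    r = g01 - x_cov @ beta
    if np.allclose(r.std(), 0):
        raise ValueError("group indicator is collinear with covariates (zero-variance residuals)")

    rng = np.random.default_rng(seed)
    if family == "gaussian":
        p_obs = _ols_term_p(y, x_cov, r)
        count = 0
        for _ in range(n_perm):
            r_star = rng.permutation(r)
            if _ols_term_p(y, x_cov, r_star) <= p_obs + 1e-15:
                count += 1
    else:
        p_obs = glm_burden(y, group, population, family=family)["p_group"]
        fam = sm.families.Poisson()
        count = 0
        for _ in range(n_perm):
            r_star = rng.permutation(r)
            exog = np.column_stack([x_cov, r_star])
            res = sm.GLM(y, exog, family=fam).fit()
            if res.pvalues[-1] <= p_obs + 1e-15:
                count += 1
    return (1 + count) / (1 + n_perm)


def _ols_term_p(y, x_cov, r):
    """Two-sided t-test p for the last column of [x_cov, r] in an OLS fit."""
    x = np.column_stack([x_cov, r])
    n, k = x.shape
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    if se == 0:
        return 1.0
    t = beta[-1] / se
    return 2 * stats.t.sf(abs(t), dof)


# ---------------------------------------------------------------------------
# Inbreeding estimators


def inbreeding_coeffs(ds: Dataset, per_chromosome: bool = False,
                      allele_freqs=None) -> pd.DataFrame:
    """Per-sample SNP-based inbreeding estimators F_I, F_II, F_III.

    Allele frequencies default to the pooled-sample estimate; monomorphic
    SNPs are excluded; missing genotypes are excluded per SNP per sample.
    With ``per_chromosome`` the estimators are also returned per chromosome
    (column ``scope`` = chromosome label, 'genome' for the genome-wide row).
    """
    scopes = [("genome", np.arange(ds.m_variants))]
    if per_chromosome:
        for chrom, grp in ds.variants.groupby("chrom", sort=False):
            scopes.append((str(chrom), grp.index.to_numpy()))
    frames = []
    for scope, cols in scopes:
        frames.append(_inbreeding_scope(ds, cols, scope, allele_freqs))
    return pd.concat(frames, ignore_index=True)


def _inbreeding_scope(ds: Dataset, cols, scope: str, allele_freqs) -> pd.DataFrame:
    codes = ds.codes[:, cols].astype(float)
    missing = ds.codes[:, cols] == MISSING
    codes[missing] = np.nan
    if allele_freqs is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(codes, axis=0) / 2.0
    else:
        p = np.asarray(allele_freqs)[cols]
    usable = (p > 0) & (p < 1) & ~np.isnan(p)
    codes = codes[:, usable]
    missing = missing[:, usable]
    p = p[usable]
    if codes.shape[1] == 0:
        raise ValueError(f"no polymorphic SNPs usable in scope {scope!r}")
    h = 2 * p * (1 - p)

    x = codes
    f1_terms = (x - 2 * p) ** 2 / h
    f2_terms = 1 - x * (2 - x) / h
    f3_terms = (x**2 - (1 + 2 * p) * x + 2 * p**2) / h
    with np.errstate(invalid="ignore"):
        f1 = np.nanmean(f1_terms, axis=1) - 1
        f2 = np.nanmean(f2_terms, axis=1)
        f3 = np.nanmean(f3_terms, axis=1)
    n_used = (~np.isnan(x)).sum(axis=1)
    if np.any(n_used == 0):
        raise ValueError("sample with zero usable SNPs in scope " + scope)
    return pd.DataFrame(
        {
            "sample_id": ds.samples["sample_id"].to_numpy(),
            "scope": scope,
            "F_I": f1,
            "F_II": f2,
            "F_III": f3,
        }
    )


def f_roh(segments: pd.DataFrame, samples: pd.DataFrame, l_auto: float,
          centromeres: pd.DataFrame | None = None, min_kb: float = 1000.0,
          per_chromosome: dict | None = None) -> pd.DataFrame:
    """ROH-based genomic inbreeding: F_ROH = sum(L_ROH) / L_AUTO per sample.

    Only segments of at least ``min_kb`` contribute.  When a centromere
    table (chrom, start_bp, end_bp) is given, the centromere-overlapping
    portion of each segment is removed before summation.  ``l_auto`` is the
    mappable autosomal length in bp.  ``per_chromosome`` optionally maps
    chromosome label -> mappable length for per-chromosome coefficients.
    """
    if l_auto <= 0:
        raise ValueError("l_auto must be positive")
    seg = segments[segments["length_kb"] >= min_kb].copy()
    lengths = (seg["end_bp"] - seg["start_bp"] + 1).to_numpy(dtype=float)
    if centromeres is not None and len(seg):
        for c in centromeres.itertuples(index=False):
            hit = (seg["chrom"].astype(str) == str(c.chrom)).to_numpy()
            if not hit.any():
                continue
            ov = np.minimum(seg["end_bp"].to_numpy(), c.end_bp) - np.maximum(
                seg["start_bp"].to_numpy(), c.start_bp
            ) + 1
            lengths = np.where(hit, lengths - np.clip(ov, 0, None), lengths)
    seg = seg.assign(_len=np.clip(lengths, 0, None))

    out = samples[["sample_id"]].copy()
    total = seg.groupby("sample_id")["_len"].sum()
    out["F_ROH"] = out["sample_id"].map(total).fillna(0.0) / l_auto
    if per_chromosome:
        for chrom, l_chrom in per_chromosome.items():
            sub = seg[seg["chrom"].astype(str) == str(chrom)]
            tot = sub.groupby("sample_id")["_len"].sum()
            out[f"F_ROH_{chrom}"] = out["sample_id"].map(tot).fillna(0.0) / l_chrom
    return out


def consanguinity_correlations(burden: pd.DataFrame, inbreeding: pd.DataFrame,
                               froh: pd.DataFrame,
                               outlier_sd: float = 6.0):
    """Pairwise Pearson correlations among consanguinity measures
    {n_roh, total_kb, F_II, F_ROH} with two-sided p-values.

    Samples whose total ROH count exceeds mean + ``outlier_sd`` * SD are
    excluded from the correlation analysis only (and logged).  Returns
    (r_matrix, p_matrix) DataFrames.
    """
    df = burden[["sample_id", "n_roh", "total_kb"]].merge(
        inbreeding.loc[inbreeding["scope"] == "genome", ["sample_id", "F_II"]],
        on="sample_id",
    ).merge(froh[["sample_id", "F_ROH"]], on="sample_id")
    if len(df) < 3:
        raise ValueError("need >= 3 samples for correlations")
    n_roh = df["n_roh"].to_numpy(dtype=float)
    keep = n_roh <= n_roh.mean() + outlier_sd * n_roh.std()
    if (~keep).any():
        logger.info("consanguinity_correlations: excluding %d outlier(s): %s",
                    (~keep).sum(), list(df.loc[~keep, "sample_id"]))
        df = df[keep]
    cols = ["n_roh", "total_kb", "F_II", "F_ROH"]
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            x, y = df[ci].to_numpy(float), df[cj].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                logger.info("zero-variance column %s or %s: r undefined", ci, cj)
                continue
            rij, pij = stats.pearsonr(x, y)
            r.loc[ci, cj] = r.loc[cj, ci] = rij
            p.loc[ci, cj] = p.loc[cj, ci] = pij
    return r, p


def inbreeding_group_tests(measures: pd.DataFrame, samples: pd.DataFrame,
                           columns=("F_I", "F_II", "F_III", "F_ROH"),
                           alternative: str = "less") -> pd.DataFrame:
    """Per-measure one-sided t-test (default H1: mean STS < mean LTS) and a
    linear regression of the measure on the 0/1 group indicator.

    ``measures`` must carry sample_id plus the requested columns (use the
    genome scope of :func:`inbreeding_coeffs`, merged with F_ROH).
    """
    df = measures.merge(samples[["sample_id", "group"]], on="sample_id")
    g = df["group"].to_numpy()
    rows = []
    for col in columns:
        if col not in df:
            continue
        x = df.loc[g == "STS", col].to_numpy(float)
        y = df.loc[g == "LTS", col].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError("each group needs >= 2 samples")
        t, p_t = stats.ttest_ind(x, y, equal_var=True, alternative=alternative)
        g01 = (g == "LTS").astype(float)
        exog = sm.add_constant(g01)
        fit = sm.OLS(df[col].to_numpy(float), exog).fit()
        rows.append((col, x.mean(), y.mean(), float(t), float(p_t),
                     float(fit.params[1]), float(fit.pvalues[1])))
    return pd.DataFrame(rows, columns=["measure", "mean_STS", "mean_LTS",
                                       "t", "p_t", "coef_glm", "p_glm"])
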
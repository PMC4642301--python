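"""PLINK text PED/MAP input/output, the in-memory genotype data model,
basic QC summaries and a genotype PCA for stratification plots.

Genotypes are held as an ``n_samples x m_variants`` integer matrix counting
copies of the A1 allele (0, 1, 2) with ``MISSING = -1`` as a distinguished
sentinel.  Coordinates are 1-based inclusive base pairs as in the PLINK MAP
dialect; a segment of ``start..end`` has length ``end - start + 1`` bp.

By convention A1 is the *minor* allele, recomputed from the data on read
(PED files carry no explicit allele order).  ``minor_orient`` applies the
same convention to an in-memory dataset so that write -> read round-trips
are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call. Never counted as hom or het.
MISSING = -1

VARIANT_COLUMNS = ["variant_id", "chrom", "bp", "a1", "a2"]
SAMPLE_COLUMNS = ["sample_id", "population", "group"]


class PlinkParseError(ValueError):
    """Raised on malformed PED/MAP input (carries the offending line number)."""


@dataclass
class Dataset:
    """A genotype matrix linked to its variant and sample tables.

    Attributes
    ----------
    codes : ndarray of shape (n_samples, m_variants)
        A1-allele dosage codes in {0, 1, 2, MISSING}.
    variants : DataFrame with columns variant_id, chrom, bp, a1, a2.
    samples : DataFrame with columns sample_id, population, group.
    """

    codes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def m_variants(self) -> int:
        return self.codes.shape[1]

    def validate(self) -> "Dataset":
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x variants)")
        if self.codes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match tables "
                f"({len(self.samples)} samples, {len(self.variants)} variants)"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        validate_variant_table(self.variants)
        validate_sample_table(self.samples)
        return self


def validate_variant_table(variants: pd.DataFrame) -> None:
    if variants["variant_id"].duplicated().any():
        dup = variants.loc[variants["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"duplicate variant id: {dup!r}")
    if len(variants) and (variants["bp"] < 1).any():
        raise ValueError("bp positions must be >= 1")
    for chrom, grp in variants.groupby("chrom", sort=False):
        bp = grp["bp"].to_numpy()
        if len(bp) > 1 and not (np.diff(bp) > 0).all():
            i = int(np.flatnonzero(np.diff(bp) <= 0)[0])
            raise ValueError(
                f"bp not strictly increasing on chrom {chrom}: "
                f"{grp['variant_id'].iloc[i]} (bp {bp[i]}) followed by "
                f"{grp['variant_id'].iloc[i + 1]} (bp {bp[i + 1]})"
            )


def validate_sample_table(samples: pd.DataFrame) -> None:
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    levels = set(samples["group"].unique())
    if len(samples) and len(levels) > 2:
        raise ValueError(f"group must have at most two levels, got {sorted(levels)}")


# ---------------------------------------------------------------------------
# PED/MAP reading and writing


def read_map(map_path) -> pd.DataFrame:
    """Read a 4-column PLINK MAP file (chrom, id, cM, bp)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise PlinkParseError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(fields)}"
                )
            rows.append((fields[1], fields[0], int(fields[3])))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "bp"])
    variants["a1"] = ""
    variants["a2"] = ""
    return variants


def read_ped_map(ped_path, map_path, sidecar_path=None) -> Dataset:
    """Read genotypes from whitespace-delimited PED/MAP text files.

    Any "0" allele makes the call MISSING.  A1 is assigned per variant as the
    minor allele of the data (ties broken toward the lexicographically
    smaller allele); genotype codes count A1 copies.

    Sample annotations come from ``sidecar_path`` (TSV with columns
    sample_id, population, group) when given; otherwise the family ID column
    is used as the population label and phenotype column 6 is mapped
    1 -> STS, 2 -> LTS.
    """
    variants = read_map(map_path)
    m = len(variants)

    sample_rows = []
    allele_a: list[np.ndarray] = []
    allele_b: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} columns "
                    f"(6 + 2 x {m} variants), got {len(fields)}"
                )
            fid, iid, _father, _mother, _sex, pheno = fields[:6]
            sample_rows.append((iid, fid, {"1": "STS", "2": "LTS"}.get(pheno, pheno)))
            alleles = np.array(fields[6:], dtype="U8")
            allele_a.append(alleles[0::2])
            allele_b.append(alleles[1::2])

    n = len(sample_rows)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population", "group"])
    a = np.array(allele_a).reshape(n, m) if n else np.empty((0, m), dtype="U8")
    b = np.array(allele_b).reshape(n, m) if n else np.empty((0, m), dtype="U8")

    codes = np.full((n, m), MISSING, dtype=np.int16)
    a1 = np.empty(m, dtype="U8")
    a2 = np.empty(m, dtype="U8")
    for j in range(m):
        col_a, col_b = a[:, j], b[:, j]
        ok = (col_a != "0") & (col_b != "0")
        obs = np.concatenate([col_a[ok], col_b[ok]])
        uniq, counts = np.unique(obs, return_counts=True)
        if len(uniq) > 2:
            raise PlinkParseError(
                f"variant {variants['variant_id'].iloc[j]} has >2 alleles: {list(uniq)}"
            )
        if len(uniq) == 0:
            a1[j], a2[j] = "0", "0"
            continue
        if len(uniq) == 1:
            # monomorphic: the minor allele is unobserved (PLINK writes A1 "0")
            a1[j], a2[j] = "0", uniq[0]
        else:
            # minor allele first; lexicographic tie-break for determinism
            order = np.lexsort((uniq, counts))
            a1[j], a2[j] = uniq[order[0]], uniq[order[1]]
        codes[ok, j] = (col_a[ok] == a1[j]).astype(np.int16) + (
            col_b[ok] == a1[j]
        ).astype(np.int16)

    variants["a1"] = a1
    variants["a2"] = a2

    if sidecar_path is not None:
        sidecar = pd.read_csv(sidecar_path, sep="\t", dtype=str)
        samples = samples[["sample_id"]].merge(sidecar, on="sample_id", how="left")

    ds = Dataset(codes=codes, variants=variants, samples=samples)
    ds.validate()
    return ds


def write_ped_map(ds: Dataset, out_prefix, sidecar: bool = True) -> dict:
    """Write ``<prefix>.ped`` / ``<prefix>.map`` (and a sample sidecar TSV).

    MISSING codes become "0 0" allele pairs. Files round-trip through
    :func:`read_ped_map` with identical codes provided the dataset is in
    minor-A1 orientation (see :func:`minor_orient`).
    """
    out_prefix = str(out_prefix)
    v = ds.variants
    with open(out_prefix + ".map", "w") as fh:
        for row in v.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.variant_id}\t0\t{row.bp}\n")

    group_to_pheno = {"STS": "1", "LTS": "2"}
    a1 = v["a1"].to_numpy()
    a2 = v["a2"].to_numpy()
    with open(out_prefix + ".ped", "w") as fh:
        for i, srow in enumerate(ds.samples.itertuples(index=False)):
            codes = ds.codes[i]
            first = np.where(codes >= 1, a1, a2)
            second = np.where(codes == 2, a1, a2)
            missing = codes == MISSING
            first = np.where(missing, "0", first)
            second = np.where(missing, "0", second)
            pairs = " ".join(f"{x} {y}" for x, y in zip(first, second))
            pheno = group_to_pheno.get(str(srow.group), str(srow.group))
            fh.write(
                f"{srow.population} {srow.sample_id} 0 0 0 {pheno} {pairs}\n"
            )

    paths = {"ped": out_prefix + ".ped", "map": out_prefix + ".map"}
    if sidecar:
        ds.samples.to_csv(out_prefix + ".samples.tsv", sep="\t", index=False)
        paths["sidecar"] = out_prefix + ".samples.tsv"
    return paths


def minor_orient(ds: Dataset) -> Dataset:
    """Return a copy with every variant oriented so that A1 is the minor
    allele (count ties broken toward the lexicographically smaller allele),
    matching the orientation :func:`read_ped_map` reconstructs."""
    codes = ds.codes.copy()
    variants = ds.variants.copy()
    obs = codes != MISSING
    with np.errstate(invalid="ignore"):
        n_obs = obs.sum(axis=0)
        a1_count = np.where(codes == MISSING, 0, codes).sum(axis=0)
    a2_count = 2 * n_obs - a1_count
    a1 = variants["a1"].to_numpy()
    a2 = variants["a2"].to_numpy()
    flip = (a1_count > a2_count) | ((a1_count == a2_count) & (a2 < a1))
    flip &= n_obs > 0
    if flip.any():
        cols = np.flatnonzero(flip)
        block = codes[:, cols]
        block[block != MISSING] = 2 - block[block != MISSING]
        codes[:, cols] = block
        variants.loc[variants.index[cols], ["a1", "a2"]] = np.column_stack(
            [a2[cols], a1[cols]]
        )
    return Dataset(codes=codes, variants=variants, samples=ds.samples.copy())


# ---------------------------------------------------------------------------
# QC summaries


def qc_summary(
    ds: Dataset,
    min_variant_call_rate: float = 0.95,
    min_sample_call_rate: float = 0.95,
    min_maf: float = 0.01,
) -> dict:
    """Per-variant call rate / MAF / heterozygosity and per-sample call rate
    / mean heterozygosity.  Failing rows are flagged, never removed."""
    if ds.m_variants == 0 or ds.n_samples == 0:
        raise ValueError("qc_summary requires a non-empty dataset")
    codes = ds.codes
    obs = codes != MISSING
    het = codes == 1

    v_n = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_call = v_n / ds.n_samples
        a1_freq = np.where(codes == MISSING, 0, codes).sum(axis=0) / (2.0 * v_n)
        maf = np.minimum(a1_freq, 1.0 - a1_freq)
        v_het = het.sum(axis=0) / v_n
    maf = np.where(v_n == 0, np.nan, maf)
    v_het = np.where(v_n == 0, np.nan, v_het)

    s_n = obs.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s_call = s_n / ds.m_variants
        s_het = het.sum(axis=1) / s_n
    s_het = np.where(s_n == 0, np.nan, s_het)

    variant_qc = pd.DataFrame(
        {
            "variant_id": ds.variants["variant_id"].to_numpy(),
            "call_rate": v_call,
            "maf": maf,
            "het_prop": v_het,
        }
    )
    variant_qc["fail"] = (
        (variant_qc["call_rate"] < min_variant_call_rate)
        | (variant_qc["maf"].fillna(0) < min_maf)
        | variant_qc["maf"].isna()
    )
    sample_qc = pd.DataFrame(
        {
            "sample_id": ds.samples["sample_id"].to_numpy(),
            "call_rate": s_call,
            "mean_het": s_het,
        }
    )
    sample_qc["fail"] = sample_qc["call_rate"] < min_sample_call_rate
    return {"variants": variant_qc, "samples": sample_qc}


def pca_genotypes(ds: Dataset, k: int) -> pd.DataFrame:
    """PCA of the standardized genotype matrix.

    Variants are centred at 2p and scaled by sqrt(2p(1-p)); missing calls
    are imputed to the variant mean.  Monomorphic variants are excluded.
    Sign convention: within each component the largest-magnitude variant
    loading is made positive, so scores are deterministic.
    """
    if k < 0 or k >= min(ds.n_samples, ds.m_variants):
        if k != 0:
            raise ValueError("k must satisfy 0 <= k < min(n_samples, m_variants)")
    scores = pd.DataFrame({"sample_id": ds.samples["sample_id"].to_numpy()})
    if k == 0:
        return scores

    codes = ds.codes.astype(float)
    codes[ds.codes == MISSING] = np.nan
    p = np.nanmean(codes, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("pca_genotypes: excluding %d monomorphic variants", n_mono)
    X = codes[:, poly]
    p = p[poly]
    X = np.where(np.isnan(X), 2 * p, X)
    X = (X - 2 * p) / np.sqrt(2 * p * (1 - p))

    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for c in range(k):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    for c in range(k):
        scores[f"PC{c + 1}"] = u[:, c] * s[c]
    return scores
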
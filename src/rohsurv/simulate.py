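"""Synthetic genotype cohorts and haplotype panels.

The cohort generator emulates the design of a case-only survival study:
four population subgroups of unequal size split into short-time (STS) and
long-time (LTS) survivor groups, allele-frequency divergence between
subpopulations under the Balding-Nichols model, per-individual inbreeding,
implanted autozygous segments whose expected count may differ by survival
group, and missing calls.  Defaults are scaled to a desk-size genome
(20 000 SNPs over four 60-Mb chromosomes, ~8.6 kb/SNP spacing comparable to
a ~230k-SNP genome-wide array) with subgroup sizes and group effects chosen
to mirror a 675-woman cohort (340 STS / 335 LTS).

The haplotype generator produces phased binary panels (0 = ancestral,
1 = derived) with a controllable site-frequency spectrum and an optional
partial-sweep core haplotype, for exercising Tajima's D, Fay-Wu's H, EHH
and iHS.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_plink import MISSING, Dataset, minor_orient

logger = logging.getLogger(__name__)

# (population, n_STS, n_LTS) mirroring the post-QC study cohort
DEFAULT_POP_SIZES = {
    "Umea": (77, 137),
    "Iceland": (141, 143),
    "Malmo": (43, 41),
    "German": (79, 14),
}


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    pop_sizes: mapping population -> (n_STS, n_LTS).
    m_variants: total autosomal SNPs, split evenly across chromosomes.
    chrom_lengths: mapping chrom label -> length in bp.
    fst: Balding-Nichols divergence between subpopulations.
    base_maf_range: ancestral allele frequency drawn Uniform(range); the
        default (0.05, 0.5) gives ~36% mean heterozygosity, matching an
        array of common tagging SNPs.
    inbreeding_f: per-individual inbreeding coefficient; a float, a
        mapping group -> float, or ("beta", a, b).
    roh_rate: expected implanted autozygous segments per individual,
        (lambda_STS, lambda_LTS).  Defaults scale the study's 10.61/12.05
        genome-wide ROHs per person to the simulated genome fraction.
    roh_length_kb: ("uniform", lo, hi) or ("constant", kb); default mean
        2 600 kb as in the study's segments.
    missing_rate: per-call missing probability.
    """

    pop_sizes: dict = field(default_factory=lambda: dict(DEFAULT_POP_SIZES))
    m_variants: int = 20_000
    chrom_lengths: dict = field(
        default_factory=lambda: {"1": 60_000_000, "2": 60_000_000,
                                 "3": 60_000_000, "4": 60_000_000}
    )
    fst: float = 0.01
    base_maf_range: tuple = (0.05, 0.5)
    inbreeding_f: object = field(default_factory=lambda: {"STS": 0.004, "LTS": 0.006})
    roh_rate: tuple = (0.95, 1.08)
    roh_length_kb: tuple = ("uniform", 1100.0, 4100.0)
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        lo, hi = self.base_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("base_maf_range must lie in (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if any(r < 0 for r in self.roh_rate):
            raise ValueError("roh_rate entries must be >= 0")
        max_len_kb = _length_dist_max(self.roh_length_kb)
        if min(self.chrom_lengths.values()) < max_len_kb * 1000:
            raise ValueError("every chromosome must fit the largest implantable segment")


def _length_dist_max(spec) -> float:
    kind = spec[0]
    if kind == "uniform":
        return float(spec[2])
    if kind == "constant":
        return float(spec[1])
    raise ValueError(f"unknown roh_length_kb spec {spec!r}")


def _draw_length_kb(spec, rng) -> float:
    kind = spec[0]
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    return float(spec[1])


def _sample_f(spec, group: str, n: int, rng) -> np.ndarray:
    if isinstance(spec, dict):
        return np.full(n, float(spec[group]))
    if isinstance(spec, (tuple, list)) and spec and spec[0] == "beta":
        return rng.beta(spec[1], spec[2], size=n)
    return np.full(n, float(spec))


def _variant_grid(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced SNP positions, m_variants split across chromosomes
    proportionally to length."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    m_per = np.floor(config.m_variants * lengths / lengths.sum()).astype(int)
    m_per[: config.m_variants - m_per.sum()] += 1
    rows = []
    j = 0
    for chrom, m, length in zip(chroms, m_per, lengths):
        spacing = length / (m + 1)
        bp = (np.arange(1, m + 1) * spacing).astype(np.int64)
        for b in bp:
            rows.append((f"snp{j}", chrom, int(b)))
            j += 1
    v = pd.DataFrame(rows, columns=["variant_id", "chrom", "bp"])
    v["a1"] = "A"
    v["a2"] = "G"
    return v


def simulate_cohort(config: SimulationConfig):
    """Generate a structured, inbred cohort with implanted autozygous runs.

    Returns (dataset, truth) where ``truth`` records per-sample inbreeding
    coefficients and implanted segments (merged per sample where they
    overlap), plus the configuration used.  Output is deterministic under a
    fixed seed and minor-A1 oriented for exact PED/MAP round-trips.
    """
    rng = np.random.default_rng(config.seed)
    variants = _variant_grid(config)
    m = len(variants)

    p_anc = rng.uniform(config.base_maf_range[0], config.base_maf_range[1], size=m)

    sample_rows = []
    f_values = []
    pop_freqs = {}
    for pop, (n_sts, n_lts) in config.pop_sizes.items():
        if config.fst > 0:
            a = p_anc * (1 - config.fst) / config.fst
            b = (1 - p_anc) * (1 - config.fst) / config.fst
            pop_freqs[pop] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)
        else:
            pop_freqs[pop] = p_anc.copy()
        for group, n in (("STS", n_sts), ("LTS", n_lts)):
            f = _sample_f(config.inbreeding_f, group, n, rng)
            for i in range(n):
                sample_rows.append((f"{pop}_{group}_{i}", pop, group))
            f_values.append(f)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population", "group"])
    f_all = np.concatenate(f_values) if f_values else np.empty(0)

    n = len(samples)
    codes = np.empty((n, m), dtype=np.int16)
    row = 0
    for pop, (n_sts, n_lts) in config.pop_sizes.items():
        p = pop_freqs[pop]
        q = 1 - p
        n_pop = n_sts + n_lts
        f = f_all[row : row + n_pop][:, None]
        t2 = p**2 + f * p * q              # P(code 2)
        t1 = t2 + 2 * p * q * (1 - f)      # P(code 2 or 1)
        u = rng.random((n_pop, m))
        codes[row : row + n_pop] = (u < t2).astype(np.int16) + (u < t1).astype(np.int16)
        row += n_pop

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        codes[miss] = MISSING

    ds = Dataset(codes=codes, variants=variants, samples=samples)

    # implant autozygous segments
    pop_of = samples["population"].to_numpy()
    group_of = samples["group"].to_numpy()
    lam = {"STS": config.roh_rate[0], "LTS": config.roh_rate[1]}
    chroms = list(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    implanted: list[dict] = []
    max_len_bp = _length_dist_max(config.roh_length_kb) * 1000
    for i in range(n):
        k = rng.poisson(lam[group_of[i]])
        for _ in range(k):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            length_kb = _draw_length_kb(config.roh_length_kb, rng)
            start = int(rng.integers(1, config.chrom_lengths[chrom] - int(length_kb * 1000) + 1))
            rec = implant_roh(
                ds, i, chrom, start, length_kb,
                rng=rng, allele_freq=pop_freqs[pop_of[i]],
            )
            if rec is not None:
                implanted.append(rec)

    ds = minor_orient(ds)
    truth = {
        "config": _config_json(config),
        "f": {samples["sample_id"].iloc[i]: float(f_all[i]) for i in range(n)},
        "implanted_segments": merge_truth_segments(implanted),
    }
    return ds, truth


def _config_json(config: SimulationConfig) -> dict:
    d = asdict(config)
    # JSON-canonical: tuples become lists so truth files round-trip exactly
    d["pop_sizes"] = {k: list(v) for k, v in d["pop_sizes"].items()}
    d["base_maf_range"] = list(d["base_maf_range"])
    d["roh_rate"] = list(d["roh_rate"])
    d["roh_length_kb"] = list(d["roh_length_kb"])
    if isinstance(d["inbreeding_f"], (tuple, list)):
        d["inbreeding_f"] = list(d["inbreeding_f"])
    return d


def implant_roh(ds: Dataset, sample_index: int, chrom, start_bp: int,
                length_kb: float, rng=None, allele_freq=None):
    """Make one sample fully homozygous over [start_bp, start_bp + 1000*length_kb).

    Each covered SNP is set to code 2 with probability equal to its (local)
    A1 allele frequency, else 0 — an autozygous segment is two IBD copies of
    one allele drawn from the population.  Modifies ``ds.codes`` in place
    and returns the truth record, or None (with a warning) when the window
    covers no SNPs.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    end_bp = int(start_bp + 1000 * length_kb) - 1
    v = ds.variants
    in_seg = (v["chrom"] == chrom) & (v["bp"] >= start_bp) & (v["bp"] <= end_bp)
    cols = v.index[in_seg].to_numpy()
    if len(cols) == 0:
        warnings.warn(f"implant_roh: segment {chrom}:{start_bp}-{end_bp} covers 0 SNPs; no-op")
        return None
    if allele_freq is None:
        obs = ds.codes[:, cols] != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(obs.sum(0) > 0,
                         np.where(ds.codes[:, cols] == MISSING, 0, ds.codes[:, cols]).sum(0)
                         / np.maximum(2 * obs.sum(0), 1), 0.5)
    else:
        p = np.asarray(allele_freq)[cols]
    ds.codes[sample_index, cols] = np.where(rng.random(len(cols)) < p, 2, 0).astype(np.int16)
    return {
        "sample_id": str(ds.samples["sample_id"].iloc[sample_index]),
        "chrom": str(chrom),
        "start_bp": int(start_bp),
        "end_bp": int(end_bp),
        "n_snps": int(len(cols)),
    }


def merge_truth_segments(records: list[dict]) -> list[dict]:
    """Union overlapping implants of the same sample/chromosome."""
    out: list[dict] = []
    by_key: dict = {}
    for r in records:
        by_key.setdefault((r["sample_id"], r["chrom"]), []).append(r)
    for (sid, chrom), recs in by_key.items():
        recs = sorted(recs, key=lambda r: r["start_bp"])
        cur = dict(recs[0])
        for r in recs[1:]:
            if r["start_bp"] <= cur["end_bp"] + 1:
                cur["end_bp"] = max(cur["end_bp"], r["end_bp"])
            else:
                out.append(cur)
                cur = dict(r)
        out.append(cur)
    return sorted(out, key=lambda r: (r["sample_id"], r["chrom"], r["start_bp"]))


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Haplotype panels


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (rows) at physically positioned sites
    (columns); 0 = ancestral, 1 = derived."""

    haplotypes: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("positions length must match number of sites")
        if not np.all(np.isin(self.haplotypes, (0, 1))):
            raise ValueError("haplotypes must be binary")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def m(self) -> int:
        return self.haplotypes.shape[1]

    def write_tsv(self, matrix_path, positions_path) -> None:
        np.savetxt(matrix_path, self.haplotypes, fmt="%d", delimiter="\t")
        np.savetxt(positions_path, self.positions, fmt="%d")

    @classmethod
    def read_tsv(cls, matrix_path, positions_path) -> "HaplotypePanel":
        hap = np.loadtxt(matrix_path, dtype=np.uint8, delimiter="\t", ndmin=2)
        pos = np.loadtxt(positions_path, dtype=np.int64, ndmin=1)
        return cls(hap, pos)


def simulate_haplotypes(n_haplotypes: int, sites, sfs_mode="neutral",
                        sweep: dict | None = None, seed: int = 0,
                        spacing_bp: int = 10_000) -> HaplotypePanel:
    """Generate a phased panel with a controlled site-frequency spectrum.

    sites: either a site count (positions evenly spaced ``spacing_bp``
        apart) or an explicit increasing position array.
    sfs_mode: "neutral" draws each site's derived count i in 1..n-1 with
        probability proportional to 1/i (the standard neutral expectation);
        "uniform" draws i uniformly; a vector of n-1 weights is also accepted.
    sweep: optional {"carrier_fraction": f, "flank_bp": L, "core_bp": pos}.
        Carrier haplotypes get the derived allele at the core site and share
        identical alleles at every site within ``flank_bp`` of the core,
        producing elevated EHH on the derived background.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(sites):
        positions = (np.arange(1, int(sites) + 1) * spacing_bp).astype(np.int64)
    else:
        positions = np.asarray(sites, dtype=np.int64)
    m = len(positions)
    n = int(n_haplotypes)
    panel = np.zeros((n, m), dtype=np.uint8)
    if m == 0 or n == 0:
        return HaplotypePanel(panel, positions)

    if isinstance(sfs_mode, str):
        if sfs_mode == "neutral":
            w = 1.0 / np.arange(1, n)
        elif sfs_mode == "uniform":
            w = np.ones(n - 1)
        else:
            raise ValueError(f"unknown sfs_mode {sfs_mode!r}")
    else:
        w = np.asarray(sfs_mode, dtype=float)
        if len(w) != n - 1:
            raise ValueError("custom SFS weight vector must have n-1 entries")
    w = w / w.sum()

    counts = rng.choice(np.arange(1, n), size=m, p=w)
    for j in range(m):
        carriers = rng.choice(n, size=counts[j], replace=False)
        panel[carriers, j] = 1

    if sweep is not None:
        frac = float(sweep["carrier_fraction"])
        if not (0 < frac < 1):
            raise ValueError("sweep carrier_fraction must be in (0, 1)")
        flank = int(sweep.get("flank_bp", 500_000))
        core_bp = int(sweep.get("core_bp", positions[m // 2]))
        core = int(np.argmin(np.abs(positions - core_bp)))
        k = max(2, int(round(frac * n)))
        carriers = rng.choice(n, size=k, replace=False)
        panel[:, core] = 0
        panel[carriers, core] = 1
        near = np.flatnonzero(np.abs(positions - positions[core]) <= flank)
        template = panel[carriers[0], near]
        panel[np.ix_(carriers, near)] = template
        panel[carriers, core] = 1
    return HaplotypePanel(panel, positions)
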
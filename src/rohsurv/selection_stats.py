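"""Selection statistics from phased haplotype panels.

Tajima's D and Fay-Wu's H are computed from the unfolded site-frequency
spectrum (derived counts; ancestral allele = 0).  Extended haplotype
homozygosity (EHH) and the integrated haplotype score (iHS) are computed
around a core site: EHH(x) is the probability that two random carriers of a
core allele are identical over all sites from the core to x, iHH is the
trapezoidal integral of EHH over physical distance (truncated at a floor
and at large gaps), and the unstandardized iHS is ln(iHH_ancestral /
iHH_derived).  iHS is standardized within derived-allele-frequency bins.

Undefined statistics (no segregating sites, too few carriers, zero iHH) are
reported as explicit None/NaN markers, never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class SfsSummary:
    """Unfolded site-frequency spectrum of a panel region.

    n: haplotype count; S: segregating sites; xi[i-1]: number of sites with
    derived-allele count i, for i = 1..n-1.
    """

    n: int
    S: int
    xi: np.ndarray


def sfs_summary(panel: HaplotypePanel, region=None) -> SfsSummary:
    """Site-frequency spectrum over a bp region (start, end) or whole panel.
    Sites fixed for either allele are excluded from S."""
    hap = panel.haplotypes
    if region is not None:
        start, end = region
        sel = (panel.positions >= start) & (panel.positions <= end)
        hap = hap[:, sel]
    n = hap.shape[0]
    counts = hap.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    xi = np.bincount(counts[seg], minlength=n)[1:n]
    return SfsSummary(n=n, S=int(seg.sum()), xi=xi)


def _pi_hat(sfs: SfsSummary) -> float:
    i = np.arange(1, sfs.n)
    return float(np.sum(sfs.xi * i * (sfs.n - i)) * 2.0 / (sfs.n * (sfs.n - 1)))


def tajimas_d(sfs: SfsSummary):
    """Tajima's D; None when there are no segregating sites (undefined).

    D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1)) with the standard constants
    derived from the haplotype count n.
    """
    n, S = sfs.n, sfs.S
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4 haplotypes")
    if S == 0:
        return None
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((_pi_hat(sfs) - S / a1) / np.sqrt(var))


def fay_wu_h(sfs: SfsSummary):
    """Unnormalized Fay-Wu's H = theta_pi - theta_H; None when S = 0.

    theta_H = sum_i xi_i * 2 i^2 / (n (n-1)) weights high-frequency derived
    alleles, so an excess of them drives H negative.
    """
    n, S = sfs.n, sfs.S
    if n < 3:
        raise ValueError("Fay-Wu's H requires n >= 3 haplotypes")
    if S == 0:
        return None
    i = np.arange(1, n)
    theta_h = float(np.sum(sfs.xi * 2.0 * i**2) / (n * (n - 1)))
    return _pi_hat(sfs) - theta_h


# ---------------------------------------------------------------------------
# EHH / iHS


def ehh(panel: HaplotypePanel, core_site: int, allele: int, direction: str):
    """Extended haplotype homozygosity curve from a core site.

    Among the carriers of ``allele`` at ``core_site``, EHH at site x is
    sum_k C(c_k, 2) / C(c, 2) over the counts c_k of distinct haplotypes
    extended from the core to x.  Returns (positions, ehh_values) moving
    right ('right') or left ('left') from the core, starting at the core
    itself (EHH = 1).  None when fewer than 2 carriers exist.
    """
    hap = panel.haplotypes
    carriers = np.flatnonzero(hap[:, core_site] == allele)
    c = len(carriers)
    if c < 2:
        return None
    if direction == "right":
        sites = np.arange(core_site, panel.m)
    elif direction == "left":
        sites = np.arange(core_site, -1, -1)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    denom = c * (c - 1) / 2.0
    # incrementally refine the partition of carriers into identical extensions
    labels = np.zeros(c, dtype=np.int64)
    values = np.empty(len(sites))
    for t, s in enumerate(sites):
        col = hap[carriers, s]
        labels = labels * 2 + col
        _, counts = np.unique(labels, return_counts=True)
        values[t] = np.sum(counts * (counts - 1) / 2.0) / denom
        labels = np.unique(labels, return_inverse=True)[1]  # keep labels small
    return panel.positions[sites], values


def _ihh_one_side(positions, values, floor: float, max_gap_bp: int):
    """Trapezoidal integral of an EHH curve over physical distance,
    truncated where EHH drops below ``floor`` or at a gap > max_gap_bp."""
    ihh = 0.0
    for t in range(1, len(values)):
        gap = abs(int(positions[t]) - int(positions[t - 1]))
        if gap > max_gap_bp:
            break
        v0, v1 = values[t - 1], values[t]
        if v1 < floor:
            # integrate down to the floor crossing, then stop
            if v0 > floor and v1 < v0:
                frac = (v0 - floor) / (v0 - v1)
                ihh += 0.5 * (v0 + floor) * gap * frac
            break
        ihh += 0.5 * (v0 + v1) * gap
    return ihh


def ihs(panel: HaplotypePanel, core_site: int, ehh_floor: float = 0.05,
        max_gap_bp: int = 200_000, freq_bounds=(0.05, 0.95)):
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) at a core site.

    Requires >= 2 carriers of each allele and a derived frequency inside
    ``freq_bounds``.  Returns None (undefined / skipped) otherwise, and when
    either integral is 0.  Cores where derived carriers share long flanking
    haplotypes give negative values of large magnitude.
    """
    hap = panel.haplotypes
    n = hap.shape[0]
    freq = hap[:, core_site].sum() / n
    if not (freq_bounds[0] < freq < freq_bounds[1]):
        logger.debug("ihs: core %d derived frequency %.3f outside bounds; skipped",
                     core_site, freq)
        return None
    ihh = {}
    for allele in (0, 1):
        total = 0.0
        for direction in ("left", "right"):
            curve = ehh(panel, core_site, allele, direction)
            if curve is None:
                return None
            total += _ihh_one_side(curve[0], curve[1], ehh_floor, max_gap_bp)
        ihh[allele] = total
    if ihh[1] == 0 or ihh[0] == 0:
        return None
    return float(np.log(ihh[0] / ihh[1]))


def ihs_scan(panel: HaplotypePanel, **kwargs) -> pd.DataFrame:
    """Unstandardized iHS at every site, with derived frequencies."""
    n = panel.n
    rows = []
    for j in range(panel.m):
        freq = panel.haplotypes[:, j].sum() / n
        raw = ihs(panel, j, **kwargs)
        rows.append((j, int(panel.positions[j]), freq,
                     np.nan if raw is None else raw))
    return pd.DataFrame(rows, columns=["site", "bp", "derived_freq", "ihs_raw"])


def standardize_ihs(scores, frequencies, n_bins: int = 20):
    """Standardize iHS within derived-frequency bins (subtract bin mean,
    divide by bin SD).  Bins with < 2 defined scores or zero SD are flagged:
    the standardized value is NaN there and the raw score is retained by the
    caller.  Returns an array aligned with the input."""
    scores = np.asarray(scores, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    out = np.full(len(scores), np.nan)
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.clip(np.digitize(freqs, edges) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        sel = (which == b) & ~np.isnan(scores)
        if sel.sum() < 2:
            if sel.sum():
                logger.info("standardize_ihs: singleton bin %d flagged", b)
            continue
        sd = scores[sel].std()
        if sd == 0:
            logger.info("standardize_ihs: zero-SD bin %d flagged", b)
            continue
        out[sel] = (scores[sel] - scores[sel].mean()) / sd
    return out


def annotate_regions(regions: pd.DataFrame, panel: HaplotypePanel,
                     window_bp: int = 100_000, n_bins: int = 20,
                     **ihs_kwargs) -> pd.DataFrame:
    """Per-region selection scores: max windowed Tajima's D, min windowed
    Fay-Wu's H (window ``window_bp``, step window/2) and max |standardized
    iHS| over core sites inside the region (standardization uses all panel
    sites).  Regions need columns start_bp, end_bp.  Undefined statistics
    are NaN."""
    scan = ihs_scan(panel, **ihs_kwargs)
    scan["ihs_std"] = standardize_ihs(scan["ihs_raw"], scan["derived_freq"],
                                      n_bins=n_bins)
    rows = []
    for reg in regions.itertuples(index=False):
        start, end = int(reg.start_bp), int(reg.end_bp)
        d_max, h_min = _windowed_extremes(panel, start, end, window_bp)
        in_reg = (scan["bp"] >= start) & (scan["bp"] <= end)
        vals = scan.loc[in_reg, "ihs_std"].abs()
        ihs_max = float(vals.max()) if vals.notna().any() else np.nan
        rows.append((start, end, ihs_max, d_max, h_min))
    return pd.DataFrame(rows, columns=["start_bp", "end_bp", "ihs_max",
                                       "tajima_d_max", "fay_wu_h_min"])


def _windowed_extremes(panel: HaplotypePanel, start: int, end: int, window_bp: int):
    step = max(window_bp // 2, 1)
    d_vals, h_vals = [], []
    w_start = start
    while w_start <= end:
        w_end = min(w_start + window_bp - 1, end)
        sfs = sfs_summary(panel, region=(w_start, w_end))
        d = tajimas_d(sfs) if sfs.n >= 4 else None
        h = fay_wu_h(sfs) if sfs.n >= 3 else None
        if d is not None:
            d_vals.append(d)
        if h is not None:
            h_vals.append(h)
        if w_end >= end:
            break
        w_start += step
    d_max = max(d_vals) if d_vals else np.nan
    h_min = min(h_vals) if h_vals else np.nan
    return d_max, h_min
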
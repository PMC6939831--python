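"""Variant filtering and windowed population-genetic statistics.

Per-window nucleotide diversity (pi) for each group, Weir & Cockerham
(1984) Fst as a ratio of averaged variance components, and the
reduction-of-diversity statistic ROD = 1 - pi_freshwater/pi_migratory.

Conventions that change the scale of the results and are therefore fixed
here once:

* pi is divided by the full window length in base pairs — "per site"
  means per base pair, monomorphic positions contributing zero — not per
  variant site.
* Window Fst is the ratio of summed variance components (sum a over
  sum a+b+c), not a mean of per-site ratios; negative window values are
  reported unclamped so empirical percentiles are well defined.
* A site where a group has fewer than 2 non-missing alleles is skipped
  for that group's pi; a site where either group has fewer than 2
  non-missing genotypes is skipped for Fst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, FRESHWATER, MIGRATORY, GenotypeDataset, SampleGrouping

log = logging.getLogger(__name__)

#: Columns of the window table produced by :func:`scan_windows`.
WINDOW_COLUMNS = ["chrom", "start", "end", "n_sites", "pi_mig", "pi_fw",
                  "fst", "rod", "eligible", "partial"]


def filter_variants(ds: GenotypeDataset, max_missing: float = 0.10,
                    min_maf: float = 0.10) -> GenotypeDataset:
    """Drop sites with too much missingness or too rare a minor allele.

    A site is kept iff its missing fraction is <= ``max_missing`` and its
    minor-allele frequency, computed from non-missing dosages, is
    >= ``min_maf``.  Samples and site order are untouched.
    """
    if ds.n_sites == 0:
        return ds
    missing = ds.dosages == MISSING
    n_nonmiss = (~missing).sum(axis=0)
    miss_frac = missing.sum(axis=0) / ds.n_samples
    alt_sum = np.where(missing, 0, ds.dosages).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(n_nonmiss > 0, alt_sum / (2.0 * n_nonmiss), 0.0)
    maf = np.minimum(af, 1.0 - af)
    keep = (miss_frac <= max_missing) & (maf >= min_maf) & (n_nonmiss > 0)
    kept = ds.take_sites(np.flatnonzero(keep))
    if kept.n_sites == 0:
        log.warning("filter_variants removed all %d sites", ds.n_sites)
    else:
        log.info("filter_variants: kept %d of %d sites", kept.n_sites, ds.n_sites)
    return kept


def site_pi(ref_count: int, alt_count: int) -> float:
    """Unbiased per-site diversity from allele counts.

    Probability that two alleles drawn without replacement differ:
    ``2 * ref * alt / (c * (c - 1))`` with ``c = ref + alt``.
    Returns NaN (site skipped) when fewer than two alleles were observed.
    """
    c = ref_count + alt_count
    if c < 2:
        return float("nan")
    return 2.0 * ref_count * alt_count / (c * (c - 1.0))


def _group_allele_counts(ds: GenotypeDataset, sample_idx: np.ndarray,
                         site_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt allele count, total non-missing allele count) per site."""
    g = ds.dosages[np.ix_(sample_idx, site_idx)]
    nonmiss = g != MISSING
    alt = np.where(nonmiss, g, 0).sum(axis=0)
    total = 2 * nonmiss.sum(axis=0)
    return alt, total


def window_pi(ds: GenotypeDataset, group_samples: list[str],
              window: tuple[str, int, int]) -> float:
    """Per-bp nucleotide diversity of a group over one window."""
    chrom, start, end = window
    if end < start:
        raise ValueError("window end before start")
    site_idx = _window_site_index(ds, chrom, start, end)
    sample_idx = ds.sample_index(group_samples)
    alt, total = _group_allele_counts(ds, sample_idx, site_idx)
    usable = total >= 2
    a = alt[usable].astype(float)
    c = total[usable].astype(float)
    pis = 2.0 * (c - a) * a / (c * (c - 1.0))
    return float(pis.sum()) / (end - start + 1)


def _window_site_index(ds: GenotypeDataset, chrom: str, start: int,
                       end: int) -> np.ndarray:
    s = ds.sites
    mask = (s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] <= end)
    return np.flatnonzero(mask.to_numpy())


def _wc_components(ds: GenotypeDataset, idx1: np.ndarray, idx2: np.ndarray,
                   site_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site variance components (a, b, c).

    Two-population case with observed heterozygosity; sites where either
    group has < 2 non-missing genotypes are dropped.
    """
    comps = []
    for idx in (idx1, idx2):
        g = ds.dosages[np.ix_(idx, site_idx)]
        nonmiss = g != MISSING
        n = nonmiss.sum(axis=0).astype(float)              # individuals
        alt = np.where(nonmiss, g, 0).sum(axis=0).astype(float)
        het = ((g == 1) & nonmiss).sum(axis=0).astype(float)
        comps.append((n, alt, het))
    (n1, alt1, het1), (n2, alt2, het2) = comps
    usable = (n1 >= 2) & (n2 >= 2)
    n1, alt1, het1 = n1[usable], alt1[usable], het1[usable]
    n2, alt2, het2 = n2[usable], alt2[usable], het2[usable]

    r = 2.0
    p1, p2 = alt1 / (2 * n1), alt2 / (2 * n2)
    h1, h2 = het1 / n1, het2 / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def _hudson_components(ds: GenotypeDataset, idx1: np.ndarray, idx2: np.ndarray,
                       site_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hudson's per-site numerator/denominator (Bhatia et al. formulation)."""
    comps = []
    for idx in (idx1, idx2):
        g = ds.dosages[np.ix_(idx, site_idx)]
        nonmiss = g != MISSING
        n_all = 2 * nonmiss.sum(axis=0).astype(float)      # alleles
        alt = np.where(nonmiss, g, 0).sum(axis=0).astype(float)
        comps.append((n_all, alt))
    (c1, a1), (c2, a2) = comps
    usable = (c1 >= 4) & (c2 >= 4)
    c1, a1, c2, a2 = c1[usable], a1[usable], c2[usable], a2[usable]
    p1, p2 = a1 / c1, a2 / c2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (c1 - 1) - p2 * (1 - p2) / (c2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def window_fst(ds: GenotypeDataset, grouping: SampleGrouping,
               window: tuple[str, int, int],
               estimator: str = "weir_cockerham") -> float:
    """Window Fst between the two groups (ratio of averages).

    Returns NaN when no in-window site is usable (either group having
    fewer than 2 non-missing genotypes everywhere).  Values may be
    negative; they are capped above by 1.
    """
    chrom, start, end = window
    site_idx = _window_site_index(ds, chrom, start, end)
    idx1 = ds.sample_index(grouping.members(MIGRATORY))
    idx2 = ds.sample_index(grouping.members(FRESHWATER))
    if estimator == "weir_cockerham":
        a, b, c = _wc_components(ds, idx1, idx2, site_idx)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den = _hudson_components(ds, idx1, idx2, site_idx)
    else:
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    den_sum = den.sum()
    if den.size == 0 or den_sum == 0:
        return float("nan")
    return min(float(num.sum() / den_sum), 1.0)


def rod(pi_fw: float, pi_mig: float) -> float:
    """Reduction of diversity: ``1 - pi_fw / pi_mig``.

    Positive when the freshwater group lost diversity relative to the
    migratory group; NaN (undefined) when ``pi_mig`` is zero.
    """
    if pi_fw < 0 or pi_mig < 0:
        raise ValueError("diversities must be non-negative")
    if pi_mig == 0:
        return float("nan")
    return 1.0 - pi_fw / pi_mig


def scan_windows(ds: GenotypeDataset, grouping: SampleGrouping,
                 window_size: int = 5000, step: int | None = None,
                 min_sites: int = 3, chrom_lengths: dict[str, int] | None = None,
                 estimator: str = "weir_cockerham") -> pd.DataFrame:
    """Tile each chromosome with windows and compute pi/Fst/ROD per window.

    Windows start at position 1 and advance by ``step`` (default: window
    size, i.e. non-overlapping).  The final partial window is kept and
    flagged.  Windows with fewer than ``min_sites`` variant sites are
    reported but marked ineligible so they do not enter percentile
    thresholds.  Returns a DataFrame with :data:`WINDOW_COLUMNS`.
    """
    if window_size <= 0 or (step is not None and step <= 0):
        raise ValueError("window_size and step must be positive")
    if step is None:
        step = window_size
    grouping.validate_against(ds)
    idx_mig = ds.sample_index(grouping.members(MIGRATORY))
    idx_fw = ds.sample_index(grouping.members(FRESHWATER))

    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom, grp in ds.sites.groupby("chrom", sort=False):
            chrom_lengths[chrom] = int(grp["pos"].max())

    rows = []
    n_skipped_sites = 0
    for chrom, length in chrom_lengths.items():
        sub_mask = (ds.sites["chrom"] == chrom).to_numpy()
        sub_idx = np.flatnonzero(sub_mask)
        sub_pos = ds.sites["pos"].to_numpy()[sub_idx]
        start = 1
        while start <= length:
            end = min(start + window_size - 1, length)
            partial = end - start + 1 < window_size
            site_idx = sub_idx[(sub_pos >= start) & (sub_pos <= end)]
            n_sites = site_idx.size

            alt_m, tot_m = _group_allele_counts(ds, idx_mig, site_idx)
            alt_f, tot_f = _group_allele_counts(ds, idx_fw, site_idx)
            wlen = float(end - start + 1)
            pi_mig = _pi_from_counts(alt_m, tot_m) / wlen
            pi_fw = _pi_from_counts(alt_f, tot_f) / wlen

            if estimator == "weir_cockerham":
                a, b, c = _wc_components(ds, idx_mig, idx_fw, site_idx)
                num, den = a, a + b + c
            else:
                num, den = _hudson_components(ds, idx_mig, idx_fw, site_idx)
            n_skipped_sites += n_sites - num.size
            den_sum = den.sum()
            fst = (min(float(num.sum() / den_sum), 1.0)
                   if num.size and den_sum != 0 else float("nan"))
            rod_val = rod(pi_fw, pi_mig)
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "n_sites": n_sites, "pi_mig": pi_mig, "pi_fw": pi_fw,
                "fst": fst, "rod": rod_val,
                "eligible": n_sites >= min_sites, "partial": partial})
            start += step
    log.info("scan_windows: %d windows, %d group-unusable site evaluations",
             len(rows), n_skipped_sites)
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def _pi_from_counts(alt: np.ndarray, total: np.ndarray) -> float:
    usable = total >= 2
    a = alt[usable].astype(float)
    c = total[usable].astype(float)
    if a.size == 0:
        return 0.0
    return float((2.0 * (c - a) * a / (c * (c - 1.0))).sum())
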
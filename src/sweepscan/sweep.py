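"""Joint top-percentile sweep-window selection and candidate gene lookup.

Windows whose Fst *and* ROD both exceed their empirical 95th percentile
(strict inequality, computed over eligible windows only) are flagged as
sweep windows, merged into regions, and intersected with the gene
annotation to produce the candidate list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GeneAnnotation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    max_fst: float
    max_rod: float


def percentile_threshold(values, q: float = 0.95) -> float:
    """Empirical q-quantile by linear interpolation (type-7 rule).

    NaN (undefined) entries are dropped first.  Fewer than 20 defined
    values triggers a warning; an empty input is an error.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no defined values to take a percentile of")
    if arr.size < 20:
        log.warning("percentile_threshold on only %d values", arr.size)
    return float(np.quantile(arr, q))  # numpy default = type 7


def select_windows(stats: pd.DataFrame, thr_fst: float,
                   thr_rod: float) -> pd.DataFrame:
    """Eligible windows with fst > thr_fst AND rod > thr_rod (strict).

    Windows with undefined (NaN) ROD or Fst are never selected.
    """
    if not (np.isfinite(thr_fst) and np.isfinite(thr_rod)):
        raise ValueError("thresholds must be finite")
    mask = (stats["eligible"]
            & (stats["fst"] > thr_fst) & (stats["rod"] > thr_rod))
    mask &= stats["fst"].notna() & stats["rod"].notna()
    return stats[mask].reset_index(drop=True)


def merge_windows(selected: pd.DataFrame, max_gap: int = 0) -> list[SweepRegion]:
    """Merge selected windows on the same chromosome into regions.

    Two windows merge when the gap between them is <= ``max_gap`` bp.
    Each region carries its member-window count and max statistics.
    """
    if len(selected) == 0:
        return []
    df = selected.sort_values(["chrom", "start"]).reset_index(drop=True)
    regions: list[SweepRegion] = []
    cur = None
    for row in df.itertuples(index=False):
        if (cur is not None and row.chrom == cur["chrom"]
                and row.start - cur["end"] - 1 <= max_gap):
            cur["end"] = max(cur["end"], row.end)
            cur["n"] += 1
            cur["max_fst"] = max(cur["max_fst"], row.fst)
            cur["max_rod"] = max(cur["max_rod"], row.rod)
        else:
            if cur is not None:
                regions.append(_finish(cur))
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "n": 1, "max_fst": row.fst, "max_rod": row.rod}
    regions.append(_finish(cur))
    return regions


def _finish(cur: dict) -> SweepRegion:
    return SweepRegion(chrom=cur["chrom"], start=int(cur["start"]),
                       end=int(cur["end"]), n_windows=int(cur["n"]),
                       max_fst=float(cur["max_fst"]),
                       max_rod=float(cur["max_rod"]))


def genes_in_regions(regions: list[SweepRegion], ann: GeneAnnotation,
                     min_overlap_bp: int = 1) -> pd.DataFrame:
    """Genes overlapping any region by at least ``min_overlap_bp``.

    Each gene appears once, with a comma-joined list of the regions it
    overlaps; output sorted by (chrom, start).
    """
    rows = []
    for g in ann.genes:
        hits = []
        best_fst = best_rod = float("-inf")
        for r in regions:
            if r.chrom != g.chrom:
                continue
            overlap = min(g.end, r.end) - max(g.start, r.start) + 1
            if overlap >= min_overlap_bp:
                hits.append(f"{r.chrom}:{r.start}-{r.end}")
                best_fst = max(best_fst, r.max_fst)
                best_rod = max(best_rod, r.max_rod)
        if hits:
            rows.append({"gene_id": g.gene_id, "chrom": g.chrom,
                         "start": g.start, "end": g.end,
                         "regions": ",".join(hits),
                         "max_fst": best_fst, "max_rod": best_rod})
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "regions", "max_fst", "max_rod"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def regions_to_frame(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start, "end": r.end,
          "n_windows": r.n_windows, "max_fst": r.max_fst,
          "max_rod": r.max_rod} for r in regions],
        columns=["chrom", "start", "end", "n_windows", "max_fst", "max_rod"])
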
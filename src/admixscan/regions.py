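"""Seed-and-extend candidate-region calling and interval intersection.

Selection-scan regions are seeded by SNPs passing a stringent q-value
threshold (default q < 0.1) and grown stepwise: from the last-identified
SNP in each direction, any SNP within 500 Kbp passing a looser suggestive
threshold becomes the new boundary, until a 500-Kbp step finds none.
Region boundaries are the outermost identified SNP positions (1-based,
closed intervals); regions grown from different seeds that touch or
overlap are merged.  GWA regions use the same mechanics with a single
p-value threshold (default p < 1e-3) for both seeding and extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "call_sos_regions",
    "call_gwa_regions",
    "intersect_regions",
    "regions_to_frame",
    "regions_to_bed",
]


@dataclass
class Region:
    """A candidate region: closed bp interval with its member SNPs."""

    chrom: int
    start: int
    end: int
    snp_pos: np.ndarray  # member SNP positions
    top_stat: float  # min q (SoS) or max -log10 p (GWA) among members
    source: str = ""
    dominant_ancestry: str | None = None

    @property
    def n_snps(self) -> int:
        return len(self.snp_pos)

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _grow(
    pos: np.ndarray, qualifies: np.ndarray, seed_idx: int, window: int
) -> tuple[int, int]:
    """Extend from a seed SNP; returns (left_index, right_index) bounds."""
    left = right = seed_idx
    moved = True
    while moved:
        moved = False
        cand = np.flatnonzero(
            qualifies & (pos > pos[right]) & (pos <= pos[right] + window)
        )
        if len(cand):
            right = int(cand[-1])
            moved = True
        cand = np.flatnonzero(
            qualifies & (pos < pos[left]) & (pos >= pos[left] - window)
        )
        if len(cand):
            left = int(cand[0])
            moved = True
    return left, right


def _call_regions(
    scan: pd.DataFrame,
    seed_mask: np.ndarray,
    extend_mask: np.ndarray,
    window: int,
    stat: np.ndarray,
    best: str,
    source: str,
) -> list[Region]:
    regions: list[Region] = []
    for c in pd.unique(scan["chrom"]):
        in_c = (scan["chrom"] == c).to_numpy()
        pos = scan.loc[in_c, "pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        seeds = seed_mask[in_c][order]
        qual = extend_mask[in_c][order] | seeds
        stat_c = stat[in_c][order]
        intervals: list[tuple[int, int]] = []
        for si in np.flatnonzero(seeds):
            lo, hi = _grow(pos, qual, int(si), window)
            intervals.append((int(pos[lo]), int(pos[hi])))
        for start, end in _merge_intervals(intervals):
            member = (pos >= start) & (pos <= end)
            vals = stat_c[member]
            top = float(np.nanmin(vals) if best == "min" else np.nanmax(vals))
            regions.append(
                Region(
                    chrom=int(c),
                    start=start,
                    end=end,
                    snp_pos=pos[member],
                    top_stat=top,
                    source=source,
                )
            )
    return regions


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge closed intervals that touch or overlap."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def call_sos_regions(
    scan: pd.DataFrame,
    seed_q: float = 0.1,
    suggestive_q: float = 0.5,
    window: int = 500_000,
    source: str = "sos",
) -> list[Region]:
    """Candidate selection regions from a scan frame with a ``q`` column.

    Seeds are SNPs with q < ``seed_q``; extension admits SNPs with q <
    ``suggestive_q`` within ``window`` bp of the last identified SNP.  The
    region's top statistic is the minimum member q value.
    """
    q = scan["q"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        seed = q < seed_q
        ext = q < suggestive_q
    return _call_regions(scan, seed, ext, window, q, "min", source)


def call_gwa_regions(
    scan: pd.DataFrame,
    p_thresh: float = 1e-3,
    window: int = 500_000,
    source: str = "gwa",
) -> list[Region]:
    """GWA suggestive regions: one p threshold seeds and extends.

    The region's top statistic is the maximum member -log10 p.
    """
    p = scan["p"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mask = p < p_thresh
        neglog = -np.log10(p)
    return _call_regions(scan, mask, mask, window, neglog, "max", source)


def intersect_regions(
    a: list[Region], b: list[Region]
) -> pd.DataFrame:
    """All pairwise overlaps (>= 1 bp of shared closed interval).

    Reports the intersection interval and its length in bp (end minus
    start of the shared interval).
    """
    rows = []
    for ra in a:
        for rb in b:
            if ra.chrom != rb.chrom:
                continue
            lo = max(ra.start, rb.start)
            hi = min(ra.end, rb.end)
            if lo > hi:
                continue
            rows.append(
                {
                    "chrom": ra.chrom,
                    "a_source": ra.source,
                    "a_start": ra.start,
                    "a_end": ra.end,
                    "b_source": rb.source,
                    "b_start": rb.start,
                    "b_end": rb.end,
                    "overlap_start": lo,
                    "overlap_end": hi,
                    "overlap_bp": hi - lo,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "a_source",
            "a_start",
            "a_end",
            "b_source",
            "b_start",
            "b_end",
            "overlap_start",
            "overlap_end",
            "overlap_bp",
        ],
    )


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    """Region table with Mbp coordinates, top statistic and ancestry label."""
    rows = [
        {
            "chrom": r.chrom,
            "start_bp": r.start,
            "end_bp": r.end,
            "start_mbp": r.start / 1e6,
            "end_mbp": r.end / 1e6,
            "n_snps": r.n_snps,
            "top_stat": r.top_stat,
            "dominant_ancestry": r.dominant_ancestry,
            "source": r.source,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start_bp",
            "end_bp",
            "start_mbp",
            "end_mbp",
            "n_snps",
            "top_stat",
            "dominant_ancestry",
            "source",
        ],
    )


def regions_to_bed(regions: list[Region]) -> pd.DataFrame:
    """0-based half-open BED representation of the regions."""
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "start": r.start - 1, "end": r.end, "name": r.source}
            for r in regions
        ],
        columns=["chrom", "start", "end", "name"],
    )
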
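"""Haplotype-homozygosity selection statistics: EHH, iHH, iHS, EHHS, iES, Rsb.

Within-population scan (iHS)
    For a core SNP, the extended haplotype homozygosity of a core allele at
    extension SNP ``t`` is the pair-homozygosity of core-to-``t``
    haplotypes among the carriers:

        EHH = sum_k n_k (n_k - 1) / (n_a (n_a - 1)),

    where ``n_k`` counts copies of the k-th distinct extended haplotype and
    ``n_a`` is the carrier count.  iHH integrates EHH over map distance
    (1 Morgan = 100 Mbp) out to the point where EHH decays below a
    threshold (default 0.05), on both sides of the core.  The raw score is
    ``iHS = ln(iHH_ancestral / iHH_derived)``; sweeps on the derived allele
    push it negative.  Raw scores are standardized to mean 0 / SD 1 within
    derived-allele-frequency bins (step 0.025), and two-sided p values come
    from the Gaussian transform ``p = -log10(1 - 2 |Phi(z) - 0.5|)``.

Between-population scan (Rsb)
    The site-level statistic EHHS replaces per-allele pair-homozygosity
    with the ratio ``(1 - h_st) / (1 - h_s)`` of sample-size-corrected
    haplotype and allele heterozygosities over *all* haplotypes; its
    integral is iES.  ``Rsb = ln(iES_pop_A / iES_pop_B)`` per SNP is
    standardized by the genome-wide median and SD and transformed to p
    values the same way.

Allele polarization uses the majority allele of the pooled sample as the
ancestral state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .panel import BP_PER_MORGAN, HaplotypePanel

__all__ = [
    "EHHCurve",
    "polarize_alleles",
    "ehh_curve",
    "ihh",
    "ihs_scan",
    "standardize_ihs",
    "ehhs_curve",
    "ies",
    "rsb_scan",
]

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


def _neglog10_two_sided(z: np.ndarray) -> np.ndarray:
    """-log10(1 - 2|Phi(z) - 0.5|), computed in the tail without underflow."""
    return -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / LOG10


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(z))


# --------------------------------------------------------------------------
# polarization
# --------------------------------------------------------------------------


def polarize_alleles(pooled_haps: np.ndarray) -> np.ndarray:
    """Assign the ancestral allele per SNP as the pooled-sample majority.

    ``pooled_haps`` is the (n_snps, n_haps) 0/1 matrix over every
    population under analysis.  Exact 50/50 ties resolve to the reference
    (0) allele with a warning.  Returns the ancestral allele (0 or 1) per
    SNP; the derived allele is the other one.
    """
    freq1 = np.asarray(pooled_haps).mean(axis=1)
    ancestral = (freq1 > 0.5).astype(np.int8)
    ties = freq1 == 0.5
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} SNPs with a 50/50 pooled frequency; "
            "reference allele taken as ancestral",
            stacklevel=2,
        )
    return ancestral


# --------------------------------------------------------------------------
# EHH for one core allele
# --------------------------------------------------------------------------


@dataclass
class EHHCurve:
    """EHH of one core allele, extended in both directions from the core.

    Each side starts at the core itself (distance 0, EHH 1) and includes
    the first point below the decay threshold when one was reached.
    """

    core: int  # global SNP index
    allele: int
    core_pos: int
    left_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    left_ehh: np.ndarray = field(default_factory=lambda: np.array([]))
    right_pos: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    right_ehh: np.ndarray = field(default_factory=lambda: np.array([]))
    n_carriers: int = 0


@njit(cache=True)
def _walk_kernel(
    haps: np.ndarray,
    cols: np.ndarray,
    order: np.ndarray,
    decay: float,
    site_mode: bool,
    start_ids: np.ndarray,
) -> np.ndarray:
    """Refine the haplotype partition SNP by SNP along ``order``.

    Returns the pair-homozygosity statistic per extension step: either the
    carrier pair fraction (EHH numerator over n(n-1)) or, in site mode,
    the raw sum of squared group shares (for EHHS heterozygosities).
    Stops after the first value below ``decay`` (pass a negative decay to
    disable early stopping).
    """
    n = len(cols)
    ids = start_ids.copy()
    n_groups = int(ids.max()) + 1
    out = np.full(len(order), np.nan)
    for step in range(len(order)):
        t = order[step]
        table = np.full(2 * n_groups, -1, dtype=np.int64)
        counts = np.zeros(2 * n_groups, dtype=np.int64)
        ng = 0
        for i in range(n):
            key = 2 * ids[i] + haps[t, cols[i]]
            g = table[key]
            if g == -1:
                g = ng
                table[key] = g
                ng += 1
            ids[i] = g
            counts[g] += 1
        acc = 0.0
        if site_mode:
            for g in range(ng):
                acc += (counts[g] / n) ** 2
        else:
            for g in range(ng):
                acc += counts[g] * (counts[g] - 1)
            acc /= n * (n - 1)
        out[step] = acc
        n_groups = ng
        if acc < decay or (not site_mode and acc == 0.0) or (site_mode and ng == n):
            break
    return out


def _extend(
    haps: np.ndarray,
    carriers: np.ndarray,
    order: np.ndarray,
    pos: np.ndarray,
    decay: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Walk extension SNPs in ``order``, refining the haplotype partition."""
    cols = np.flatnonzero(carriers)
    n = len(cols)
    if len(order) == 0:
        return np.array([], dtype=np.int64), np.array([])
    vals = _walk_kernel(
        haps,
        cols,
        np.asarray(order, dtype=np.int64),
        -1.0 if decay is None else float(decay),
        False,
        np.zeros(n, dtype=np.int64),
    )
    keep = ~np.isnan(vals)
    return pos[np.asarray(order)[keep]].astype(np.int64), vals[keep]


def ehh_curve(
    panel: HaplotypePanel,
    core: int,
    allele: int,
    decay: float | None = 0.05,
) -> EHHCurve:
    """EHH of ``allele`` at the ``core`` SNP, both directions.

    Requires at least two carriers of the core allele.  Extension stops
    once EHH drops below ``decay`` (the sub-threshold point is kept for
    interpolation) or at the chromosome end.
    """
    sl = panel.chrom_slice(int(panel.chrom[core]))
    carriers = panel.haps[core] == allele
    n = int(carriers.sum())
    if n < 2:
        raise ValueError("fewer than two carriers of the core allele")
    curve = EHHCurve(
        core=core,
        allele=allele,
        core_pos=int(panel.pos[core]),
        n_carriers=n,
    )
    left = np.arange(core - 1, sl.start - 1, -1)
    right = np.arange(core + 1, sl.stop)
    curve.left_pos, curve.left_ehh = _extend(panel.haps, carriers, left, panel.pos, decay)
    curve.right_pos, curve.right_ehh = _extend(
        panel.haps, carriers, right, panel.pos, decay
    )
    return curve


def _integrate_side(
    side_pos: np.ndarray, side_ehh: np.ndarray, core_pos: int, decay: float
) -> tuple[float, bool]:
    """Trapezoid integral of one side in Morgans, to the decay crossing.

    The curve starts implicitly at (0, 1) at the core.  If EHH never drops
    below the threshold before the chromosome end the side is flagged
    truncated and integrated in full.
    """
    x = np.abs(side_pos - core_pos) / BP_PER_MORGAN
    y = side_ehh
    area = 0.0
    x_prev, y_prev = 0.0, 1.0
    for xi, yi in zip(x, y):
        if yi < decay:
            # interpolate the crossing and stop
            frac = (y_prev - decay) / (y_prev - yi)
            x_cross = x_prev + frac * (xi - x_prev)
            area += 0.5 * (y_prev + decay) * (x_cross - x_prev)
            return area, False
        area += 0.5 * (y_prev + yi) * (xi - x_prev)
        x_prev, y_prev = xi, yi
    return area, True


def ihh(curve: EHHCurve, decay: float = 0.05) -> tuple[float, bool]:
    """Integrated EHH (both sides, in Morgans) with an edge-truncation flag."""
    left, trunc_l = _integrate_side(curve.left_pos, curve.left_ehh, curve.core_pos, decay)
    right, trunc_r = _integrate_side(
        curve.right_pos, curve.right_ehh, curve.core_pos, decay
    )
    return left + right, trunc_l or trunc_r


# --------------------------------------------------------------------------
# iHS scan
# --------------------------------------------------------------------------


def ihs_scan(
    panel: HaplotypePanel,
    ancestral: np.ndarray,
    maf: float = 0.05,
    decay: float = 0.05,
) -> pd.DataFrame:
    """Raw iHS per SNP: ``ln(iHH_ancestral / iHH_derived)``.

    SNPs with MAF <= ``maf`` in the panel are excluded; SNPs whose iHH is
    zero or whose alleles have fewer than two carriers are flagged
    undefined rather than returned as infinities.
    """
    freq1 = panel.allele_freqs()
    rows = []
    for s in range(panel.n_snps):
        maf_s = min(freq1[s], 1.0 - freq1[s])
        anc = int(ancestral[s])
        dfreq = 1.0 - freq1[s] if anc == 1 else freq1[s]
        row = {
            "chrom": int(panel.chrom[s]),
            "pos": int(panel.pos[s]),
            "snp_id": f"snp_{panel.chrom[s]}_{panel.pos[s]}",
            "dfreq": float(dfreq),
            "ihh_a": np.nan,
            "ihh_d": np.nan,
            "ihs_raw": np.nan,
            "truncated": False,
            "undefined": True,
        }
        if maf_s > maf:
            n1 = int(panel.haps[s].sum())
            n0 = panel.n_haps - n1
            if min(n0, n1) >= 2:
                c_anc = ehh_curve(panel, s, anc, decay)
                c_der = ehh_curve(panel, s, 1 - anc, decay)
                ihh_a, tr_a = ihh(c_anc, decay)
                ihh_d, tr_d = ihh(c_der, decay)
                row["ihh_a"], row["ihh_d"] = ihh_a, ihh_d
                row["truncated"] = tr_a or tr_d
                if ihh_a > 0 and ihh_d > 0:
                    row["ihs_raw"] = float(np.log(ihh_a / ihh_d))
                    row["undefined"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def _merge_small_bins(bin_ids: np.ndarray, min_size: int) -> np.ndarray:
    """Merge occupied frequency bins smaller than ``min_size`` into their
    nearest (by bin index) neighbor; returns relabeled bin ids."""
    uniq, counts = np.unique(bin_ids, return_counts=True)
    groups = {int(b): [int(b)] for b in uniq}
    sizes = {int(b): int(c) for b, c in zip(uniq, counts)}
    merged = True
    while merged and len(sizes) > 1:
        merged = False
        for b in sorted(sizes, key=lambda k: sizes[k]):
            if sizes[b] >= min_size:
                continue
            others = [o for o in sizes if o != b]
            nearest = min(others, key=lambda o: (abs(o - b), o))
            sizes[nearest] += sizes.pop(b)
            groups[nearest].extend(groups.pop(b))
            merged = True
            break
    relabel = {}
    for rep, members in groups.items():
        for m in members:
            relabel[m] = rep
    return np.array([relabel[int(b)] for b in bin_ids])


def standardize_ihs(
    raw: pd.DataFrame,
    bin_step: float = 0.025,
    min_bin_size: int = 10,
) -> pd.DataFrame:
    """Standardize raw iHS within derived-allele-frequency bins and attach p.

    Within each bin (step ``bin_step`` on the derived frequency; bins with
    fewer than ``min_bin_size`` defined SNPs, or zero spread, are merged
    with their nearest neighbor) the raw scores are centered and scaled to
    unit population SD.  ``neglog10p`` is the two-sided Gaussian transform
    and ``p`` the corresponding tail probability.
    """
    df = raw.copy()
    df["ihs"] = np.nan
    df["p"] = np.nan
    df["neglog10p"] = np.nan
    ok = ~df["undefined"].to_numpy()
    if not ok.any():
        return df
    vals = df.loc[ok, "ihs_raw"].to_numpy()
    dfreq = df.loc[ok, "dfreq"].to_numpy()
    bins = np.minimum((dfreq / bin_step).astype(int), int(1 / bin_step) - 1)
    bins = _merge_small_bins(bins, min_bin_size)
    # merge any zero-spread bin too (degenerate SD)
    for b in np.unique(bins):
        sel = bins == b
        if np.std(vals[sel]) == 0 and len(np.unique(bins)) > 1:
            warnings.warn(f"zero-SD frequency bin {b} merged", stacklevel=2)
            others = np.unique(bins[~sel])
            nearest = others[np.argmin(np.abs(others - b))]
            bins[sel] = nearest
    z = np.empty(len(vals))
    for b in np.unique(bins):
        sel = bins == b
        sd = np.std(vals[sel])
        if sd == 0:
            z[sel] = 0.0
        else:
            z[sel] = (vals[sel] - np.mean(vals[sel])) / sd
    df.loc[ok, "ihs"] = z
    df.loc[ok, "p"] = _two_sided_p(z)
    df.loc[ok, "neglog10p"] = _neglog10_two_sided(z)
    return df


# --------------------------------------------------------------------------
# EHHS / iES / Rsb
# --------------------------------------------------------------------------


def _hap_het(counts: np.ndarray, n: int) -> float:
    """Sample-size-corrected heterozygosity from category counts."""
    return n / (n - 1) * (1.0 - float(np.sum((counts / n) ** 2)))


def ehhs_curve(
    panel: HaplotypePanel, core: int, decay: float | None = 0.05
) -> EHHCurve:
    """Site-level EHHS of a core SNP over all haplotypes, both directions.

    ``EHHS_{s,t} = (1 - h_{s,t}) / (1 - h_s)`` with ``h_{s,t}`` the
    corrected haplotype heterozygosity from the core to ``t`` and ``h_s``
    the corrected allele heterozygosity at the core; it equals 1 at the
    core by construction.  Monomorphic cores are rejected.
    """
    sl = panel.chrom_slice(int(panel.chrom[core]))
    n = panel.n_haps
    allele_counts = np.bincount(panel.haps[core], minlength=2)
    if allele_counts.min() == 0:
        raise ValueError("monomorphic core SNP: EHHS undefined")
    h_s = _hap_het(allele_counts.astype(float), n)
    if decay is None:
        acc_thresh = -1.0
    else:
        # EHHS < decay expressed on the kernel's sum-of-squared-shares scale
        acc_thresh = 1.0 - (n - 1) / n * (1.0 - decay * (1.0 - h_s))

    def walk(order: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if len(order) == 0:
            return np.array([], dtype=np.int64), np.array([])
        acc = _walk_kernel(
            panel.haps,
            np.arange(n, dtype=np.int64),
            np.asarray(order, dtype=np.int64),
            acc_thresh,
            True,
            panel.haps[core].astype(np.int64),
        )
        keep = ~np.isnan(acc)
        h_st = n / (n - 1) * (1.0 - acc[keep])
        vals = (1.0 - h_st) / (1.0 - h_s)
        return panel.pos[np.asarray(order)[keep]].astype(np.int64), vals

    curve = EHHCurve(
        core=core,
        allele=-1,
        core_pos=int(panel.pos[core]),
        n_carriers=n,
    )
    left = np.arange(core - 1, sl.start - 1, -1)
    right = np.arange(core + 1, sl.stop)
    curve.left_pos, curve.left_ehh = walk(left)
    curve.right_pos, curve.right_ehh = walk(right)
    return curve


def ies(
    panel: HaplotypePanel, core: int, decay: float = 0.05
) -> tuple[float, bool]:
    """Integrated EHHS at a core SNP, with an edge-truncation flag."""
    return ihh(ehhs_curve(panel, core, decay), decay)


def rsb_scan(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    decay: float = 0.05,
) -> pd.DataFrame:
    """Standardized Rsb between two populations on a shared SNP grid.

    ``Rsb_raw = ln(iES_A / iES_B)`` per SNP computable in both populations
    (SNPs monomorphic in either are dropped and logged); the standardized
    score subtracts the genome-wide median and divides by the genome-wide
    SD; p values use the two-sided Gaussian transform.
    """
    if not (
        np.array_equal(panel_a.chrom, panel_b.chrom)
        and np.array_equal(panel_a.pos, panel_b.pos)
    ):
        raise ValueError("populations are on different SNP grids")
    rows = []
    n_dropped = 0
    for s in range(panel_a.n_snps):
        row = {
            "chrom": int(panel_a.chrom[s]),
            "pos": int(panel_a.pos[s]),
            "snp_id": f"snp_{panel_a.chrom[s]}_{panel_a.pos[s]}",
            "ies_a": np.nan,
            "ies_b": np.nan,
            "rsb_raw": np.nan,
            "truncated": False,
            "undefined": True,
        }
        fa = panel_a.haps[s].mean()
        fb = panel_b.haps[s].mean()
        if 0 < fa < 1 and 0 < fb < 1:
            ies_a, tr_a = ies(panel_a, s, decay)
            ies_b, tr_b = ies(panel_b, s, decay)
            row["ies_a"], row["ies_b"] = ies_a, ies_b
            row["truncated"] = tr_a or tr_b
            if ies_a > 0 and ies_b > 0:
                row["rsb_raw"] = float(np.log(ies_a / ies_b))
                row["undefined"] = False
            else:
                n_dropped += 1
        else:
            n_dropped += 1
        rows.append(row)
    if n_dropped:
        logger.info("Rsb: %d SNPs not computable in both populations", n_dropped)
    df = pd.DataFrame(rows)
    ok = ~df["undefined"].to_numpy()
    df["rsb"] = np.nan
    df["p"] = np.nan
    df["neglog10p"] = np.nan
    if ok.any():
        vals = df.loc[ok, "rsb_raw"].to_numpy()
        med = np.median(vals)
        sd = np.std(vals)
        if sd == 0:
            z = np.zeros(len(vals))
        else:
            z = (vals - med) / sd
        df.loc[ok, "rsb"] = z
        df.loc[ok, "p"] = _two_sided_p(z)
        df.loc[ok, "neglog10p"] = _neglog10_two_sided(z)
    return df
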
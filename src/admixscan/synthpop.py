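"""Forward simulation of admixed cohorts with tracked ancestry tracts.

The generator emulates the structure of an East African crossbred dairy
population: three divergent ancestral pools (IND = Bos indicus, AFT =
African Bos taurus, EUT = European Bos taurus exotic dairy breeds), an
admixed cohort produced by repeated generations of crossing and inter-se
mating, optional selective sweeps injected as homogenized haplotype blocks,
and repeated-record phenotypes with polygenic, permanent-environment and
residual variance components.

Every operation takes an explicit integer seed and is deterministic given
it; there is no module-level RNG state.

Model summary
-------------
* Ancestral differentiation follows the Balding-Nichols drift model: the
  drifted allele frequency of a pool is a Beta draw with mean equal to the
  shared base frequency ``p`` and variance ``p (1 - p) Fst``.
* Founder haplotypes are drawn SNP-independently from each pool's drifted
  frequencies (no background LD beyond drift).
* Admixture is forward-in-time random mating in a finite breeding
  population: the base generation consists of pure individuals in the
  target pool proportions, each later generation of fresh meioses between
  two distinct random parents.  A cohort animal of admixture age ``g`` is
  an offspring of the generation ``g - 1`` population, so age-1 animals
  are F1s with intact single-ancestry haplotypes.  Meiosis places a
  Poisson number of crossovers (mean = chromosome length in Morgans at
  1 Morgan = 100 Mbp) uniformly along the chromosome, with no
  interference (Haldane model).
* The returned :class:`~admixscan.panel.AncestryMatrix` is the exact tract
  ancestry of every allele; true tract junctions are recorded separately so
  downstream crossover counting can be validated against the simulator.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import (
    AFT,
    BP_PER_MORGAN,
    EUT,
    IND,
    POOLS,
    AncestryMatrix,
    HaplotypePanel,
    PhenotypeTable,
)

__all__ = [
    "AlleleFreqTable",
    "FounderLdSpec",
    "SweepSpec",
    "QtlEffect",
    "QtlSpec",
    "VarianceSpec",
    "snp_grid",
    "sample_ancestral_freqs",
    "simulate_founder_haplotypes",
    "simulate_admixture",
    "inject_sweep",
    "simulate_phenotypes",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class AlleleFreqTable:
    """Base and per-pool drifted allele frequencies for the three ancestral pools.

    ``drifted`` has one column per pool in IND/AFT/EUT order.  With a pool's
    Fst equal to zero its drifted frequencies equal the base frequencies.
    """

    base: np.ndarray  # (n_snps,)
    drifted: np.ndarray  # (n_snps, 3)
    fst: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=np.float64)
        self.drifted = np.asarray(self.drifted, dtype=np.float64)
        if self.drifted.shape != (len(self.base), 3):
            raise ValueError("drifted must be (n_snps, 3)")
        for arr in (self.base, self.drifted):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("allele frequencies must lie in [0, 1]")

    @property
    def n_snps(self) -> int:
        return len(self.base)


@dataclass
class FounderLdSpec:
    """Within-pool background LD via prototype copying.

    Each founder haplotype is a mosaic of a small number of pool-specific
    prototype haplotypes, switching prototypes at Poisson points along the
    map and re-drawing the occasional allele from the pool frequency
    (emission error).  This reproduces the long shared haplotype blocks
    real breeds carry, at an LD scale of roughly 1/switch_per_morgan
    Morgans.
    """

    n_prototypes: int = 6
    switch_per_morgan: float = 5.0
    emission_error: float = 0.01

    def __post_init__(self) -> None:
        if self.n_prototypes < 2:
            raise ValueError("need at least two prototypes")
        if self.switch_per_morgan <= 0 or not 0 <= self.emission_error < 1:
            raise ValueError("invalid LD parameters")


@dataclass
class SweepSpec:
    """A manufactured selective sweep: a homogenized haplotype block.

    The favored core haplotype (that of a randomly chosen donor) is copied
    onto recipients until its carrier frequency reaches ``target_freq``,
    over a flank of ``half_width_bp`` on each side of the core SNP.
    """

    chrom: int
    core_index: int  # index of the core SNP within its chromosome block
    target_freq: float
    half_width_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.target_freq <= 1:
            raise ValueError("target_freq must be in (0, 1]")
        if self.half_width_bp <= 0:
            raise ValueError("half_width_bp must be positive")


@dataclass
class QtlEffect:
    """One causal locus with an ancestral-origin and/or residual allele effect.

    ``origin_effect`` is in phenotype units per EUT-origin allele copy;
    ``allele_effect`` is in phenotype units per alternate-allele copy.
    """

    snp_index: int
    origin_effect: float = 0.0
    allele_effect: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.origin_effect) and np.isfinite(self.allele_effect)):
            raise ValueError("QTL effects must be finite")


@dataclass
class QtlSpec:
    loci: list[QtlEffect] = field(default_factory=list)

    def validate(self, n_snps: int) -> None:
        for q in self.loci:
            if not 0 <= q.snp_index < n_snps:
                raise ValueError(f"QTL locus {q.snp_index} absent from panel")


@dataclass
class VarianceSpec:
    """Variance components of the repeated-records phenotype model.

    sigma_g2
        Polygenic additive variance (animal effect with covariance
        ``sigma_g2 * G``).
    sigma_pe2
        Permanent-environment variance (iid animal effect shared by all of
        an animal's records).
    sigma_e2
        Residual variance (iid per record).
    records_per_animal
        A constant count, or one count per animal.
    """

    sigma_g2: float = 1.0
    sigma_pe2: float = 0.5
    sigma_e2: float = 1.0
    records_per_animal: int | np.ndarray = 3

    def __post_init__(self) -> None:
        for v in (self.sigma_g2, self.sigma_pe2, self.sigma_e2):
            if v < 0:
                raise ValueError("variance components must be non-negative")
        r = np.asarray(self.records_per_animal)
        if (r < 1).any():
            raise ValueError("every animal needs at least one record")


# --------------------------------------------------------------------------
# SNP grid and ancestral pools
# --------------------------------------------------------------------------


def snp_grid(
    n_chrom: int,
    snps_per_chrom: int,
    chrom_length_bp: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lay out a SNP grid of ``n_chrom`` chromosomes of equal bp length.

    With a seed, positions are uniform random (sorted, distinct); without,
    they are evenly spaced.  Returns ``(chrom, pos)`` arrays.
    """
    if n_chrom < 1 or snps_per_chrom < 1:
        raise ValueError("need at least one chromosome and one SNP")
    if snps_per_chrom > chrom_length_bp:
        raise ValueError("more SNPs than bp positions on a chromosome")
    chrom = np.repeat(np.arange(1, n_chrom + 1), snps_per_chrom)
    blocks = []
    if seed is None:
        step = chrom_length_bp // snps_per_chrom
        base = np.arange(1, snps_per_chrom + 1) * step
        for _ in range(n_chrom):
            blocks.append(base)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_chrom):
            p = rng.choice(chrom_length_bp, size=snps_per_chrom, replace=False) + 1
            blocks.append(np.sort(p))
    return chrom, np.concatenate(blocks).astype(np.int64)


def sample_ancestral_freqs(
    n_snps: int,
    base_range: tuple[float, float] = (0.05, 0.95),
    fst: tuple[float, float, float] = (0.25, 0.25, 0.25),
    seed: int = 0,
) -> AlleleFreqTable:
    """Draw base frequencies and Balding-Nichols drifted pool frequencies.

    For pool ``j`` with differentiation ``Fst_j``, the drifted frequency at
    a SNP with base frequency ``p`` is ``Beta(p (1-F)/F, (1-p)(1-F)/F)``,
    which has mean ``p`` and variance ``p (1 - p) Fst_j``.  ``Fst = 0``
    reproduces the base frequency exactly.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = base_range
    if not (0 < lo <= hi < 1):
        raise ValueError("base_range must lie strictly inside (0, 1)")
    fst = tuple(float(f) for f in fst)
    for f in fst:
        if not 0 <= f < 1:
            raise ValueError("Fst must lie in [0, 1) per pool")
    rng = np.random.default_rng(seed)
    base = rng.uniform(lo, hi, size=n_snps)
    drifted = np.empty((n_snps, 3))
    for j, f in enumerate(fst):
        if f == 0:
            drifted[:, j] = base
        else:
            ratio = (1.0 - f) / f
            drifted[:, j] = rng.beta(base * ratio, (1.0 - base) * ratio)
    return AlleleFreqTable(base=base, drifted=drifted, fst=fst)


def simulate_founder_haplotypes(
    freqs: AlleleFreqTable,
    chrom: np.ndarray,
    pos: np.ndarray,
    n_hap_per_pool: int,
    seed: int = 0,
    ld: FounderLdSpec | None = None,
) -> dict[str, HaplotypePanel]:
    """Draw founder haplotypes per pool from the drifted pool frequencies.

    By default SNPs are independent within pool (no background LD beyond
    drift, which keeps downstream oracles tractable).  With an
    :class:`FounderLdSpec`, haplotypes are prototype-copying mosaics that
    carry realistic long shared blocks within each pool.

    Returns a dict keyed by pool name.  Each panel's "animals" are pairs of
    founder haplotypes; sample ids are ``{POOL}_{k}``.
    """
    if n_hap_per_pool < 2:
        raise ValueError("need at least two haplotypes per pool")
    if n_hap_per_pool % 2:
        raise ValueError("n_hap_per_pool must be even (haplotypes pair into animals)")
    if len(pos) != freqs.n_snps:
        raise ValueError("frequency table length does not match the SNP grid")
    rng = np.random.default_rng(seed)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    out = {}
    for j, pool in enumerate(POOLS):
        p = freqs.drifted[:, j]
        if ld is None:
            haps = (
                rng.random((freqs.n_snps, n_hap_per_pool)) < p[:, None]
            ).astype(np.int8)
        else:
            haps = np.empty((freqs.n_snps, n_hap_per_pool), dtype=np.int8)
            start = 0
            for c in dict.fromkeys(chrom.tolist()):
                stop = start + int(np.count_nonzero(chrom == c))
                haps[start:stop] = _ld_pool_haplotypes(
                    p[start:stop], pos[start:stop], n_hap_per_pool, ld, rng
                )
                start = stop
        samples = [f"{pool}_{k}" for k in range(n_hap_per_pool // 2)]
        out[pool] = HaplotypePanel(chrom, pos, haps, samples)
    return out


def _ld_pool_haplotypes(
    p: np.ndarray, pos: np.ndarray, n_haps: int, ld: FounderLdSpec, rng
) -> np.ndarray:
    """Prototype-copying haplotypes for one pool on one chromosome."""
    n_snps = len(p)
    protos = (rng.random((n_snps, ld.n_prototypes)) < p[:, None]).astype(np.int8)
    length_bp = int(pos[-1])
    lam = ld.switch_per_morgan * length_bp / BP_PER_MORGAN
    haps = np.empty((n_snps, n_haps), dtype=np.int8)
    for h in range(n_haps):
        n_switch = rng.poisson(lam)
        cuts = np.sort(rng.integers(1, length_bp + 1, size=n_switch))
        picks = rng.integers(0, ld.n_prototypes, size=n_switch + 1)
        path = picks[np.searchsorted(cuts, pos, side="left")]
        hap = protos[np.arange(n_snps), path]
        if ld.emission_error > 0:
            flip = rng.random(n_snps) < ld.emission_error
            hap = hap.copy()
            hap[flip] = (rng.random(int(flip.sum())) < p[flip]).astype(np.int8)
        haps[:, h] = hap
    return haps


# --------------------------------------------------------------------------
# forward admixture with tract tracking
# --------------------------------------------------------------------------
#
# During simulation a haplotype is a breakpoint list: segments given as
# (end_bp, pool, founder_hap_column); segment k covers (end_{k-1}, end_k].

Segments = list[tuple[int, int, int]]


def _two_parents(n: int, rng) -> tuple[int, int]:
    """Two distinct parent indices (no selfing)."""
    pa = int(rng.integers(n))
    pb = int(rng.integers(n - 1))
    if pb >= pa:
        pb += 1
    return pa, pb


def _meiosis(hap_a: Segments, hap_b: Segments, length_bp: int, rng) -> Segments:
    """One meiosis: Haldane crossovers at 1 cM/Mbp, no interference."""
    n_x = rng.poisson(length_bp / BP_PER_MORGAN)
    current, other = (hap_a, hap_b) if rng.random() < 0.5 else (hap_b, hap_a)
    if n_x == 0:
        return list(current)
    cuts, mult = np.unique(rng.integers(1, length_bp, size=n_x), return_counts=True)
    cuts = cuts[mult % 2 == 1]  # coincident crossovers cancel pairwise
    out: Segments = []
    prev = 0
    for cut in cuts:
        cut = int(cut)
        _copy_range(out, current, prev, cut)
        prev = cut
        current, other = other, current
    _copy_range(out, current, prev, length_bp)
    return out


def _copy_range(out: Segments, src: Segments, start: int, stop: int) -> None:
    """Append the (start, stop] slice of ``src`` onto ``out``, merging ends."""
    ends = [s[0] for s in src]
    i = bisect.bisect_left(ends, start + 1)
    while i < len(src) and src[i][0] < stop:
        _push(out, (src[i][0], src[i][1], src[i][2]))
        i += 1
    if i < len(src):
        _push(out, (stop, src[i][1], src[i][2]))


def _push(out: Segments, seg: tuple[int, int, int]) -> None:
    if out and out[-1][1] == seg[1] and out[-1][2] == seg[2]:
        out[-1] = (seg[0], seg[1], seg[2])
    else:
        out.append(seg)


def _founder_pools(pool_probs: np.ndarray, pop_size: int) -> np.ndarray:
    """Deterministic pool composition of the base generation.

    Largest-remainder rounding of ``pop_size * proportions`` so the base
    population's ancestry composition matches the target exactly (up to
    integer rounding) rather than adding multinomial noise on top of drift.
    """
    ideal = pool_probs * pop_size
    counts = np.floor(ideal).astype(int)
    short = pop_size - counts.sum()
    for j in np.argsort(ideal - np.floor(ideal))[::-1][:short]:
        counts[j] += 1
    return np.repeat(np.arange(3), counts)


def _project(
    segs: Segments, pos_chrom: np.ndarray, founder_haps: dict[int, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Fill alleles and labels at SNP positions; count visible EUT junctions.

    The visible-junction count is derived from the tract list alone: a pair
    of adjacent SNPs shows a recent crossover iff an odd number of
    EUT <-> non-EUT tract boundaries falls between them.
    """
    n = len(pos_chrom)
    alleles = np.empty(n, dtype=np.int8)
    labels = np.empty(n, dtype=np.int8)
    prev = 0
    class_bounds = []
    prev_class = None
    for end, pool, fid in segs:
        lo = np.searchsorted(pos_chrom, prev, side="right")
        hi = np.searchsorted(pos_chrom, end, side="right")
        if hi > lo:
            alleles[lo:hi] = founder_haps[pool][lo:hi, fid]
            labels[lo:hi] = pool
        cls = pool == EUT
        if prev_class is not None and cls != prev_class:
            class_bounds.append(prev)
        prev_class = cls
        prev = end
    if class_bounds:
        gaps = np.searchsorted(pos_chrom, np.array(class_bounds), side="right")
        inside = (gaps > 0) & (gaps < n)
        counts = np.bincount(gaps[inside], minlength=n + 1)
        visible = int(np.sum(counts % 2 == 1))
    else:
        visible = 0
    return alleles, labels, visible


def simulate_admixture(
    founders: dict[str, HaplotypePanel],
    n_animals: int,
    generations: int | np.ndarray | tuple[int, int] = (12, 24),
    proportions: tuple[float, float, float] = (0.24, 0.03, 0.73),
    pop_size: int = 200,
    seed: int = 0,
) -> tuple[HaplotypePanel, AncestryMatrix, dict]:
    """Forward-simulate an admixed cohort from three founder pools.

    A breeding population of ``pop_size`` individuals evolves by discrete
    non-overlapping generations of random mating (two distinct parents per
    offspring).  The base generation consists of pure individuals whose
    pool composition matches ``proportions``; each later generation is
    produced by fresh meioses with Poisson crossovers.  A cohort animal of
    admixture age ``g`` is an offspring of two random generation ``g - 1``
    individuals, so age-1 animals are F1s of pure parents with intact
    single-ancestry haplotypes, while old ages give deeply recombined
    inter-se animals.

    Parameters
    ----------
    founders
        Pool panels from :func:`simulate_founder_haplotypes`; all three on
        one SNP grid.
    generations
        Admixture age: a constant, a ``(low, high)`` tuple for per-animal
        uniform integer draws (inclusive), or one age per animal.
    proportions
        Base-generation pool shares in (IND, AFT, EUT) order; the expected
        genome-wide ancestry fractions of the cohort (finite ``pop_size``
        adds drift around them).

    Returns
    -------
    (panel, ancestry, truth)
        ``truth`` records per-animal generation ages and, per haplotype
        per chromosome, the simulator's visible EUT <-> non-EUT junction
        count at SNP resolution (the oracle for crossover counting).
    """
    grid = founders[POOLS[0]]
    for pool in POOLS[1:]:
        other = founders[pool]
        if not (
            np.array_equal(other.chrom, grid.chrom)
            and np.array_equal(other.pos, grid.pos)
        ):
            raise ValueError("founder pools are on mismatched SNP grids")
    pool_probs = np.asarray(proportions, dtype=float)
    if pool_probs.shape != (3,) or not np.isclose(pool_probs.sum(), 1.0):
        raise ValueError("proportions must be three values summing to 1")
    if pop_size < 2:
        raise ValueError("pop_size must be at least 2")
    rng = np.random.default_rng(seed)
    if isinstance(generations, tuple):
        lo, hi = generations
        gens = rng.integers(lo, hi + 1, size=n_animals)
    else:
        gens = np.broadcast_to(np.asarray(generations, dtype=int), (n_animals,)).copy()
    if (gens < 1).any():
        raise ValueError("generations must be >= 1")
    g_max = int(gens.max())
    n_hap_per_pool = grid.n_haps
    base_pools = _founder_pools(pool_probs, pop_size)

    n_snps = grid.n_snps
    haps = np.empty((n_snps, 2 * n_animals), dtype=np.int8)
    labels = np.empty((n_snps, 2 * n_animals), dtype=np.int8)
    chrom_ids = grid.chromosomes
    junctions = np.zeros((2 * n_animals, len(chrom_ids)), dtype=np.int64)

    founder_mats = {j: founders[POOLS[j]].haps for j in range(3)}
    for ci, (c, sl) in enumerate(grid.iter_chromosomes()):
        pos_chrom = grid.pos[sl]
        length_bp = int(pos_chrom[-1])
        fh = {p: founder_mats[p][sl] for p in range(3)}
        # base generation: pure individuals, pools fixed by composition
        pop: list[tuple[Segments, Segments]] = []
        for k in range(pop_size):
            pool = int(base_pools[k])
            i, j = rng.integers(0, n_hap_per_pool, size=2)
            pop.append(
                ([(length_bp, pool, int(i))], [(length_bp, pool, int(j))])
            )
        history = [pop]
        for _ in range(g_max - 1):
            prev = history[-1]
            nxt: list[tuple[Segments, Segments]] = []
            for _k in range(pop_size):
                pa, pb = _two_parents(len(prev), rng)
                nxt.append(
                    (
                        _meiosis(*prev[pa], length_bp, rng),
                        _meiosis(*prev[pb], length_bp, rng),
                    )
                )
            history.append(nxt)
        for a in range(n_animals):
            parents = history[int(gens[a]) - 1]
            pa, pb = _two_parents(len(parents), rng)
            for h, parent in enumerate((parents[pa], parents[pb])):
                segs = _meiosis(*parent, length_bp, rng)
                col = 2 * a + h
                alleles, labs, visible = _project(segs, pos_chrom, fh)
                haps[sl, col] = alleles
                labels[sl, col] = labs
                junctions[col, ci] = visible

    samples = [f"adm_{a}" for a in range(n_animals)]
    panel = HaplotypePanel(grid.chrom, grid.pos, haps, samples)
    ancestry = AncestryMatrix(grid.chrom, grid.pos, labels, samples)
    truth = {
        "generations": gens,
        "junctions": junctions,  # (n_haps, n_chrom) visible recent crossovers
        "chromosomes": chrom_ids,
        "proportions": tuple(pool_probs),
    }
    return panel, ancestry, truth


# --------------------------------------------------------------------------
# sweep injection
# --------------------------------------------------------------------------


def inject_sweep(
    panel: HaplotypePanel, spec: SweepSpec, seed: int = 0, donor: int | None = None
) -> tuple[HaplotypePanel, dict]:
    """Copy a donor haplotype's flank onto recipients until the carrier
    frequency of the favored core haplotype reaches the target.

    Carriers are haplotypes identical to the donor over the whole flank.
    Alleles outside the flank are untouched.  The donor haplotype is
    chosen at random unless given explicitly (e.g. to favor the minor
    core allele, the classic partial-sweep setting).  Returns the modified
    panel (a copy) and a dict with the donor, flank SNP range and core
    index.
    """
    rng = np.random.default_rng(seed)
    sl = panel.chrom_slice(spec.chrom)
    n_chrom_snps = sl.stop - sl.start
    if not 0 <= spec.core_index < n_chrom_snps:
        raise ValueError("core SNP index outside chromosome bounds")
    core = sl.start + spec.core_index
    core_pos = panel.pos[core]
    pos_chrom = panel.pos[sl]
    if (
        core_pos - spec.half_width_bp < pos_chrom[0]
        or core_pos + spec.half_width_bp > pos_chrom[-1]
    ):
        warnings.warn(
            "sweep flank extends beyond the chromosome; truncated", stacklevel=2
        )
    in_flank = np.abs(pos_chrom - core_pos) <= spec.half_width_bp
    flank_idx = np.flatnonzero(in_flank) + sl.start

    haps = panel.haps.copy()
    if donor is None:
        donor = int(rng.integers(panel.n_haps))
    donor_flank = haps[flank_idx, donor]
    carriers = np.all(haps[flank_idx, :] == donor_flank[:, None], axis=0)
    n_target = int(round(spec.target_freq * panel.n_haps))
    n_current = int(carriers.sum())
    if n_target < n_current:
        raise ValueError(
            "target carrier frequency below the current carrier frequency"
        )
    if n_target > n_current:
        pool = np.flatnonzero(~carriers)
        recipients = rng.choice(pool, size=n_target - n_current, replace=False)
        haps[np.ix_(flank_idx, recipients)] = donor_flank[:, None]
    swept = HaplotypePanel(panel.chrom, panel.pos, haps, list(panel.samples))
    info = {
        "donor": donor,
        "core_snp": int(core),
        "flank_snps": flank_idx,
        "n_carriers": n_target if n_target > n_current else n_current,
    }
    return swept, info


# --------------------------------------------------------------------------
# phenotypes
# --------------------------------------------------------------------------


def simulate_phenotypes(
    ancestry: AncestryMatrix,
    panel: HaplotypePanel,
    qtl: QtlSpec,
    var: VarianceSpec,
    grm: np.ndarray | None = None,
    mu: float = 0.0,
    seed: int = 0,
) -> PhenotypeTable:
    """Simulate repeated phenotype records under the additive mixed model.

    Each record is ``mu + sum_q (origin_effect x EUT dosage) + sum_q
    (allele_effect x allele dosage) + u + pe + e`` with ``u ~ N(0, sigma_g2
    G)``, ``pe ~ N(0, sigma_pe2 I)`` per animal and ``e ~ N(0, sigma_e2 I)``
    per record.
    """
    from .ancestry import eut_dosage  # local import to avoid a cycle

    qtl.validate(panel.n_snps)
    n_animals = panel.n_animals
    if var.sigma_g2 > 0:
        if grm is None:
            raise ValueError("a GRM is required when sigma_g2 > 0")
        grm = np.asarray(grm, dtype=float)
        if grm.shape != (n_animals, n_animals):
            raise ValueError("GRM dimension must equal the animal count")

    rng = np.random.default_rng(seed)
    genetic = np.full(n_animals, mu, dtype=float)
    if qtl.loci:
        odos = eut_dosage(ancestry)
        ados = panel.dosages()
        for q in qtl.loci:
            genetic += q.origin_effect * odos[q.snp_index]
            genetic += q.allele_effect * ados[q.snp_index].astype(float)
    if var.sigma_g2 > 0:
        # small jitter keeps the factorization of near-singular G viable
        jitter = 1e-8 * np.trace(grm) / n_animals
        chol = np.linalg.cholesky(
            var.sigma_g2 * (grm + jitter * np.eye(n_animals))
        )
        genetic += chol @ rng.standard_normal(n_animals)
    if var.sigma_pe2 > 0:
        genetic += np.sqrt(var.sigma_pe2) * rng.standard_normal(n_animals)

    counts = np.broadcast_to(
        np.asarray(var.records_per_animal, dtype=int), (n_animals,)
    )
    animal_per_record = np.repeat(np.arange(n_animals), counts)
    values = genetic[animal_per_record]
    if var.sigma_e2 > 0:
        values = values + np.sqrt(var.sigma_e2) * rng.standard_normal(len(values))
    else:
        values = values.copy()
    animal_ids = np.array(panel.samples, dtype=object)[animal_per_record]
    return PhenotypeTable(animal=animal_ids, value=values)
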
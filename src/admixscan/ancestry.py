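"""Local-ancestry summaries: dosages, crossover counts, the recency filter.

The admixed cohort mixes animals with very different admixture ages.  A
*recent crossover* is an adjacent-SNP ancestry transition between EUT and a
non-EUT (IND or AFT) label on one haplotype; IND <-> AFT transitions are
internal to the indigenous component and do not count.  Counting these
transitions per Morgan (1 Morgan = 100 Mbp) and averaging the lower-count
haplotype across chromosomes yields a per-animal recency score: recently
admixed animals carry long intact blocks and score near zero, deep inter-se
animals accumulate crossovers.  Animals scoring below a threshold (default
3 per Morgan) are removed before the haplotype-based selection scans, where
their long intact haplotypes would otherwise swamp genuine sweep signals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import BP_PER_MORGAN, EUT, POOLS, AncestryMatrix

__all__ = [
    "CrossoverSummary",
    "eut_dosage",
    "count_crossovers",
    "crossover_summary",
    "filter_recent",
    "global_proportions",
    "region_dominant_ancestry",
]

logger = logging.getLogger(__name__)


def eut_dosage(ancestry: AncestryMatrix) -> np.ndarray:
    """EUT-origin allele dosage per SNP per animal, coded 0/1/2.

    The dosage is the number of the animal's two haplotypes whose allele at
    the SNP descends from the EUT ancestor; IND and AFT both count as
    non-EUT.
    """
    is_eut = (ancestry.labels == EUT).astype(np.int8)
    return is_eut[:, 0::2] + is_eut[:, 1::2]


def count_crossovers(track: np.ndarray, length_bp: float) -> float:
    """Recent crossovers per Morgan along one haplotype on one chromosome.

    ``track`` is the haplotype's ancestry-label sequence; only transitions
    where exactly one side is EUT are counted.  The per-Morgan rate divides
    by the chromosome length converted at 1 Morgan = 100 Mbp.
    """
    track = np.asarray(track)
    if track.size == 0:
        raise ValueError("empty ancestry track")
    if length_bp <= 0:
        raise ValueError("chromosome length must be positive")
    is_eut = track == EUT
    count = int(np.count_nonzero(is_eut[1:] != is_eut[:-1]))
    return count / (length_bp / BP_PER_MORGAN)


@dataclass
class CrossoverSummary:
    """Per animal x chromosome crossover rates and the per-animal recency score.

    ``low``/``high`` hold the per-Morgan rates of the lower- and
    higher-count haplotype of each animal on each chromosome; ``score`` is
    the unweighted mean of the ``low`` values across chromosomes.
    """

    samples: list[str]
    chromosomes: list[int]
    low: np.ndarray  # (n_animals, n_chrom)
    high: np.ndarray  # (n_animals, n_chrom)
    score: np.ndarray  # (n_animals,)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, s in enumerate(self.samples):
            row: dict = {"animal_id": s, "score": self.score[a]}
            for ci, c in enumerate(self.chromosomes):
                row[f"chr{c}_low"] = self.low[a, ci]
                row[f"chr{c}_high"] = self.high[a, ci]
            rows.append(row)
        return pd.DataFrame(rows)


def crossover_summary(ancestry: AncestryMatrix) -> CrossoverSummary:
    """Count recent crossovers for both haplotypes of every animal.

    Per chromosome the two haplotypes are ranked; the recency score is the
    unweighted mean over chromosomes of the lower-count haplotype's
    per-Morgan rate.  Chromosome length is taken as the position of its
    last SNP.
    """
    chroms = ancestry.chromosomes
    n_animals = ancestry.n_animals
    low = np.zeros((n_animals, len(chroms)))
    high = np.zeros((n_animals, len(chroms)))
    for ci, (c, sl) in enumerate(ancestry.iter_chromosomes()):
        length = float(ancestry.pos[sl.stop - 1])
        is_eut = ancestry.labels[sl] == EUT
        flips = (is_eut[1:] != is_eut[:-1]).sum(axis=0) / (length / BP_PER_MORGAN)
        h1, h2 = flips[0::2], flips[1::2]
        low[:, ci] = np.minimum(h1, h2)
        high[:, ci] = np.maximum(h1, h2)
    score = low.mean(axis=1)
    return CrossoverSummary(
        samples=list(ancestry.samples),
        chromosomes=chroms,
        low=low,
        high=high,
        score=score,
    )


def filter_recent(
    summary: CrossoverSummary, threshold: float = 3.0
) -> tuple[list[str], list[str]]:
    """Split animals into (retained, removed) at the recency-score threshold.

    Animals with score >= threshold are retained ("three or more crossovers
    per Morgan" at the default); recently admixed animals below it are
    removed before the selection scans.
    """
    keep = summary.score >= threshold
    retained = [s for s, k in zip(summary.samples, keep) if k]
    removed = [s for s, k in zip(summary.samples, keep) if not k]
    logger.info(
        "recency filter at %.3g crossovers/Morgan: %d retained, %d removed",
        threshold,
        len(retained),
        len(removed),
    )
    return retained, removed


def global_proportions(ancestry: AncestryMatrix) -> pd.DataFrame:
    """Genome-wide ancestry fractions per animal, plus the cohort mean.

    Fractions are SNP-weighted shares of each pool over an animal's two
    haplotypes and sum to one per animal.  The cohort mean appears in the
    frame's ``attrs["cohort_mean"]``.
    """
    n_animals = ancestry.n_animals
    fracs = np.zeros((n_animals, 3))
    for code in range(3):
        hits = (ancestry.labels == code).sum(axis=0)
        fracs[:, code] = (hits[0::2] + hits[1::2]) / (2 * ancestry.n_snps)
    df = pd.DataFrame(fracs, columns=list(POOLS))
    df.insert(0, "animal_id", ancestry.samples)
    df.attrs["cohort_mean"] = {p: float(fracs[:, i].mean()) for i, p in enumerate(POOLS)}
    return df


def region_dominant_ancestry(
    ancestry: AncestryMatrix,
    chrom: int,
    start_bp: int,
    end_bp: int,
    animals: list[str] | None = None,
) -> str:
    """Dominant ancestral pool of a genomic region among the given animals.

    The label is the argmax of the mean ancestry fraction per pool over the
    region's SNPs and the animals' haplotypes; exact ties resolve in fixed
    IND, AFT, EUT order with a logged warning.
    """
    mat = ancestry.take_animals(animals) if animals is not None else ancestry
    sl = mat.chrom_slice(chrom)
    in_region = (mat.pos[sl] >= start_bp) & (mat.pos[sl] <= end_bp)
    if not in_region.any():
        raise ValueError(
            f"no SNPs in region {chrom}:{start_bp}-{end_bp}"
        )
    block = mat.labels[sl][in_region]
    fracs = np.array([(block == code).mean() for code in range(3)])
    best = fracs.max()
    winners = np.flatnonzero(fracs == best)
    if len(winners) > 1:
        logger.warning(
            "dominant-ancestry tie in %d:%d-%d between %s; using pool order",
            chrom,
            start_bp,
            end_bp,
            [POOLS[w] for w in winners],
        )
    return POOLS[int(winners[0])]
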
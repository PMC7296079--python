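"""Core in-memory containers shared across the pipeline.

The pipeline operates on phased biallelic haplotypes of an admixed cohort
together with per-allele local-ancestry labels.  Two array-backed containers
carry that state:

``HaplotypePanel``
    A SNPs x haplotypes 0/1 allele matrix with bp positions, grouped by
    chromosome.  Haplotype columns come in pairs: columns ``2i`` and
    ``2i + 1`` are the two phased haplotypes of animal ``i``.

``AncestryMatrix``
    A SNPs x haplotypes matrix of ancestral-pool labels aligned to a panel.
    Labels are integer codes for the three ancestral pools: IND (Bos
    indicus), AFT (African Bos taurus) and EUT (European Bos taurus).

Physical positions double as map positions throughout, at a uniform
recombination rate of 1 Morgan per 100 Mbp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: Ancestral pool names in fixed code order.
POOLS: tuple[str, str, str] = ("IND", "AFT", "EUT")
POOL_CODE: dict[str, int] = {p: i for i, p in enumerate(POOLS)}
IND, AFT, EUT = 0, 1, 2

#: Map convention: 1 Morgan corresponds to 100 Mbp of physical distance.
BP_PER_MORGAN: float = 1e8


def _check_grid(chrom: np.ndarray, pos: np.ndarray) -> None:
    if chrom.ndim != 1 or pos.ndim != 1 or chrom.shape != pos.shape:
        raise ValueError("chrom and pos must be 1-D arrays of equal length")
    # SNPs must be grouped by chromosome with strictly increasing positions.
    seen: set[int] = set()
    start = 0
    for c, stop in _group_bounds(chrom):
        if c in seen:
            raise ValueError(f"chromosome {c} is not contiguous in the SNP grid")
        seen.add(c)
        p = pos[start:stop]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not strictly increasing on chromosome {c}")
        start = stop


def _group_bounds(chrom: np.ndarray) -> Iterator[tuple[int, int]]:
    """Yield (chromosome, stop_index) for each contiguous chromosome block."""
    if len(chrom) == 0:
        return
    change = np.flatnonzero(np.diff(chrom)) + 1
    stops = np.append(change, len(chrom))
    for stop in stops:
        yield int(chrom[stop - 1]), int(stop)


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a cohort.

    Parameters
    ----------
    chrom
        Chromosome number per SNP, grouped contiguously.
    pos
        bp position per SNP, strictly increasing within chromosome.
    haps
        ``(n_snps, n_haps)`` int8 matrix of 0/1 alleles; columns ``2i`` and
        ``2i+1`` belong to animal ``i``.
    samples
        Animal identifiers, one per haplotype pair.
    """

    chrom: np.ndarray
    pos: np.ndarray
    haps: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.haps = np.asarray(self.haps, dtype=np.int8)
        self.samples = [str(s) for s in self.samples]
        _check_grid(self.chrom, self.pos)
        if self.haps.ndim != 2 or self.haps.shape[0] != len(self.pos):
            raise ValueError("haps must be (n_snps, n_haps)")
        if self.haps.shape[1] != 2 * len(self.samples):
            raise ValueError("need exactly two haplotype columns per sample")
        bad = (self.haps != 0) & (self.haps != 1)
        if bad.any():
            raise ValueError("alleles must be 0 or 1")

    # ---- basic geometry -------------------------------------------------
    @property
    def n_snps(self) -> int:
        return self.haps.shape[0]

    @property
    def n_haps(self) -> int:
        return self.haps.shape[1]

    @property
    def n_animals(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list[int]:
        return [c for c, _ in _group_bounds(self.chrom)]

    def chrom_slice(self, c: int) -> slice:
        """Index slice of the SNPs on chromosome ``c``."""
        idx = np.flatnonzero(self.chrom == c)
        if len(idx) == 0:
            raise KeyError(f"no SNPs on chromosome {c}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def iter_chromosomes(self) -> Iterator[tuple[int, slice]]:
        start = 0
        for c, stop in _group_bounds(self.chrom):
            yield c, slice(start, stop)
            start = stop

    def chrom_length_bp(self, c: int) -> int:
        """Chromosome length for map conversions: position of its last SNP."""
        sl = self.chrom_slice(c)
        return int(self.pos[sl.stop - 1])

    # ---- derived matrices ----------------------------------------------
    def dosages(self) -> np.ndarray:
        """Per-animal alternate-allele dosage in {0, 1, 2}, ``(n_snps, n_animals)``."""
        return (self.haps[:, 0::2] + self.haps[:, 1::2]).astype(np.int8)

    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over all haplotypes."""
        return self.haps.mean(axis=1)

    # ---- subsetting ------------------------------------------------------
    def take_snps(self, index: np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            self.chrom[index], self.pos[index], self.haps[index], list(self.samples)
        )

    def take_animals(self, which: Sequence[int] | Sequence[str]) -> "HaplotypePanel":
        idx = self._animal_indices(which)
        cols = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return HaplotypePanel(
            self.chrom, self.pos, self.haps[:, cols], [self.samples[i] for i in idx]
        )

    def _animal_indices(self, which: Sequence[int] | Sequence[str]) -> np.ndarray:
        if len(which) and isinstance(next(iter(which)), str):
            lut = {s: i for i, s in enumerate(self.samples)}
            return np.array([lut[s] for s in which], dtype=np.int64)
        return np.asarray(which, dtype=np.int64)

    @staticmethod
    def concat_animals(panels: Sequence["HaplotypePanel"]) -> "HaplotypePanel":
        """Stack cohorts genotyped on the same SNP grid side by side."""
        first = panels[0]
        for p in panels[1:]:
            if not (
                np.array_equal(p.chrom, first.chrom) and np.array_equal(p.pos, first.pos)
            ):
                raise ValueError("panels are on different SNP grids")
        haps = np.concatenate([p.haps for p in panels], axis=1)
        samples = [s for p in panels for s in p.samples]
        return HaplotypePanel(first.chrom, first.pos, haps, samples)


@dataclass
class AncestryMatrix:
    """Per-allele local-ancestry labels aligned to a :class:`HaplotypePanel`.

    ``labels`` holds pool codes (0=IND, 1=AFT, 2=EUT) with the same
    (n_snps, n_haps) layout as the panel's allele matrix.
    """

    chrom: np.ndarray
    pos: np.ndarray
    labels: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.samples = [str(s) for s in self.samples]
        _check_grid(self.chrom, self.pos)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.pos):
            raise ValueError("labels must be (n_snps, n_haps)")
        if self.labels.shape[1] != 2 * len(self.samples):
            raise ValueError("need exactly two haplotype columns per sample")
        if ((self.labels < 0) | (self.labels > 2)).any():
            raise ValueError("ancestry labels must code IND/AFT/EUT (0/1/2); "
                             "missing labels are not permitted")

    @property
    def n_snps(self) -> int:
        return self.labels.shape[0]

    @property
    def n_haps(self) -> int:
        return self.labels.shape[1]

    @property
    def n_animals(self) -> int:
        return len(self.samples)

    @property
    def chromosomes(self) -> list[int]:
        return [c for c, _ in _group_bounds(self.chrom)]

    chrom_slice = HaplotypePanel.chrom_slice
    iter_chromosomes = HaplotypePanel.iter_chromosomes
    chrom_length_bp = HaplotypePanel.chrom_length_bp
    _animal_indices = HaplotypePanel._animal_indices

    def take_animals(self, which: Sequence[int] | Sequence[str]) -> "AncestryMatrix":
        idx = self._animal_indices(which)
        cols = np.stack([2 * idx, 2 * idx + 1], axis=1).ravel()
        return AncestryMatrix(
            self.chrom, self.pos, self.labels[:, cols], [self.samples[i] for i in idx]
        )

    @staticmethod
    def concat_animals(mats: Sequence["AncestryMatrix"]) -> "AncestryMatrix":
        first = mats[0]
        for m in mats[1:]:
            if not (
                np.array_equal(m.chrom, first.chrom) and np.array_equal(m.pos, first.pos)
            ):
                raise ValueError("ancestry matrices are on different SNP grids")
        labels = np.concatenate([m.labels for m in mats], axis=1)
        samples = [s for m in mats for s in m.samples]
        return AncestryMatrix(first.chrom, first.pos, labels, samples)


@dataclass
class PhenotypeTable:
    """Repeated phenotype records (e.g. milk-yield deviations) keyed by animal."""

    animal: np.ndarray  # str per record
    value: np.ndarray  # float per record
    record: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=object)
        self.value = np.asarray(self.value, dtype=np.float64)
        if self.record is None:
            self.record = np.arange(len(self.value), dtype=np.int64)
        self.record = np.asarray(self.record, dtype=np.int64)
        if not (len(self.animal) == len(self.value) == len(self.record)):
            raise ValueError("animal, value and record must have equal length")
        if len(self.value) == 0:
            raise ValueError("phenotype table is empty")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("non-finite phenotype values")

    @property
    def n_records(self) -> int:
        return len(self.value)

    def animals(self) -> list[str]:
        """Distinct animal ids in first-appearance order."""
        return list(dict.fromkeys(self.animal.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal_id": self.animal, "record_id": self.record, "value": self.value}
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "PhenotypeTable":
        return PhenotypeTable(
            animal=df["animal_id"].to_numpy(),
            value=df["value"].to_numpy(dtype=float),
            record=df["record_id"].to_numpy(dtype=np.int64)
            if "record_id" in df
            else None,
        )
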
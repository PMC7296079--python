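"""Genomic relationship matrices (VanRaden method 1) and PCA.

The GRM is ``G = Z Z' / (2 sum p(1-p))`` with ``Z = M - 2p`` the
frequency-centered dosage matrix.  Centering frequencies default to the
analyzed sample's own allele frequencies.  A leave-one-chromosome-out
(LOCO) variant excludes the chromosome of the SNP under test from ``G`` so
the polygenic term does not absorb the tested signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

__all__ = ["GRM", "build_grm", "grm_pca", "write_grm", "read_grm"]

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """A symmetric animal x animal genomic relationship matrix."""

    matrix: np.ndarray
    samples: list[str]
    freqs: np.ndarray  # centering frequency of every SNP used
    snp_index: np.ndarray  # indices of the SNPs summed over
    excluded_chrom: int | None = None

    @property
    def n_animals(self) -> int:
        return self.matrix.shape[0]

    def subset(self, animals: list[str]) -> "GRM":
        lut = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([lut[a] for a in animals])
        return GRM(
            matrix=self.matrix[np.ix_(idx, idx)],
            samples=list(animals),
            freqs=self.freqs,
            snp_index=self.snp_index,
            excluded_chrom=self.excluded_chrom,
        )


def build_grm(
    panel: HaplotypePanel,
    exclude_chrom: int | None = None,
    freqs: np.ndarray | None = None,
    ridge: float = 0.0,
) -> GRM:
    """VanRaden method-1 GRM from a haplotype panel.

    Monomorphic SNPs (at the centering frequencies) are dropped from the
    sum.  ``exclude_chrom`` removes one chromosome for LOCO association
    testing.  ``ridge`` adds a small diagonal for factorization stability
    and is logged when non-zero.
    """
    dosages = panel.dosages().astype(np.float64)
    if freqs is None:
        freqs = dosages.mean(axis=1) / 2.0
    freqs = np.asarray(freqs, dtype=np.float64)
    include = np.ones(panel.n_snps, dtype=bool)
    if exclude_chrom is not None:
        include &= panel.chrom != exclude_chrom
    include &= (freqs > 0) & (freqs < 1)
    if not include.any():
        raise ValueError("no SNPs left to build the GRM from")
    idx = np.flatnonzero(include)
    p = freqs[idx]
    z = dosages[idx] - 2.0 * p[:, None]
    denom = 2.0 * np.sum(p * (1.0 - p))
    g = (z.T @ z) / denom
    if ridge > 0:
        logger.info("adding ridge %.3g to the GRM diagonal", ridge)
        g = g + ridge * np.eye(g.shape[0])
    return GRM(
        matrix=g,
        samples=list(panel.samples),
        freqs=p,
        snp_index=idx,
        excluded_chrom=exclude_chrom,
    )


def grm_pca(grm: GRM, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of the relationship matrix.

    Returns per-animal scores (eigenvectors scaled by the square root of
    their eigenvalues) and the per-component variance fractions
    (eigenvalue over trace), ordered by decreasing eigenvalue.
    """
    if k > grm.n_animals:
        raise ValueError("k exceeds the matrix dimension")
    if not np.all(np.isfinite(grm.matrix)):
        raise ValueError("non-finite entries in the GRM")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = np.sum(vals)
    fractions = np.clip(vals[:k], 0, None) / trace
    scores = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0, None))
    df = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "animal_id", grm.samples)
    return df, fractions


def write_grm(grm: GRM, path) -> None:
    """Dense TSV with a header row of animal ids."""
    pd.DataFrame(grm.matrix, columns=grm.samples).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_grm(path) -> GRM:
    df = pd.read_csv(path, sep="\t")
    m = df.to_numpy(dtype=float)
    return GRM(
        matrix=m,
        samples=list(df.columns),
        freqs=np.array([]),
        snp_index=np.array([], dtype=int),
    )
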
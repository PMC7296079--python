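"""Readers and writers for the pipeline's file formats.

Formats
-------
* Phased VCF: biallelic records with ``GT`` fields like ``0|1``; written
  as plain text, read through cyvcf2.  Unphased or multiallelic records
  are rejected with counts reported.
* Haplotype TSV: columns ``chrom, pos, ref, alt`` then two columns per
  animal (``{id}_1``, ``{id}_2``) holding 0/1 alleles.
* Ancestry TSV: ``chrom, pos`` then two label columns per animal with
  IND/AFT/EUT labels.
* Phenotype CSV: ``animal_id, record_id, value``.
* Scan TSV: the per-SNP statistic tables written by the scans.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import POOL_CODE, POOLS, AncestryMatrix, HaplotypePanel, PhenotypeTable

__all__ = [
    "write_haplotype_tsv",
    "read_haplotype_tsv",
    "write_vcf",
    "read_vcf",
    "write_ancestry_tsv",
    "read_ancestry_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_scan",
    "read_scan",
    "write_json",
    "read_json",
]

logger = logging.getLogger(__name__)


# ---- haplotype TSV -------------------------------------------------------


def write_haplotype_tsv(panel: HaplotypePanel, path) -> None:
    cols = {"chrom": panel.chrom, "pos": panel.pos, "ref": "A", "alt": "G"}
    df = pd.DataFrame(cols)
    for i, s in enumerate(panel.samples):
        df[f"{s}_1"] = panel.haps[:, 2 * i]
        df[f"{s}_2"] = panel.haps[:, 2 * i + 1]
    df.to_csv(path, sep="\t", index=False)


def read_haplotype_tsv(path) -> HaplotypePanel:
    df = pd.read_csv(path, sep="\t")
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    samples = []
    for c in hap_cols[0::2]:
        if not c.endswith("_1"):
            raise ValueError(f"malformed haplotype column name: {c}")
        samples.append(c[:-2])
    haps = df[hap_cols].to_numpy(dtype=np.int8)
    return HaplotypePanel(
        df["chrom"].to_numpy(), df["pos"].to_numpy(), haps, samples
    )


# ---- phased VCF ----------------------------------------------------------


def write_vcf(panel: HaplotypePanel, path) -> None:
    """Minimal phased VCF (GT-only, ``0|1`` style) for the panel."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixscan\n")
        for c in panel.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for s in range(panel.n_snps):
            gts = "\t".join(
                f"{panel.haps[s, 2 * i]}|{panel.haps[s, 2 * i + 1]}"
                for i in range(panel.n_animals)
            )
            fh.write(
                f"{panel.chrom[s]}\t{panel.pos[s]}\t"
                f"snp_{panel.chrom[s]}_{panel.pos[s]}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> HaplotypePanel:
    """Read a phased biallelic VCF; unphased or multiallelic records are
    rejected and the rejection counts logged."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, rows = [], [], []
    n_unphased = n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = var.genotypes  # [hap1, hap2, phased] per sample
        if not all(g[2] for g in gts):
            n_unphased += 1
            continue
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int8)
        if (alleles < 0).any() or (alleles > 1).any():
            n_multi += 1
            continue
        rows.append(alleles.reshape(-1))
        c = var.CHROM
        chrom.append(int(c[3:]) if str(c).startswith("chr") else int(c))
        pos.append(var.POS)
    if n_unphased or n_multi:
        logger.warning(
            "rejected %d unphased and %d non-biallelic records", n_unphased, n_multi
        )
    if not rows:
        raise ValueError(f"no usable phased biallelic records in {path}")
    return HaplotypePanel(
        np.array(chrom), np.array(pos), np.vstack(rows), samples
    )


# ---- ancestry TSV --------------------------------------------------------


def write_ancestry_tsv(ancestry: AncestryMatrix, path) -> None:
    df = pd.DataFrame({"chrom": ancestry.chrom, "pos": ancestry.pos})
    for i, s in enumerate(ancestry.samples):
        for h in (0, 1):
            df[f"{s}_{h + 1}"] = [POOLS[c] for c in ancestry.labels[:, 2 * i + h]]
    df.to_csv(path, sep="\t", index=False)


def read_ancestry_tsv(path) -> AncestryMatrix:
    df = pd.read_csv(path, sep="\t")
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    samples = [c[:-2] for c in hap_cols[0::2]]
    labels = np.empty((len(df), len(hap_cols)), dtype=np.int8)
    for j, c in enumerate(hap_cols):
        try:
            labels[:, j] = [POOL_CODE[v] for v in df[c]]
        except KeyError as exc:
            raise ValueError(f"unknown ancestry label in column {c}: {exc}") from exc
    return AncestryMatrix(
        df["chrom"].to_numpy(), df["pos"].to_numpy(), labels, samples
    )


# ---- phenotypes, scans, JSON --------------------------------------------


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.to_frame().to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable.from_frame(pd.read_csv(path))


def write_scan(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
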
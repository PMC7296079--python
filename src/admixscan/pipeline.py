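"""End-to-end orchestration of the admixture GWA + selection-scan analysis.

``run_pipeline`` executes, from a single config: synthetic-cohort
simulation (or loading of user data), ancestry and crossover summaries,
the recency filter, GRM and PCA, the dual-effect GWA scans, iHS under the
all-samples and filtered scenarios, Rsb of the filtered admixed cohort
against a reference population, q values, candidate-region calling with
dominant-ancestry labels, and the GWA x SoS overlap report.  Every output
is written under the configured directory together with a JSON manifest
of seed, thresholds and per-stage record counts, so a rerun with the same
config reproduces every file.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, ancestry as anc_mod, io as io_mod
from .assoc import gwa_scan
from .ehh import ihs_scan, polarize_alleles, rsb_scan, standardize_ihs
from .mtc import fdr_threshold_line, qvalues
from .panel import AncestryMatrix, HaplotypePanel
from .regions import (
    call_gwa_regions,
    call_sos_regions,
    intersect_regions,
    regions_to_frame,
)
from .relatedness import build_grm, grm_pca, write_grm
from .synthpop import (
    FounderLdSpec,
    QtlEffect,
    QtlSpec,
    SweepSpec,
    VarianceSpec,
    inject_sweep,
    sample_ancestral_freqs,
    simulate_admixture,
    simulate_founder_haplotypes,
    simulate_phenotypes,
    snp_grid,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_cohort"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries a machine-readable stage code."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Thresholds, scenario switches and simulation sizes for one run."""

    out_dir: str = "admixscan_out"
    seed: int = 0
    # simulation sizes
    n_chrom: int = 4
    snps_per_chrom: int = 1000
    chrom_length_bp: int = 25_000_000
    n_admixed: int = 300
    n_recent: int = 75
    n_founder_haps: int = 60
    generations: tuple[int, int] = (12, 24)
    proportions: tuple[float, float, float] = (0.24, 0.03, 0.73)
    fst: tuple[float, float, float] = (0.25, 0.25, 0.25)
    founder_ld: bool = True
    ld_prototypes: int = 6
    ld_switch_per_morgan: float = 5.0
    ld_emission_error: float = 0.01
    # optional sweep
    sweep_chrom: int | None = None
    sweep_core_index: int | None = None
    sweep_target_freq: float = 0.6
    sweep_half_width_bp: int = 1_000_000
    # phenotype model
    sigma_g2: float = 1.0
    sigma_pe2: float = 0.5
    sigma_e2: float = 1.0
    records_per_animal: int = 3
    qtl: list = field(default_factory=list)  # (snp_index, origin_eff, allele_eff)
    # analysis thresholds
    crossover_threshold: float = 3.0
    maf: float = 0.05
    decay: float = 0.05
    bin_step: float = 0.025
    seed_q: float = 0.1
    suggestive_q_ihs: float = 0.5
    suggestive_q_rsb: float = 0.25
    gwa_p_thresh: float = 1e-3
    region_window: int = 500_000
    scenarios: tuple[str, ...] = ("all", "filtered")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("generations", "proportions", "fst", "scenarios"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return PipelineConfig(**d)


def simulate_cohort(config: PipelineConfig):
    """Simulate the study cohort plus an EASZ-like indigenous reference.

    The admixed cohort mixes deep inter-se animals (which carry any
    injected sweep) with recent F1 crosses (which do not: a sweep that
    acted in the admixed population predates them).  The reference
    population is drawn from the indigenous pools only.
    """
    if not 0 <= config.n_recent < config.n_admixed:
        raise ValueError("n_recent must be smaller than n_admixed")
    rng_seeds = np.random.SeedSequence(config.seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seeds]
    chrom, pos = snp_grid(
        config.n_chrom, config.snps_per_chrom, config.chrom_length_bp, seed=seeds[0]
    )
    freqs = sample_ancestral_freqs(len(pos), fst=config.fst, seed=seeds[1])
    ld = (
        FounderLdSpec(
            n_prototypes=config.ld_prototypes,
            switch_per_morgan=config.ld_switch_per_morgan,
            emission_error=config.ld_emission_error,
        )
        if config.founder_ld
        else None
    )
    founders = simulate_founder_haplotypes(
        freqs, chrom, pos, config.n_founder_haps, seed=seeds[2], ld=ld
    )
    panel_deep, anc_deep, truth_deep = simulate_admixture(
        founders,
        config.n_admixed - config.n_recent,
        generations=config.generations,
        proportions=config.proportions,
        seed=seeds[3],
    )
    sweep_info = None
    if config.sweep_chrom is not None:
        core_index = config.sweep_core_index
        donor = None
        sl = panel_deep.chrom_slice(config.sweep_chrom)
        if core_index is None:
            # mid-frequency core nearest the chromosome center: the classic
            # partial-sweep setting, and safely inside the MAF filter
            freqs_c = panel_deep.haps[sl].mean(axis=1)
            mid_ok = np.flatnonzero((freqs_c >= 0.3) & (freqs_c <= 0.7))
            if len(mid_ok) == 0:
                mid_ok = np.arange(sl.stop - sl.start)
            core_index = int(mid_ok[np.argmin(np.abs(mid_ok - (sl.stop - sl.start) // 2))])
        core_global = sl.start + core_index
        minor = int(panel_deep.haps[core_global].mean() <= 0.5)
        carriers = np.flatnonzero(panel_deep.haps[core_global] == minor)
        if len(carriers):
            donor = int(carriers[0])  # favor the minor core allele
        spec = SweepSpec(
            chrom=config.sweep_chrom,
            core_index=core_index,
            target_freq=config.sweep_target_freq,
            half_width_bp=config.sweep_half_width_bp,
        )
        panel_deep, sweep_info = inject_sweep(
            panel_deep, spec, seed=seeds[4], donor=donor
        )
    if config.n_recent > 0:
        panel_f1, anc_f1, truth_f1 = simulate_admixture(
            founders,
            config.n_recent,
            generations=1,
            proportions=config.proportions,
            seed=seeds[5] ^ 1,
        )
        panel_f1.samples = [f"f1_{i}" for i in range(config.n_recent)]
        anc_f1.samples = list(panel_f1.samples)
        panel = HaplotypePanel.concat_animals([panel_deep, panel_f1])
        ancestry = AncestryMatrix.concat_animals([anc_deep, anc_f1])
        truth = {
            "generations": np.concatenate(
                [truth_deep["generations"], truth_f1["generations"]]
            ),
            "junctions": np.concatenate(
                [truth_deep["junctions"], truth_f1["junctions"]]
            ),
            "chromosomes": truth_deep["chromosomes"],
        }
    else:
        panel, ancestry, truth = panel_deep, anc_deep, truth_deep
    # EASZ-like indigenous reference: admixture of the two indigenous pools
    ref_panel, _, _ = simulate_admixture(
        founders,
        max(config.n_admixed // 4, 10),
        generations=config.generations,
        proportions=(0.85, 0.15, 0.0),
        seed=seeds[5],
    )
    ref_panel.samples = [f"easz_{i}" for i in range(ref_panel.n_animals)]
    return panel, ancestry, truth, ref_panel, founders, sweep_info


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a result bundle and writes all outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                info = fn() or {}
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][name] = info
            logger.info("stage %s done in %.2fs", name, info["seconds"])
            return info

        return deco

    @stage("simulate")
    def _simulate():
        panel, ancestry, truth, ref_panel, founders, sweep_info = simulate_cohort(
            config
        )
        results.update(
            panel=panel, ancestry=ancestry, truth=truth, ref_panel=ref_panel
        )
        io_mod.write_haplotype_tsv(panel, out / "haplotypes.tsv")
        io_mod.write_vcf(panel, out / "haplotypes.vcf")
        io_mod.write_ancestry_tsv(ancestry, out / "ancestry.tsv")
        io_mod.write_json(
            {
                "generations": truth["generations"],
                "sweep": None
                if sweep_info is None
                else {k: v for k, v in sweep_info.items()},
                "qtl": config.qtl,
            },
            out / "truth.json",
        )
        return {"n_animals": panel.n_animals, "n_snps": panel.n_snps}

    @stage("phenotypes")
    def _phenotypes():
        panel, ancestry = results["panel"], results["ancestry"]
        grm_all = build_grm(panel)
        results["grm_all"] = grm_all
        qtl = QtlSpec([QtlEffect(*t) for t in config.qtl])
        var = VarianceSpec(
            config.sigma_g2,
            config.sigma_pe2,
            config.sigma_e2,
            config.records_per_animal,
        )
        pheno = simulate_phenotypes(
            ancestry, panel, qtl, var, grm=grm_all.matrix, seed=config.seed + 17
        )
        results["pheno"] = pheno
        io_mod.write_phenotypes(pheno, out / "phenotypes.csv")
        return {"n_records": pheno.n_records}

    @stage("ancestry_stats")
    def _ancestry_stats():
        ancestry = results["ancestry"]
        props = anc_mod.global_proportions(ancestry)
        props.to_csv(out / "ancestry_proportions.csv", index=False)
        summary = anc_mod.crossover_summary(ancestry)
        summary.to_frame().to_csv(out / "crossovers.csv", index=False)
        retained, removed = anc_mod.filter_recent(
            summary, config.crossover_threshold
        )
        if not retained:
            raise ValueError("recency filter removed every animal")
        (out / "retained_animals.txt").write_text("\n".join(retained) + "\n")
        results.update(summary=summary, retained=retained)
        return {
            "cohort_mean": props.attrs["cohort_mean"],
            "retained": len(retained),
            "removed": len(removed),
        }

    @stage("grm_pca")
    def _grm_pca():
        grm_all = results["grm_all"]
        write_grm(grm_all, out / "grm.tsv")
        pcs, fractions = grm_pca(grm_all, k=2)
        pcs.to_csv(out / "pca.csv", index=False)
        return {"pc_variance_fractions": fractions.tolist()}

    @stage("gwa")
    def _gwa():
        scans = gwa_scan(results["pheno"], results["panel"], results["ancestry"])
        results["gwa"] = scans
        for name, df in scans.items():
            io_mod.write_scan(df, out / f"gwa_{name}.tsv")
        return {"n_tests": int(len(scans["origin"]))}

    @stage("ihs")
    def _ihs():
        panel, ref_panel = results["panel"], results["ref_panel"]
        pooled = np.concatenate([panel.haps, ref_panel.haps], axis=1)
        ancestral = polarize_alleles(pooled)
        results["ancestral"] = ancestral
        ihs = {}
        for scenario in config.scenarios:
            sub = (
                panel
                if scenario == "all"
                else panel.take_animals(results["retained"])
            )
            df = standardize_ihs(
                ihs_scan(sub, ancestral, maf=config.maf, decay=config.decay),
                bin_step=config.bin_step,
            )
            ok = df["p"].notna()
            df["q"] = np.nan
            if ok.any():
                df.loc[ok, "q"] = qvalues(df.loc[ok, "p"].to_numpy()).q
            ihs[scenario] = df
            io_mod.write_scan(df, out / f"ihs_{scenario}.tsv")
        results["ihs"] = ihs
        return {s: int(df["p"].notna().sum()) for s, df in ihs.items()}

    @stage("rsb")
    def _rsb():
        panel, ref_panel = results["panel"], results["ref_panel"]
        filtered = panel.take_animals(results["retained"])
        df = rsb_scan(filtered, ref_panel, decay=config.decay)
        ok = df["p"].notna()
        df["q"] = np.nan
        if ok.any():
            df.loc[ok, "q"] = qvalues(df.loc[ok, "p"].to_numpy()).q
        results["rsb"] = df
        io_mod.write_scan(df, out / "rsb.tsv")
        return {"n_tests": int(ok.sum())}

    @stage("regions")
    def _regions():
        scenario = "filtered" if "filtered" in config.scenarios else "all"
        ihs_regions = call_sos_regions(
            results["ihs"][scenario],
            seed_q=config.seed_q,
            suggestive_q=config.suggestive_q_ihs,
            window=config.region_window,
            source="ihs",
        )
        rsb_regions = call_sos_regions(
            results["rsb"],
            seed_q=config.seed_q,
            suggestive_q=config.suggestive_q_rsb,
            window=config.region_window,
            source="rsb",
        )
        gwa_regions = call_gwa_regions(
            results["gwa"]["allele"],
            p_thresh=config.gwa_p_thresh,
            window=config.region_window,
            source="gwa_allele",
        )
        for regs in (ihs_regions, rsb_regions):
            for r in regs:
                r.dominant_ancestry = anc_mod.region_dominant_ancestry(
                    results["ancestry"], r.chrom, r.start, r.end, results["retained"]
                )
        results.update(
            ihs_regions=ihs_regions,
            rsb_regions=rsb_regions,
            gwa_regions=gwa_regions,
        )
        regions_to_frame(ihs_regions + rsb_regions + gwa_regions).to_csv(
            out / "regions.tsv", sep="\t", index=False
        )
        thresholds = {}
        for name, df in (
            ("ihs", results["ihs"][scenario]),
            ("rsb", results["rsb"]),
        ):
            ok = df["p"].notna()
            if ok.any():
                qs = qvalues(df.loc[ok, "p"].to_numpy())
                line = fdr_threshold_line(qs, 0.1)
                thresholds[name] = line
        io_mod.write_json(thresholds, out / "fdr_thresholds.json")
        return {
            "ihs_regions": len(ihs_regions),
            "rsb_regions": len(rsb_regions),
            "gwa_regions": len(gwa_regions),
        }

    @stage("overlap")
    def _overlap():
        sos = results["ihs_regions"] + results["rsb_regions"]
        ov = intersect_regions(results["gwa_regions"], sos)
        ov.to_csv(out / "overlap.tsv", sep="\t", index=False)
        return {"n_overlaps": int(len(ov))}

    io_mod.write_json(manifest, out / "manifest.json")
    config.to_yaml(out / "config.yaml")
    results["manifest"] = manifest
    return results
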
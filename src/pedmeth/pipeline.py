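"""Study loading and end-to-end pipeline orchestration.

``load_study`` harmonizes the genotype, pedigree, methylation and optional
fragment/annotation inputs into one object; ``run_pipeline`` executes
QC -> MPO / mQTL / ASM / VMR -> cross-method comparison and writes every
stage's table, stamped with the configuration hash and seeds, so identical
inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import asm as asm_mod
from . import compare as compare_mod
from . import io as pio
from . import mpo as mpo_mod
from . import mqtl as mqtl_mod
from . import preprocess
from . import vmr as vmr_mod
from .config import AnalysisConfig
from .containers import (AllelicFragmentSet, GenotypeMatrix, MethylationMatrix,
                         PedigreeSet)

log = logging.getLogger(__name__)

OUTPUT_FILES = ("qc_report.tsv", "mpo_results.tsv", "mqtl_results.tsv",
                "asm_merged.tsv", "vmr.tsv", "vmr_clusters.tsv",
                "comparison.tsv")


@dataclass
class Study:
    pedigree: PedigreeSet
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    fragments: AllelicFragmentSet | None = None
    regions: pd.DataFrame | None = None


def load_study(vcf_path, fam_path, meth_path, frags_path=None,
               bed_path=None) -> Study:
    """Load and harmonize the study inputs.

    Samples are ordered as in the methylation matrix, restricted to those
    also present in the genotypes; zero overlap is fatal. Pedigree
    validation (parents present, families consistent) happens on load.
    """
    pedigree = pio.read_fam(fam_path)
    genotypes = pio.read_vcf(vcf_path)
    meth = pio.read_methylation_tsv(meth_path)

    shared = [s for s in meth.samples if s in set(genotypes.samples)]
    if not shared:
        raise ValueError("no samples shared between methylation and genotype "
                         "inputs")
    if len(shared) < len(meth.samples):
        log.warning("dropping %d methylation samples absent from genotypes",
                    len(meth.samples) - len(shared))
    meth = meth.subset_samples(shared)
    genotypes = genotypes.subset_samples(shared)

    frags = pio.read_fragments_tsv(frags_path) if frags_path else None
    regions = pio.read_bed(bed_path) if bed_path else None
    log.info("study loaded: %d samples, %d SNPs, %d CpGs, %d trios",
             len(shared), genotypes.n_snps, meth.n_sites,
             len(pedigree.trios()))
    return Study(pedigree, genotypes, meth, frags, regions)


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"vcf": out / "genotypes.vcf", "fam": out / "pedigree.fam",
             "meth": out / "methylation.tsv"}
    pio.write_vcf(study.genotypes, paths["vcf"])
    pio.write_fam(study.pedigree, paths["fam"])
    pio.write_methylation_tsv(study.methylation, paths["meth"])
    if study.fragments is not None:
        paths["frags"] = out / "fragments.tsv"
        pio.write_fragments_tsv(study.fragments, paths["frags"])
    return paths


def _stage_seed(base: int, stage: str) -> int:
    offsets = {"mqtl": 1, "vmr": 2, "vmr_calib": 3}
    return (int(base) * 8 + offsets[stage]) % (2**31 - 1)


def run_pipeline(study: Study, config: AnalysisConfig,
                 out_dir: str | Path) -> dict:
    """Run every stage in dependency order and write the result bundle.

    Returns a dict of in-memory results; writes the tables listed in
    ``OUTPUT_FILES`` plus ``summary.json`` under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def _stage(name):
        log.info("pipeline stage: %s", name)

    _stage("qc")
    meth, qc_report = preprocess.qc_pipeline(study.methylation, config)
    results["qc_report"] = qc_report

    trios = study.pedigree.trios()
    fam_of = study.pedigree.family_of()

    _stage("snp_qc")
    genotypes, mendel_report = mqtl_mod.snp_qc(
        study.genotypes, trios, maf_min=config.maf_min,
        hwe_min_p=config.hwe_min_p, family_of=fam_of,
        founders=study.pedigree.founders())
    results["mendel_report"] = mendel_report

    _stage("mpo")
    mpo_results, mpo_clusters = mpo_mod.run_mpo(
        meth, trios, genotypes, h2_min=config.h2_min,
        min_trios=config.min_trios, fdr=config.fdr)
    results["mpo"] = mpo_results
    results["mpo_clusters"] = mpo_clusters

    _stage("mqtl")
    mqtl_results = mqtl_mod.mqtl_scan(
        meth, genotypes, study.pedigree, window=config.window,
        n_perm=config.n_perm, seed=_stage_seed(config.seed, "mqtl"))
    results["mqtl"] = mqtl_results

    _stage("asm")
    if study.fragments is not None and len(study.fragments):
        asm_events = asm_mod.call_asm(
            study.fragments, p_max=config.asm_p_max,
            delta_min=config.asm_delta_min,
            min_per_allele=config.asm_min_per_allele, genotypes=genotypes)
    else:
        asm_events = asm_mod.call_asm(
            AllelicFragmentSet(pd.DataFrame(
                columns=AllelicFragmentSet.REQUIRED)))
    asm_merged = asm_mod.merge_asm_events(asm_events)
    results["asm_events"] = asm_events
    results["asm_merged"] = asm_merged

    _stage("vmr")
    if config.vmr_t_min is not None:
        t_min = float(config.vmr_t_min)
    else:
        t_min = vmr_mod.choose_t_min_by_fpr(
            meth, genotypes, fpr_target=config.vmr_fpr_target,
            min_cpgs=config.vmr_min_cpgs, max_spacing=config.vmr_max_spacing,
            window=config.window, min_group_n=config.vmr_min_group_n,
            seed=_stage_seed(config.seed, "vmr_calib"))
    scores = vmr_mod.variance_scan(meth, genotypes, window=config.window,
                                   min_group_n=config.vmr_min_group_n)
    vmrs = vmr_mod.call_vmrs(scores, t_min, min_cpgs=config.vmr_min_cpgs,
                             max_spacing=config.vmr_max_spacing)
    fpr = vmr_mod.estimate_fpr_by_permutation(
        meth, genotypes, t_min, min_cpgs=config.vmr_min_cpgs,
        max_spacing=config.vmr_max_spacing, window=config.window,
        min_group_n=config.vmr_min_group_n,
        seed=_stage_seed(config.seed, "vmr"))
    clusters = vmr_mod.cluster_vmrs(vmrs,
                                    max_distance=config.vmr_cluster_distance)
    results["vmr"] = vmrs
    results["vmr_clusters"] = clusters
    results["vmr_t_min"] = t_min
    results["vmr_fpr"] = fpr

    _stage("compare")
    comparison = compare_mod.comparison_report(mpo_results, mqtl_results,
                                               asm_merged, fdr=config.fdr)
    results["comparison"] = comparison

    # ------------------------------------------------------------- outputs
    stamp = f"# config_hash={config.hash()} seed={config.seed}\n"

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with path.open("w") as fh:
            fh.write(stamp)
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    _write(qc_report, "qc_report.tsv")
    _write(mpo_results, "mpo_results.tsv")
    _write(mqtl_results, "mqtl_results.tsv")
    _write(asm_merged, "asm_merged.tsv")
    _write(vmrs, "vmr.tsv")
    _write(clusters, "vmr_clusters.tsv")
    _write(comparison, "comparison.tsv")
    if len(mpo_clusters):
        pio.write_bed(mpo_clusters.assign(start0=mpo_clusters["start"] - 1),
                      out / "mpo_clusters.bed",
                      cols=("chrom", "start0", "end"))
    if len(clusters):
        pio.write_bed(clusters.assign(start0=clusters["start"] - 1),
                      out / "vmr_clusters.bed",
                      cols=("chrom", "start0", "end"))

    summary = {
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "n_samples": study.methylation.n_samples,
        "n_cpgs_input": study.methylation.n_sites,
        "n_cpgs_analyzed": meth.n_sites,
        "n_snps_input": study.genotypes.n_snps,
        "n_snps_analyzed": genotypes.n_snps,
        "n_trios": len(trios),
        "n_heritable": int(mpo_results["heritable"].sum()),
        "n_mqtl_pairs": len(mqtl_results),
        "n_mqtl_significant": int((mqtl_results["q"] < config.fdr).sum())
        if len(mqtl_results) else 0,
        "n_asm_events": len(asm_events),
        "n_asm_merged": len(asm_merged),
        "vmr_t_min": t_min,
        "n_vmrs": len(vmrs),
        "n_vmr_clusters": len(clusters),
        "vmr_fpr": None if np.isnan(fpr.fpr) else fpr.fpr,
        "mendel_errors_total": int(mendel_report["n_errors"].sum())
        if len(mendel_report) else 0,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    results["summary"] = summary
    return results
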
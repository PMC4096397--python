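"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (GT field, biallelic SNVs only; 1-based positions),
pedigrees as PLINK FAM, methylation as a wide TSV (chrom, pos, strand, then
one fraction and one depth column per sample; missing = NA), allele-tagged
fragments as a long TSV, region annotation as BED (0-based half-open), and
simulation ground truth as a JSON sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (AllelicFragmentSet, GenotypeMatrix, MethylationMatrix,
                         PedigreeSet)
from .synthetic import CohortTruth

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- genotypes

def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in range(g.n_snps):
            row = g.snps.iloc[i]
            gts = "\t".join(gt_of.get(d, "./.") for d in g.dosages[i])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}"
                     f"\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF; multi-allelic records are skipped
    with a warning."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("skipping multi-allelic record at %s:%d",
                        var.CHROM, var.POS)
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        d = np.array([{0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}[t]
                      for t in var.gt_types])
        snps.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0]))
        rows.append(d)
    vcf.close()
    snps_df = pd.DataFrame(snps, columns=["id", "chrom", "pos", "ref", "alt"])
    dosages = np.array(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(snps_df, samples, dosages)


# ----------------------------------------------------------------- pedigree

def write_fam(ped: PedigreeSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for _, r in ped.samples.iterrows():
            father = r["father_id"] if pd.notna(r["father_id"]) else "0"
            mother = r["mother_id"] if pd.notna(r["mother_id"]) else "0"
            fh.write(f"{r['family_id']}\t{r['sample_id']}\t{father}\t{mother}"
                     f"\t{r['sex']}\t-9\n")


def read_fam(path: str | Path) -> PedigreeSet:
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["family_id", "sample_id", "father_id",
                            "mother_id", "sex", "phenotype"],
                     dtype=str)
    df["father_id"] = df["father_id"].replace("0", None)
    df["mother_id"] = df["mother_id"].replace("0", None)
    df["sex"] = df["sex"].astype(int)
    return PedigreeSet(df[["sample_id", "family_id", "father_id",
                           "mother_id", "sex"]])


# -------------------------------------------------------------- methylation

def write_methylation_tsv(m: MethylationMatrix, path: str | Path) -> None:
    cols = {"chrom": m.sites["chrom"], "pos": m.sites["pos"],
            "strand": m.sites["strand"]}
    for j, s in enumerate(m.samples):
        cols[f"{s}.frac"] = [f"{v:.6g}" if not np.isnan(v) else "NA"
                             for v in m.values[:, j]]
        cols[f"{s}.depth"] = m.depths[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | Path) -> MethylationMatrix:
    """Read the wide methylation TSV.

    Rows with out-of-range fractions or negative depths are rejected with a
    logged warning naming the 1-based file line; parsing continues.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    fixed = ["chrom", "pos", "strand"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"methylation TSV missing columns: {missing}")
    samples = [c[:-5] for c in df.columns if c.endswith(".frac")]
    for s in samples:
        if f"{s}.depth" not in df.columns:
            raise ValueError(f"sample {s} has a fraction column but no depth")
    frac = df[[f"{s}.frac" for s in samples]].to_numpy(dtype=float)
    depth = df[[f"{s}.depth" for s in samples]].to_numpy()
    with np.errstate(invalid="ignore"):
        bad_frac = ((frac < 0) | (frac > 1)).any(axis=1)  # NaN compares False
    bad = bad_frac | (depth < 0).any(axis=1)
    if bad.any():
        for i in np.flatnonzero(bad):
            log.warning("rejecting methylation record at line %d "
                        "(fraction outside [0, 1] or negative depth)", i + 2)
        df, frac, depth = df.loc[~bad], frac[~bad], depth[~bad]
    sites = df[fixed].reset_index(drop=True)
    return MethylationMatrix(sites, samples, frac, depth.astype(int))


# ---------------------------------------------------------------- fragments

def write_fragments_tsv(frags: AllelicFragmentSet, path: str | Path) -> None:
    out = frags.records.copy()
    out["methylated"] = out["methylated"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> AllelicFragmentSet:
    df = pd.read_csv(path, sep="\t",
                     dtype={"sample_id": str, "snp_id": str, "chrom": str})
    df["methylated"] = df["methylated"].astype(bool)
    df["cpg_pos"] = df["cpg_pos"].astype(int)
    return AllelicFragmentSet(df)


# ---------------------------------------------------------------------- BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """BED with a 4th name column used as the region label."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chrom", "start", "end", "label"],
                     dtype={"chrom": str, "label": str})
    return df


def write_bed(df: pd.DataFrame, path: str | Path,
              cols: tuple = ("chrom", "start", "end")) -> None:
    out = df.loc[:, list(cols)].copy()
    out.to_csv(path, sep="\t", index=False, header=False)


# -------------------------------------------------------------------- truth

def write_truth_json(truth: CohortTruth, path: str | Path) -> None:
    payload = {
        "cpg_class": truth.cpg_class.to_dict(orient="list"),
        "snp_cpg_pairs": [list(x) for x in truth.snp_cpg_pairs],
        "cis_pairs": [list(x) for x in truth.cis_pairs],
        "vsnp_blocks": truth.vsnp_blocks,
        "family_noise_positions": truth.family_noise_positions,
        "baseline": [float(b) for b in truth.baseline],
        "allele_meth_probs": {f"{k[0]}|{k[1]}": list(v)
                              for k, v in truth.allele_meth_probs.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path: str | Path) -> CohortTruth:
    d = json.loads(Path(path).read_text())
    probs = {}
    for key, v in d["allele_meth_probs"].items():
        snp, pos = key.split("|")
        probs[(snp, int(pos))] = tuple(v)
    return CohortTruth(
        cpg_class=pd.DataFrame(d["cpg_class"]),
        snp_cpg_pairs=[(s, int(p)) for s, p in d["snp_cpg_pairs"]],
        cis_pairs=[(s, int(p), float(b)) for s, p, b in d["cis_pairs"]],
        vsnp_blocks=d["vsnp_blocks"],
        family_noise_positions=[int(p) for p in d["family_noise_positions"]],
        baseline=np.array(d["baseline"]),
        allele_meth_probs=probs,
    )
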
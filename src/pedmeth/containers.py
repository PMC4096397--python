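"""Core in-memory containers shared by all analysis stages.

Coordinates are 1-based (the C of the CpG dinucleotide on the forward
strand; VCF-style SNP positions). Methylation values are fractions in
[0, 1]; missing cells are NaN. Genotypes are additive alt-allele dosages
in {0, 1, 2} with NaN for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "strand"]
SNP_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


@dataclass
class MethylationMatrix:
    """CpG sites x samples methylation fractions with per-cell read depth.

    ``sites`` has columns chrom, pos (1-based C of the CG dinucleotide,
    forward strand) and strand (strand of capture). ``values`` is
    (n_sites, n_samples) float with NaN for missing; ``depths`` the
    matching integer read depths.
    """

    sites: pd.DataFrame
    samples: list[str]
    values: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        self.depths = np.asarray(self.depths)
        n_sites, n_samples = len(self.sites), len(self.samples)
        if self.values.shape != (n_sites, n_samples):
            raise ValueError(
                f"values shape {self.values.shape} != ({n_sites}, {n_samples})")
        if self.depths.shape != self.values.shape:
            raise ValueError("depths shape must match values")
        if len(set(self.samples)) != n_samples:
            raise ValueError("duplicate sample ids")
        present = ~np.isnan(self.values)
        if present.any():
            v = self.values[present]
            if (v < 0).any() or (v > 1).any():
                raise ValueError("methylation fractions must be in [0, 1]")
        if n_sites and (self.sites["pos"] < 1).any():
            raise ValueError("positions are 1-based, must be >= 1")
        # strictly sorted within chromosome
        for _, grp in self.sites.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError("site positions must be strictly sorted "
                                 "within each chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_keys(self) -> pd.Index:
        return pd.MultiIndex.from_frame(self.sites[["chrom", "pos"]])

    def subset_sites(self, mask: np.ndarray) -> "MethylationMatrix":
        mask = np.asarray(mask)
        return MethylationMatrix(self.sites.loc[mask].reset_index(drop=True),
                                 list(self.samples),
                                 self.values[mask], self.depths[mask])

    def subset_samples(self, sample_ids: list[str]) -> "MethylationMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return MethylationMatrix(self.sites.copy(), list(sample_ids),
                                 self.values[:, idx], self.depths[:, idx])


@dataclass
class GenotypeMatrix:
    """Biallelic SNPs x samples alt-allele dosages (0/1/2, NaN missing)."""

    snps: pd.DataFrame
    samples: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n_snps, n_samples = len(self.snps), len(self.samples)
        if self.dosages.shape != (n_snps, n_samples):
            raise ValueError(
                f"dosages shape {self.dosages.shape} != ({n_snps}, {n_samples})")
        if len(set(self.samples)) != n_samples:
            raise ValueError("duplicate sample ids")
        present = ~np.isnan(self.dosages)
        if present.any() and not np.isin(self.dosages[present], (0., 1., 2.)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for _, grp in self.snps.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if len(p) > 1 and (np.diff(p) < 0).any():
                raise ValueError("SNP positions must be sorted within chromosome")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(self.snps.loc[mask].reset_index(drop=True),
                              list(self.samples), self.dosages[mask])

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(self.snps.copy(), list(sample_ids),
                              self.dosages[:, idx])

    def polymorphic_positions(self) -> set[tuple[str, int]]:
        """(chrom, pos) of SNPs with at least two observed genotype states."""
        out = set()
        for i in range(self.n_snps):
            d = self.dosages[i]
            d = d[~np.isnan(d)]
            if len(np.unique(d)) >= 2 or (len(d) and d[0] == 1):
                out.add((self.snps.at[i, "chrom"], int(self.snps.at[i, "pos"])))
        return out


@dataclass
class PedigreeSet:
    """Nuclear-pedigree sample table (PLINK FAM semantics).

    ``samples`` has columns sample_id, family_id, father_id, mother_id, sex;
    founder parents carry father_id/mother_id None.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id: {dup}")
        by_id = self.samples.set_index("sample_id")
        for _, row in self.samples.iterrows():
            for parent in (row["father_id"], row["mother_id"]):
                if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                    continue
                if parent not in by_id.index:
                    raise ValueError(
                        f"sample {row['sample_id']} references absent parent {parent}")
                if by_id.at[parent, "family_id"] != row["family_id"]:
                    raise ValueError(
                        f"parent {parent} of {row['sample_id']} is in a "
                        "different family")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def founders(self) -> list[str]:
        mask = self.samples["father_id"].isna() & self.samples["mother_id"].isna()
        return list(self.samples.loc[mask, "sample_id"])

    def families(self) -> dict[str, list[str]]:
        return {fam: list(grp["sample_id"])
                for fam, grp in self.samples.groupby("family_id", sort=False)}

    def trios(self) -> "TrioSet":
        """All (father, mother, child) triplets; two children of the same
        parents yield two trios."""
        trios = []
        for _, row in self.samples.iterrows():
            f, m = row["father_id"], row["mother_id"]
            if pd.notna(f) and pd.notna(m):
                trios.append((f, m, row["sample_id"]))
        return TrioSet(trios)

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.samples["sample_id"], self.samples["family_id"]))


@dataclass
class TrioSet:
    """(father_id, mother_id, child_id) triplets — the MPO unit of analysis."""

    trios: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for f, m, c in self.trios:
            if len({f, m, c}) != 3:
                raise ValueError(f"trio ids must be distinct: {(f, m, c)}")

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)


@dataclass
class AllelicFragmentSet:
    """Read-fragment records pairing an allele call at a heterozygous SNP
    with a methylation call at a CpG on the same fragment.

    ``records`` columns: sample_id, snp_id, chrom, cpg_pos, allele
    ("ref"/"alt"), methylated (bool).
    """

    records: pd.DataFrame

    REQUIRED = ["sample_id", "snp_id", "chrom", "cpg_pos", "allele", "methylated"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"fragment records missing columns: {missing}")
        if len(self.records):
            bad = ~self.records["allele"].isin(["ref", "alt"])
            if bad.any():
                raise ValueError("allele must be 'ref' or 'alt'")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)
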
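#!/usr/bin/env python
"""Site-level QC of the simulated methylome.

Masks cells below 10x depth, drops CpGs measured in fewer than 80% of
samples, restricts to autosomes, and keeps variable CpGs (SD >= 0.1),
mirroring the filters a targeted-bisulfite family study applies before any
genetic analysis. Writes the filtered matrix and the QC report.
"""

from pathlib import Path

from pedmeth import io as pio
from pedmeth.config import AnalysisConfig
from pedmeth.preprocess import qc_pipeline, site_sd

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results"


def main() -> None:
    meth = pio.read_methylation_tsv(COHORT / "methylation.tsv")
    config = AnalysisConfig()
    filtered, report = qc_pipeline(meth, config)

    OUT.mkdir(parents=True, exist_ok=True)
    report.to_csv(OUT / "qc_report.tsv", sep="\t", index=False)
    pio.write_methylation_tsv(filtered, OUT / "methylation_filtered.tsv")

    print(report.to_string(index=False))
    sd = site_sd(filtered)
    n_highly = int((sd >= config.sd_highly_variable).sum())
    print(f"retained {filtered.n_sites}/{meth.n_sites} CpGs as variable "
          f"(SD >= {config.sd_variable}); {n_highly} highly variable "
          f"(SD >= {config.sd_highly_variable})")


if __name__ == "__main__":
    main()
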
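"""Recurrent amplification/deletion regions across the simulated cohort.

Thresholds every patient's smoothed Z-profile at +/-2, scores per-bin
recurrence (amplitude-weighted frequency), assigns significance by
cyclic-shift permutation FDR (q < 0.25), and reports the called regions.
Also tabulates the bundled hg19 census: curated pancreatic-cancer genes
overlapped with the bundled recurrent-region coordinates.
Writes results/recurrent_regions.tsv and results/curated_gene_census.tsv.
"""

from pathlib import Path

import pandas as pd

from cfgi import pipeline
from cfgi.bins import read_counts_table
from cfgi.recurrence import (
    call_aberrations,
    gene_overlap,
    load_curated_genes,
    load_recurrent_regions,
    region_significance,
    regions_table,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main():
    bins = pd.read_csv(SIM / "bins.tsv", sep="\t")
    controls = read_counts_table(SIM / "controls.tsv", bins)
    cohort = read_counts_table(SIM / "cohort.tsv", bins)
    panel = pipeline.control_panel(controls, bins)

    smoothed = [pipeline.sample_zprofile(s, bins, panel)[1] for s in cohort]
    calls, amps = call_aberrations(smoothed, bins)
    regions = region_significance(calls, amps, bins, n_perm=500, seed=7)
    tab = regions_table(regions)
    tab.to_csv(RESULTS / "recurrent_regions.tsv", sep="\t", index=False)
    print(f"{len(tab)} recurrent regions at q < 0.25 "
          f"({(tab['type'] == 'amp').sum()} amp, {(tab['type'] == 'del').sum()} del)")
    if len(tab):
        print(tab.to_string(index=False))

    census = gene_overlap(load_recurrent_regions(), load_curated_genes())
    census.to_csv(RESULTS / "curated_gene_census.tsv", sep="\t", index=False)
    amp = census[census.region_type == "amp"]
    dele = census[census.region_type == "del"]
    print(f"\nhg19 census: {(amp.curated_type == 'OCG').sum()} oncogenes and "
          f"{(amp.curated_type == 'PPA').sum()} poor-prognosis genes in "
          f"amplification regions; {(dele.curated_type == 'TSG').sum()} tumor "
          f"suppressors and {(dele.curated_type == 'OCG').sum()} oncogene in "
          f"the deletion region")


if __name__ == "__main__":
    main()
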
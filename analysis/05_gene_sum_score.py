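"""Gene sum score: gene-level scoring, CV selection, and application.

Places synthetic gene intervals inside the recurrent regions called in
step 04 (plus null genes elsewhere), scores each patient's genes 0/1
from length-weighted gene-level Z, selects prognostic genes by five-fold
cross-validated log-rank ranking, and applies the union-set gene sum
score back to the cohort.  Writes results/gss_model.json and
results/gss.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cfgi import pipeline
from cfgi.bins import read_counts_table
from cfgi.gss import cv_select, gene_z, gss_apply, score_genes

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def synthetic_genes(regions: pd.DataFrame, bins: pd.DataFrame, rng) -> pd.DataFrame:
    """Three 1-Mb genes inside each called region, plus ten null genes."""
    rows = []
    for ri, (_, reg) in enumerate(regions.iterrows()):
        for j in range(3):
            start = int(rng.integers(reg["start"], max(reg["start"] + 1, reg["end"] - 10**6)))
            rows.append({"symbol": f"R{ri}_{reg['chrom']}_{reg['type']}{j}",
                         "chrom": reg["chrom"], "start": start,
                         "end": start + 10**6 - 1, "region_type": reg["type"]})
    covered = set(regions["chrom"])
    spare = [c for c in bins["chrom"].unique() if c not in covered] or ["chr1"]
    for j in range(10):
        chrom = spare[j % len(spare)]
        cmax = bins.loc[bins.chrom == chrom, "end"].max()
        start = int(rng.integers(1, cmax - 10**6))
        rows.append({"symbol": f"null{j}", "chrom": chrom, "start": start,
                     "end": start + 10**6 - 1,
                     "region_type": "amp" if j % 2 else "del"})
    return pd.DataFrame(rows)


def main():
    bins = pd.read_csv(SIM / "bins.tsv", sep="\t")
    regions = pd.read_csv(RESULTS / "recurrent_regions.tsv", sep="\t")
    clin = pd.read_csv(SIM / "cohort_clinical.tsv", sep="\t")
    controls = read_counts_table(SIM / "controls.tsv", bins)
    cohort = read_counts_table(SIM / "cohort.tsv", bins)
    panel = pipeline.control_panel(controls, bins)
    rng = np.random.default_rng(55)

    genes = synthetic_genes(regions, bins, rng)
    gz_rows = {}
    for s in cohort:
        _, sm = pipeline.sample_zprofile(s, bins, panel)
        gz_rows[s.sample_id] = gene_z(sm, genes, bins)
    gz = pd.DataFrame(gz_rows).T.loc[clin["id"]]
    scores = score_genes(gz, genes.set_index("symbol")["region_type"])

    model = cv_select(scores, clin["os_time"].to_numpy(),
                      clin["os_event"].to_numpy(), k=5, seed=11)
    applied = gss_apply(scores, model.union_genes,
                        cutoff=int(np.median([f["cutoff"] for f in model.folds])))
    applied.insert(0, "id", clin["id"].to_numpy())
    applied.to_csv(RESULTS / "gss.tsv", sep="\t", index=False)
    with open(RESULTS / "gss_model.json", "w") as fh:
        json.dump({"seed": model.seed,
                   "folds": model.folds,
                   "overlap_genes": model.overlap_genes,
                   "union_genes": model.union_genes}, fh, indent=2)

    print(f"{len(genes)} gene intervals ({len(genes) - 10} in called regions, 10 null)")
    for f in model.folds:
        print(f"  fold {f['fold']}: top_n={f['top_n']} cutoff={f['cutoff']} "
              f"test log-rank p={f['test_p']:.3g}")
    print(f"overlap set: {len(model.overlap_genes)} genes; "
          f"union set: {len(model.union_genes)} genes")
    n_null_selected = sum(g.startswith('null') for g in model.union_genes)
    print(f"null genes in the union set: {n_null_selected}/10")


if __name__ == "__main__":
    main()
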
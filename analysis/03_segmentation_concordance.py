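"""Plasma-vs-tissue copy-number concordance at segment resolution.

For each matched pair: segment the tissue Z-profile (the baseline),
average the plasma Z over the bins of each baseline segment, and report
the Pearson correlation between the two segment-level vectors.
Writes results/concordance.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cfgi import pipeline
from cfgi.bins import read_counts_table
from cfgi.segmentation import concordance, project_segments, segment

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main():
    bins = pd.read_csv(SIM / "bins.tsv", sep="\t")
    controls = read_counts_table(SIM / "controls.tsv", bins)
    pairs = read_counts_table(SIM / "pairs.tsv", bins)
    panel = pipeline.control_panel(controls, bins)

    by_id = {s.sample_id: s for s in pairs}
    rows = []
    for i in range(1, 11):
        plasma = by_id[f"PAIR{i:02d}_plasma"]
        tissue = by_id[f"PAIR{i:02d}_tissue"]
        zp, _ = pipeline.sample_zprofile(plasma, bins, panel)
        zt, _ = pipeline.sample_zprofile(tissue, bins, panel)
        segs = segment(zt, bins, n_perm=500, seed=i)
        proj, kept = project_segments(zp, bins, segs)
        res = concordance(proj, np.array([s.mean_z for s in kept]))
        rows.append({"pair": i, "n_segments": res.n_segments,
                     "r": res.r, "r_squared": res.r_squared})
    tab = pd.DataFrame(rows)
    tab.to_csv(RESULTS / "concordance.tsv", sep="\t", index=False)
    print(tab.to_string(index=False))
    print(f"\nmedian segment-resolution r^2 across pairs: "
          f"{tab['r_squared'].median():.2f} "
          f"(plasma at tumor fraction 0.3 vs undiluted tissue)")


if __name__ == "__main__":
    main()
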
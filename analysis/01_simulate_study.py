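"""Simulate the full study's inputs on a scaled-down genome.

Generates, under scratch/sim/ (bulky intermediates) and results/
(small summaries):

* a 6-chromosome x 40 Mb genome tiled into 240 one-megabase bins with a
  synthetic GC track;
* 38 healthy-control count profiles (GC-biased negative-binomial counts);
* a 100-patient plasma cohort - 30 patients carry planted copy-number
  segments at tumor fractions 0.2-0.5 (high burden), 70 carry little or
  nothing (fractions 0-0.05) - with exponential survival times whose
  hazard triples in the high-burden group;
* 10 matched plasma/tissue pairs sharing segments (plasma diluted to
  tumor fraction 0.3, tissue undiluted).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import cfgi
from cfgi import simulate as sim
from cfgi.bins import write_counts_table

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"
READS = 500_000
SEED = 20260926


def main():
    SIM.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    bins = sim.synthetic_gc(cfgi.build_bins(sim.toy_chromosomes(6, 40_000_000)), seed=1)
    bins.to_csv(SIM / "bins.tsv", sep="\t", index=False)

    controls = sim.simulate_controls(bins, n_controls=38, reads_per_sample=READS,
                                     seed=int(rng.integers(2**31)))
    write_counts_table(SIM / "controls.tsv", controls, bins)

    # plasma cohort with planted burden and burden-linked survival; the
    # high-burden group shares recurrent driver segments (carried with
    # probability 0.7 each) plus private passenger segments
    drivers = [sim.CNASegment("chr1", 8, 18, 5.0),
               sim.CNASegment("chr2", 25, 34, 0.5),
               sim.CNASegment("chr5", 12, 22, 4.0)]
    passenger_chroms = ["chr3", "chr4", "chr6"]
    samples, clin_rows = [], []
    for i in range(100):
        high = i < 30
        f = rng.uniform(0.2, 0.5) if high else rng.uniform(0.0, 0.05)
        segs = []
        if high:
            segs += [d for d in drivers if rng.random() < 0.7]
            n_pass = int(rng.integers(0, 3))
        else:
            n_pass = int(rng.integers(0, 2))
        for chrom in rng.choice(passenger_chroms, size=n_pass, replace=False):
            n = int((bins["chrom"] == chrom).sum())
            width = int(rng.integers(5, 15))
            start = int(rng.integers(0, n - width))
            segs.append(sim.CNASegment(chrom, start, start + width - 1,
                                       float(rng.choice([0, 1, 4, 5]))))
        n_seg = len(segs)
        s = sim.simulate_tumor(bins, segs, f, sample_id=f"PT{i + 1:03d}",
                               reads_per_sample=READS, seed=int(rng.integers(2**31)))
        samples.append(s)
        lam = 0.06 * (3.0 if high else 1.0)
        t = rng.exponential(1 / lam)
        c = rng.uniform(0, 40)
        clin_rows.append({
            "id": s.sample_id, "true_group": "high" if high else "low",
            "tumor_fraction": round(f, 3), "n_segments": int(n_seg),
            "os_time": round(min(t, c), 2), "os_event": int(t <= c),
        })
    write_counts_table(SIM / "cohort.tsv", samples, bins)
    clin = pd.DataFrame(clin_rows)
    clin.to_csv(SIM / "cohort_clinical.tsv", sep="\t", index=False)

    # matched plasma/tissue pairs
    pair_samples = []
    for i in range(10):
        segs = sim.random_cna_segments(bins, 3, rng)
        plasma, tissue = sim.simulate_tumor_pair(bins, segs, 0.3,
                                                 reads_per_sample=READS,
                                                 seed=int(rng.integers(2**31)))
        plasma.sample_id = f"PAIR{i + 1:02d}_plasma"
        tissue.sample_id = f"PAIR{i + 1:02d}_tissue"
        pair_samples += [plasma, tissue]
    write_counts_table(SIM / "pairs.tsv", pair_samples, bins)

    # full-size clinical cohort for the survival layer
    cohort315 = sim.simulate_cohort(seed=SEED % 2**31)
    cohort315.to_csv(SIM / "clinical_315.tsv", sep="\t", index=False)

    manifest = {
        "seed": SEED, "reads_per_sample": READS, "n_bins": len(bins),
        "n_controls": 38, "cohort_n": 100, "cohort_high": 30, "n_pairs": 10,
        "clinical_n": len(cohort315),
    }
    with open(RESULTS / "sim_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    print(f"wrote {manifest['n_bins']} bins, 38 controls, 100 cohort profiles, "
          f"10 matched pairs, and a {len(cohort315)}-patient clinical table")
    print(f"high-burden patients: 30/100, median tumor fraction "
          f"{clin.loc[clin.true_group == 'high', 'tumor_fraction'].median():.2f}")


if __name__ == "__main__":
    main()
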
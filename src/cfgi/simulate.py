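"""Synthetic low-pass cfDNA data with known ground truth.

Generates everything the pipeline consumes, with all randomness flowing
from an explicit seed:

* control bin-count profiles — negative-binomial counts around a smooth
  GC-dependent expectation (Gamma-Poisson mixture, dispersion 0.02 by
  default, matching the overdispersion of low-pass WGS bin counts), at
  3.1 million reads per sample and 38 controls by default;
* tumor profiles — planted copy-number segments scale the expected bin
  count by ``1 + f*(c - 2)/2`` for tumor fraction ``f`` and segment copy
  number ``c`` (tissue is the ``f = 1`` limit), renormalized so the
  expected total depth is unchanged;
* clinical cohorts — exponential progression/death times with a
  prescribed group hazard ratio for each endpoint, uniform independent
  censoring calibrated to a target censoring fraction, stages and serum
  markers with instability-group-dependent distributions.

The joint PFS/OS construction keeps both marginals exactly proportional
hazards (PFS = min of progression and death, with the progression rate
in the high group solved so the marginal PFS hazard ratio equals the
requested value) and guarantees PFS <= OS per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .bins import BinnedCounts, build_bins


def toy_chromosomes(n_chroms: int = 6, length: int = 40_000_000) -> pd.DataFrame:
    """Small chromosome table for scaled-down simulated genomes."""
    return pd.DataFrame(
        {"chrom": [f"chr{i + 1}" for i in range(n_chroms)], "length": length}
    )


def synthetic_gc(bins: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Fill the gc column with a smooth synthetic per-bin GC track.

    Synthetic stand-in for genome-derived GC content: a slow sinusoid
    along each chromosome plus bin-level jitter, clipped to [0.30, 0.60].
    """
    rng = np.random.default_rng(seed)
    out = bins.copy()
    gc = np.empty(len(bins))
    for _, grp in bins.groupby("chrom", sort=False):
        n = len(grp)
        phase = rng.uniform(0, 2 * np.pi)
        base = 0.42 + 0.07 * np.sin(2 * np.pi * 2 * np.arange(n) / max(n, 1) + phase)
        gc[grp.index.to_numpy()] = base + rng.normal(0, 0.012, size=n)
    out["gc"] = np.clip(gc, 0.30, 0.60)
    return out


@dataclass
class GCBias:
    """Smooth multiplicative GC bias: 1 + amp * gaussian bump at ``peak``."""

    amplitude: float = 0.6
    peak: float = 0.45
    width: float = 0.08

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        return 1.0 + self.amplitude * np.exp(-((gc - self.peak) ** 2) / (2 * self.width**2))


FLAT_BIAS = GCBias(amplitude=0.0)


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draw with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_controls(
    bins: pd.DataFrame,
    n_controls: int = 38,
    reads_per_sample: int = 3_100_000,
    dispersion: float = 0.02,
    gc_bias: GCBias = GCBias(),
    seed: int = 0,
) -> list[BinnedCounts]:
    """Healthy-control count profiles with GC-dependent expected depth."""
    rng = np.random.default_rng(seed)
    usable = bins["usable"].to_numpy()
    gc = bins["gc"].to_numpy()
    if np.isnan(gc[usable]).any():
        raise ValueError("bins need GC values (synthetic_gc or gc_from_fasta)")
    weight = np.zeros(len(bins))
    weight[usable] = gc_bias(gc[usable])
    mu = reads_per_sample * weight / weight.sum()
    out = []
    for i in range(n_controls):
        counts = np.zeros(len(bins), dtype=np.int64)
        counts[usable] = _nb_counts(mu[usable], dispersion, rng)
        out.append(BinnedCounts(sample_id=f"control_{i + 1:02d}", counts=counts))
    return out


@dataclass
class CNASegment:
    """Planted copy-number segment in chromosome-local bin coordinates."""

    chrom: str
    start_bin: int  # 0-based inclusive, within the chromosome
    end_bin: int  # inclusive
    copy_number: float  # diploid = 2

    def __post_init__(self):
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")
        if self.end_bin < self.start_bin:
            raise ValueError("end_bin before start_bin")


def cna_multipliers(
    bins: pd.DataFrame, segments: list[CNASegment], tumor_fraction: float
) -> np.ndarray:
    """Expected-depth multiplier per bin: 1 + f * (c - 2) / 2 inside segments."""
    if not 0 <= tumor_fraction <= 1:
        raise ValueError("tumor fraction must be in [0, 1]")
    mult = np.ones(len(bins))
    claimed = np.zeros(len(bins), dtype=bool)
    for seg in segments:
        grp = bins.index[bins["chrom"] == seg.chrom].to_numpy()
        if len(grp) == 0:
            raise ValueError(f"segment chromosome {seg.chrom} not in bin set")
        if seg.end_bin >= len(grp):
            raise ValueError(f"segment extends past {seg.chrom}")
        rows = grp[seg.start_bin : seg.end_bin + 1]
        if claimed[rows].any():
            raise ValueError("overlapping CNA segments")
        claimed[rows] = True
        mult[rows] = 1.0 + tumor_fraction * (seg.copy_number - 2.0) / 2.0
    return mult


def simulate_tumor(
    bins: pd.DataFrame,
    segments: list[CNASegment],
    tumor_fraction: float,
    sample_id: str = "tumor",
    reads_per_sample: int = 3_100_000,
    dispersion: float = 0.02,
    gc_bias: GCBias = GCBias(),
    seed: int = 0,
) -> BinnedCounts:
    """One tumor-bearing count profile at the given tumor fraction."""
    rng = np.random.default_rng(seed)
    usable = bins["usable"].to_numpy()
    gc = bins["gc"].to_numpy()
    weight = np.zeros(len(bins))
    weight[usable] = gc_bias(gc[usable])
    weight *= cna_multipliers(bins, segments, tumor_fraction)
    mu = reads_per_sample * weight / weight[usable].sum()
    counts = np.zeros(len(bins), dtype=np.int64)
    counts[usable] = _nb_counts(mu[usable], dispersion, rng)
    return BinnedCounts(sample_id=sample_id, counts=counts)


def simulate_tumor_pair(
    bins: pd.DataFrame,
    segments: list[CNASegment],
    tumor_fraction: float,
    **kwargs,
) -> tuple[BinnedCounts, BinnedCounts]:
    """Matched (plasma, tissue) profiles sharing the same CNA segments.

    Plasma carries the segments diluted by ``tumor_fraction``; tissue is
    the undiluted ``f = 1`` profile.
    """
    seed = kwargs.pop("seed", 0)
    plasma = simulate_tumor(bins, segments, tumor_fraction,
                            sample_id="plasma", seed=seed, **kwargs)
    tissue = simulate_tumor(bins, segments, 1.0,
                            sample_id="tissue", seed=seed + 1, **kwargs)
    return plasma, tissue


def random_cna_segments(
    bins: pd.DataFrame,
    n_segments: int,
    rng: np.random.Generator,
    min_bins: int = 5,
    max_bins: int = 15,
    copy_numbers: tuple = (0, 1, 3, 4),
) -> list[CNASegment]:
    """Non-overlapping random segments, one per randomly chosen chromosome."""
    chroms = list(bins["chrom"].unique())
    chosen = rng.choice(len(chroms), size=min(n_segments, len(chroms)), replace=False)
    segs = []
    for ci in chosen:
        chrom = chroms[ci]
        n = int((bins["chrom"] == chrom).sum())
        width = int(rng.integers(min_bins, min(max_bins, n // 2) + 1))
        start = int(rng.integers(0, n - width))
        segs.append(CNASegment(chrom, start, start + width - 1,
                               float(rng.choice(copy_numbers))))
    return segs


# ---------------------------------------------------------------------------
# clinical cohorts


def _censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Uniform-censoring horizon c so the mean censoring fraction matches.

    For T ~ Exp(rate) and C ~ U(0, c), P(censored) = (1 - e^{-rate c})/(rate c).
    """
    if not 0 < censor_rate < 1:
        raise ValueError("censor_rate must be in (0, 1)")

    def frac(c):
        x = rates * c
        return np.mean((1.0 - np.exp(-x)) / x) - censor_rate

    return brentq(frac, 1e-9, 1e9)


def simulate_cohort(
    n_low: int = 239,
    n_high: int = 76,
    hr_pfs: float = 2.69,
    hr_os: float = 3.07,
    median_pfs_low: float = 7.0,
    median_os_low: float = 12.0,
    censor_rate: float = 0.4,
    iscore_cutoff: float = 7.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical cohort with exponential PFS/OS and a planted group effect.

    Death hazard: lambda_d * hr_os^g; progression hazard solved so the
    marginal PFS hazard ratio is exactly ``hr_pfs``; PFS = min(progression,
    death) so PFS <= OS always.  One uniform censoring time per subject
    (shared by both endpoints) calibrated to ``censor_rate`` on PFS.
    Defaults mirror a 315-patient pancreatic-cancer cohort split 239
    low / 76 high instability.
    """
    rng = np.random.default_rng(seed)
    lam_d = math.log(2) / median_os_low
    lam_tot = math.log(2) / median_pfs_low
    lam_p = lam_tot - lam_d
    if lam_p <= 0:
        raise ValueError("median_pfs_low must be below median_os_low")
    r = (hr_pfs * lam_tot - hr_os * lam_d) / lam_p
    if r <= 0:
        raise ValueError("infeasible hazard-ratio pair: progression rate would be negative")

    n = n_low + n_high
    high = np.zeros(n, dtype=bool)
    high[n_low:] = True

    death_rate = lam_d * np.where(high, hr_os, 1.0)
    prog_rate = lam_p * np.where(high, r, 1.0)
    t_death = rng.exponential(1.0 / death_rate)
    t_prog = rng.exponential(1.0 / prog_rate)
    t_pfs = np.minimum(t_prog, t_death)

    horizon = _censor_horizon(np.where(high, hr_pfs, 1.0) * lam_tot, censor_rate)
    c = rng.uniform(0, horizon, size=n)
    pfs_time = np.minimum(t_pfs, c)
    pfs_event = (t_pfs <= c).astype(int)
    os_time = np.minimum(t_death, c)
    os_event = (t_death <= c).astype(int)

    # instability score consistent with the group label
    i_low = np.clip(rng.normal(6.1, 0.55, size=n), 3.5, iscore_cutoff)
    i_high = iscore_cutoff + 0.05 + rng.gamma(2.0, 0.45, size=n)
    i_score = np.where(high, np.minimum(i_high, 10.1), i_low)

    # stage mix concentrating high instability in metastatic disease
    stages = np.array(["resectable", "locally_advanced", "metastatic"])
    p_low = np.array([104, 74, 61]) / 239.0
    p_high = np.array([6, 4, 66]) / 76.0
    stage = np.where(high, rng.choice(stages, size=n, p=p_high),
                     rng.choice(stages, size=n, p=p_low))

    ca19_9 = np.exp(rng.normal(np.where(high, 6.5, 4.5), 1.6))
    cea = np.exp(rng.normal(np.where(high, 2.2, 1.2), 1.0))
    cohort = pd.DataFrame(
        {
            "id": [f"P{i + 1:04d}" for i in range(n)],
            "group": np.where(high, "high", "low"),
            "i_score": i_score,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "os_time": os_time,
            "os_event": os_event,
            "stage": stage,
            "age": rng.normal(65.4, 9.7, size=n).round(1),
            "sex": rng.choice(["male", "female"], size=n, p=[0.575, 0.425]),
            "location": np.where(rng.random(n) < np.where(high, 0.74, 0.45),
                                 "body_tail", "head_neck"),
            "ca19_9": ca19_9.round(1),
            "cea": cea.round(1),
            "ecog": rng.choice([0, 1, 2, 3], size=n, p=[0.55, 0.43, 0.015, 0.005]),
        }
    )
    return cohort.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)


def simulate_cutpoint_cohort(
    n: int = 315,
    cutoff: float = 7.3,
    hr: float = 3.0,
    marker_low: float = 5.0,
    marker_high: float = 10.0,
    median_low: float = 10.0,
    censor_rate: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Continuous marker with a step hazard change planted at ``cutoff``.

    Marker ~ Uniform(marker_low, marker_high); survival exponential with
    hazard multiplied by ``hr`` strictly above the cutoff; uniform
    censoring calibrated to ``censor_rate``.
    """
    rng = np.random.default_rng(seed)
    marker = rng.uniform(marker_low, marker_high, size=n)
    lam = (math.log(2) / median_low) * np.where(marker > cutoff, hr, 1.0)
    t = rng.exponential(1.0 / lam)
    horizon = _censor_horizon(lam, censor_rate)
    c = rng.uniform(0, horizon, size=n)
    return pd.DataFrame(
        {
            "i_score": marker,
            "time": np.minimum(t, c),
            "event": (t <= c).astype(int),
        }
    )
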
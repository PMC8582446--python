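"""Change-point segmentation of Z-profiles and plasma/tissue concordance.

Segmentation is a lightweight recursive binary splitter ("CBS-lite"): per
chromosome, the candidate split maximizing the two-sample t-statistic
between the flanking stretches is tested against a within-chromosome
permutation null; accepted splits recurse on both sides.  This captures
the change-point behaviour needed downstream without the pruning/undo
machinery of full circular binary segmentation.

Concordance between a plasma profile and its matched tissue profile is
Pearson correlation of mean Z-scores at segment resolution: tissue
segments are the baseline, and plasma Z is averaged over the 1-Mb bins
whose midpoints fall in each baseline segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_z: float
    bin_indices: np.ndarray = field(repr=False)


def _split_tstats(x: np.ndarray, min_width: int) -> np.ndarray:
    """|t| for every split position i (left = x[:i]), NaN where too narrow.

    Pooled-variance two-sample t; an epsilon guards zero-variance stretches.
    """
    n = len(x)
    t = np.full(n, np.nan)
    if n < 2 * min_width:
        return t
    cs = np.cumsum(x)
    cs2 = np.cumsum(x * x)
    i = np.arange(min_width, n - min_width + 1)
    nl = i.astype(float)
    nr = n - nl
    sl = cs[i - 1]
    sr = cs[-1] - sl
    ml = sl / nl
    mr = sr / nr
    ssl = cs2[i - 1] - nl * ml**2
    ssr = (cs2[-1] - cs2[i - 1]) - nr * mr**2
    pooled = (ssl + ssr) / np.maximum(n - 2, 1)
    se = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / nl + 1.0 / nr)) + 1e-12
    t[i] = np.abs(ml - mr) / se
    return t


def _best_split(x: np.ndarray, min_width: int) -> tuple[int | None, float]:
    t = _split_tstats(x, min_width)
    if np.all(np.isnan(t)):
        return None, 0.0
    i = int(np.nanargmax(t))
    return i, float(t[i])


def _split_pvalue(x: np.ndarray, observed_t: float, min_width: int,
                  n_perm: int, rng: np.random.Generator) -> float:
    hits = 0
    for _ in range(n_perm):
        _, t = _best_split(rng.permutation(x), min_width)
        if t >= observed_t:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _segment_array(x: np.ndarray, alpha: float, min_width: int,
                   n_perm: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive splitting of one chromosome; returns [start, stop) index pairs."""
    n = len(x)
    if n < 2 * min_width:
        return [(0, n)]
    i, t_obs = _best_split(x, min_width)
    if i is None:
        return [(0, n)]
    p = _split_pvalue(x, t_obs, min_width, n_perm, rng)
    if p >= alpha:
        return [(0, n)]
    left = _segment_array(x[:i], alpha, min_width, n_perm, rng)
    right = _segment_array(x[i:], alpha, min_width, n_perm, rng)
    return left + [(i + a, i + b) for a, b in right]


def segment(
    z: np.ndarray,
    bins: pd.DataFrame,
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[Segment]:
    """Segment a Z-profile into constant-copy-number stretches per chromosome.

    Splits are accepted when the permutation p-value of the maximal
    t-statistic falls below ``alpha``.  Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        vals = z[idx]
        mask = grp["usable"].to_numpy() & np.isfinite(vals)
        if not mask.any():
            continue
        use_idx = idx[mask]
        x = vals[mask]
        for a, b in _segment_array(x, alpha, min_width, n_perm, rng):
            members = use_idx[a:b]
            segments.append(
                Segment(
                    chrom=chrom,
                    start=int(bins.loc[members[0], "start"]),
                    end=int(bins.loc[members[-1], "end"]),
                    n_bins=len(members),
                    mean_z=float(x[a:b].mean()),
                    bin_indices=members,
                )
            )
    return segments


def segments_table(segments: list[Segment], sample_id: str = "sample") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_bins": [s.n_bins for s in segments],
            "mean_z": [s.mean_z for s in segments],
        }
    )


def project_segments(
    z: np.ndarray, bins: pd.DataFrame, baseline: list[Segment]
) -> tuple[np.ndarray, list[Segment]]:
    """Mean Z per baseline segment, by bin-midpoint membership.

    Returns the projected means and the baseline segments retained
    (segments covering no usable bin of ``z`` are dropped from both).
    """
    usable = bins["usable"].to_numpy() & np.isfinite(z)
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
    chroms = bins["chrom"].to_numpy()
    means, kept = [], []
    for seg in baseline:
        sel = usable & (chroms == seg.chrom) & (mid >= seg.start) & (mid <= seg.end)
        if not sel.any():
            continue
        means.append(float(z[sel].mean()))
        kept.append(seg)
    if not kept:
        raise ValueError("no baseline segment overlaps a usable bin")
    return np.asarray(means), kept


@dataclass
class ConcordanceResult:
    r: float | None
    r_squared: float | None
    n_segments: int


def concordance(plasma_seg_z: np.ndarray, tissue_seg_z: np.ndarray) -> ConcordanceResult:
    """Pearson correlation of segment-resolution Z-scores (needs n >= 3)."""
    a = np.asarray(plasma_seg_z, dtype=float)
    b = np.asarray(tissue_seg_z, dtype=float)
    if len(a) != len(b):
        raise ValueError("segment vectors differ in length")
    if len(a) < 3:
        raise ValueError("need at least 3 segments for a concordance value")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return ConcordanceResult(None, None, len(a))
    r = float(stats.pearsonr(a, b).statistic)
    return ConcordanceResult(r, r * r, len(a))
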
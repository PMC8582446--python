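"""Genome-wide instability score (I-score) from bin-level Z-profiles.

Z-scores are first LOESS-smoothed along each chromosome (adjacent-bin
smoothing damps bin-level sampling noise while preserving multi-bin CNA
signal), then collapsed to a single scalar per sample:

    I-score = ln( sum over usable bins of |smoothed z| )

Samples are dichotomized into low/high instability groups at a cutoff on
the I-score scale; the cutoff is cohort-derived (see
:func:`cfgi.survival.contal_oquigley`), with 7.3 as the shipped default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

#: default low/high instability cutoff on the natural-log I-score scale
DEFAULT_CUTOFF = 7.3

#: smallest smoothing window, in bins
MIN_SPAN_BINS = 4
#: default window as a fraction of a chromosome's usable bins
SPAN_FRACTION = 0.05


def smooth_z(z: np.ndarray, bins: pd.DataFrame, span_bins: int | None = None) -> np.ndarray:
    """LOESS-smooth Z-scores against bin index, independently per chromosome.

    The window is ``span_bins`` bins when given, else
    ``max(4, 5% of the chromosome's usable bins)``.  Chromosomes with
    fewer than 4 usable bins are passed through unsmoothed with a warning.
    Smoothing never crosses a chromosome boundary.
    """
    out = np.full(len(z), np.nan)
    for chrom, grp in bins.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        vals = z[idx]
        mask = grp["usable"].to_numpy() & np.isfinite(vals)
        n = int(mask.sum())
        if n == 0:
            continue
        if n < MIN_SPAN_BINS:
            warnings.warn(f"{chrom}: fewer than {MIN_SPAN_BINS} usable bins, z passed through")
            out[idx[mask]] = vals[mask]
            continue
        w = span_bins if span_bins is not None else max(MIN_SPAN_BINS, int(round(SPAN_FRACTION * n)))
        frac = min(1.0, w / n)
        sm = lowess(vals[mask], np.arange(n, dtype=float), frac=frac, it=0, return_sorted=False)
        out[idx[mask]] = sm
    return out


@dataclass
class IScoreResult:
    sample_id: str
    i_score: float | None
    sum_abs_smoothed_z: float
    n_bins_used: int
    group: str | None
    cutoff: float
    reason: str | None = None


def i_score(
    smoothed: np.ndarray,
    bins: pd.DataFrame,
    sample_id: str = "sample",
    cutoff: float = DEFAULT_CUTOFF,
) -> IScoreResult:
    """Collapse a smoothed Z-profile to ln(sum |smoothed z|) and classify.

    A zero-instability profile (all smoothed z exactly 0) is reported as
    missing with a reason, never as -inf.
    """
    mask = bins["usable"].to_numpy() & np.isfinite(smoothed)
    vals = np.abs(smoothed[mask])
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError("no usable smoothed z values")
    total = float(vals.sum())
    if total <= 0:
        return IScoreResult(sample_id, None, 0.0, n_used, None, cutoff,
                            reason="zero-instability profile")
    score = math.log(total)
    return IScoreResult(sample_id, score, total, n_used, classify(score, cutoff), cutoff)


def classify(score: float | None, cutoff: float = DEFAULT_CUTOFF) -> str | None:
    """Low/high instability call: high iff score strictly exceeds the cutoff."""
    if score is None:
        return None
    return "high" if score > cutoff else "low"


def results_table(results: list[IScoreResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "i_score": [r.i_score for r in results],
            "sum_abs_smoothed_z": [r.sum_abs_smoothed_z for r in results],
            "n_bins_used": [r.n_bins_used for r in results],
            "group": [r.group for r in results],
            "cutoff": [r.cutoff for r in results],
        }
    )
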
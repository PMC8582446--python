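"""Convenience chains: counts -> corrected RF -> Z -> smoothed Z -> I-score."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bins import BinnedCounts, relative_frequency
from .gcnorm import ReferencePanel, build_panel, gc_correct, z_score
from .iscore import DEFAULT_CUTOFF, IScoreResult, i_score, smooth_z


def control_panel(
    control_counts: list[BinnedCounts], bins: pd.DataFrame, gc_span: float = 0.75
) -> ReferencePanel:
    """GC-correct each control and build the reference panel."""
    rfs = [gc_correct(relative_frequency(c, bins), bins, span=gc_span)
           for c in control_counts]
    return build_panel(rfs, bins)


def sample_zprofile(
    counts: BinnedCounts,
    bins: pd.DataFrame,
    panel: ReferencePanel,
    gc_span: float = 0.75,
    smooth_span: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and smoothed Z-profile for one sample against a panel."""
    rf = gc_correct(relative_frequency(counts, bins), bins, span=gc_span)
    z = z_score(rf, panel)
    return z, smooth_z(z, bins, span_bins=smooth_span)


def sample_iscore(
    counts: BinnedCounts,
    bins: pd.DataFrame,
    panel: ReferencePanel,
    cutoff: float = DEFAULT_CUTOFF,
    gc_span: float = 0.75,
    smooth_span: int | None = None,
) -> IScoreResult:
    """End-to-end I-score for one sample."""
    _, smoothed = sample_zprofile(counts, bins, panel, gc_span, smooth_span)
    return i_score(smoothed, bins, sample_id=counts.sample_id, cutoff=cutoff)
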
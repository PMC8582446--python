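"""GC-bias correction and the panel-of-normals Z-score transform.

Low-pass WGS bin counts carry a smooth dependence on bin GC content
(library prep + sequencer bias).  Each sample's per-bin relative
frequencies are corrected by fitting a LOESS trend of RF against GC and
subtracting it (additive residuals, sample mean restored, profile
renormalized to sum 1).

A reference panel of healthy controls then supplies, per bin, the mean
``m`` and standard deviation ``sd`` of corrected relative frequencies,
and a sample's instability signal is the standardized deviation

    z_bin = (rf_bin - m_bin) / sd_bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

#: bins whose panel SD falls below this relative-frequency floor are
#: excluded from Z-scores (near-constant bins would blow up the ratio)
SD_FLOOR = 1e-9


def gc_correct(
    rf: np.ndarray,
    bins: pd.DataFrame,
    span: float = 0.75,
    iterations: int = 2,
) -> np.ndarray:
    """Remove the LOESS trend of relative frequency against GC content.

    Degree-1 local regression of rf on gc with window fraction ``span``;
    the corrected profile is ``rf - trend(gc) + mean(rf)``, clipped at 0
    and renormalized to sum 1 over usable bins.  ``iterations`` robustness
    reweights let the trend ignore strongly aberrant (CNA) bins.
    Correction is per-sample.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    usable = bins["usable"].to_numpy()
    mask = usable & np.isfinite(rf)
    gc = bins["gc"].to_numpy(dtype=float)
    if np.isnan(gc[mask]).any():
        raise ValueError("GC fraction missing for usable bins")
    out = np.full(len(rf), np.nan)
    x = gc[mask]
    y = rf[mask]
    if np.ptp(x) == 0:
        warnings.warn("constant GC across bins; correction is the identity")
        out[mask] = y / y.sum()
        return out
    trend = lowess(y, x, frac=span, it=iterations, return_sorted=False)
    corrected = np.clip(y - trend + y.mean(), 0.0, None)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("degenerate profile after GC correction")
    out[mask] = corrected / total
    return out


@dataclass
class ReferencePanel:
    """Per-bin mean/SD of corrected relative frequencies from controls."""

    m: np.ndarray
    sd: np.ndarray
    usable: np.ndarray  # bool; panel bins eligible for Z-scores
    n_controls: int

    def to_frame(self, bins: pd.DataFrame) -> pd.DataFrame:
        f = bins[["chrom", "start", "end"]].copy()
        f["m"] = self.m
        f["sd"] = self.sd
        f["usable"] = self.usable
        return f


def build_panel(control_rfs: list[np.ndarray], bins: pd.DataFrame) -> ReferencePanel:
    """Build the reference panel from GC-corrected control profiles.

    Mean and sample SD (n-1 denominator) per usable bin; bins with SD
    below :data:`SD_FLOOR` are flagged out of the Z-score support.
    """
    if len(control_rfs) < 2:
        raise ValueError("need at least 2 control profiles")
    n_bins = len(bins)
    for rf in control_rfs:
        if len(rf) != n_bins:
            raise ValueError("control profile not aligned to the bin set")
    mat = np.vstack(control_rfs)
    usable = bins["usable"].to_numpy() & np.isfinite(mat).all(axis=0)
    m = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    m[usable] = mat[:, usable].mean(axis=0)
    sd[usable] = mat[:, usable].std(axis=0, ddof=1)
    low = usable & (sd < SD_FLOOR)
    if low.any():
        warnings.warn(f"{int(low.sum())} bins below SD floor excluded from Z-scores")
    return ReferencePanel(m=m, sd=sd, usable=usable & ~low, n_controls=len(control_rfs))


def z_score(rf: np.ndarray, panel: ReferencePanel) -> np.ndarray:
    """Standardize a corrected profile against the panel: (rf - m) / sd."""
    if len(rf) != len(panel.m):
        raise ValueError("profile and panel are on different bin sets")
    z = np.full(len(rf), np.nan)
    mask = panel.usable & np.isfinite(rf)
    z[mask] = (rf[mask] - panel.m[mask]) / panel.sd[mask]
    return z


def write_panel(path, panel: ReferencePanel, bins: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_controls={panel.n_controls} cfgi=0.1.0\n")
        panel.to_frame(bins).to_csv(fh, sep="\t", index=False)


def read_panel(path) -> tuple[pd.DataFrame, ReferencePanel]:
    with open(path) as fh:
        header = fh.readline()
        n_controls = int(header.split("n_controls=")[1].split()[0])
        tab = pd.read_csv(fh, sep="\t")
    panel = ReferencePanel(
        m=tab["m"].to_numpy(),
        sd=tab["sd"].to_numpy(),
        usable=tab["usable"].to_numpy(dtype=bool),
        n_controls=n_controls,
    )
    return tab[["chrom", "start", "end"]], panel
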
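"""Recurrent copy-number aberration regions across a cohort.

A simplified amplitude-weighted recurrence scorer: per bin and direction,

    G_amp(bin) = sum over samples of |smoothed z| * 1[call == amp] / n_samples

(analogously for deletions), with calls from fixed thresholds on the
smoothed Z-scale (amp: z > 2, del: z < -2).  Significance comes from a
permutation null that cyclically shifts each sample's per-chromosome
call/amplitude vector independently — preserving each sample's aberration
length spectrum while destroying cross-sample positional recurrence.
Per-bin empirical p-values are Benjamini-Hochberg adjusted within each
direction, and maximal runs of bins with q below the cutoff (0.25 by
convention) are merged into regions.

This intentionally forgoes the peel-off and arm-level/focal decomposition
of the full GISTIC2.0 algorithm; what is kept is the amplitude-weighted
frequency score and the q < 0.25 decision surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

AMP_THRESH = 2.0
DEL_THRESH = -2.0


def call_aberrations(
    profiles: list[np.ndarray],
    bins: pd.DataFrame,
    amp_thresh: float = AMP_THRESH,
    del_thresh: float = DEL_THRESH,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold smoothed Z-profiles into (calls, amplitudes) matrices.

    ``calls`` is samples x bins with +1 (amp, z strictly > amp_thresh),
    -1 (del, z strictly < del_thresh) or 0; ``amplitudes`` is |z| with 0
    at missing bins.
    """
    n_bins = len(bins)
    for p in profiles:
        if len(p) != n_bins:
            raise ValueError("profile not aligned to the bin set")
    mat = np.vstack(profiles)
    finite = np.isfinite(mat)
    calls = np.zeros(mat.shape, dtype=np.int8)
    calls[finite & (mat > amp_thresh)] = 1
    calls[finite & (mat < del_thresh)] = -1
    amps = np.where(finite, np.abs(mat), 0.0)
    return calls, amps


def g_score(calls: np.ndarray, amps: np.ndarray) -> dict[str, np.ndarray]:
    """Amplitude-weighted recurrence score per bin and direction."""
    if calls.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    n = calls.shape[0]
    return {
        "amp": (amps * (calls == 1)).sum(axis=0) / n,
        "del": (amps * (calls == -1)).sum(axis=0) / n,
    }


@dataclass
class RecurrentRegion:
    type: str  # "amp" | "del"
    chrom: str
    start: int
    end: int
    g_score: float
    q_value: float
    member_bins: np.ndarray = field(repr=False)


def _chrom_blocks(bins: pd.DataFrame) -> list[np.ndarray]:
    return [
        grp.index.to_numpy()[grp["usable"].to_numpy()]
        for _, grp in bins.groupby("chrom", sort=False)
    ]


def region_significance(
    calls: np.ndarray,
    amps: np.ndarray,
    bins: pd.DataFrame,
    n_perm: int = 500,
    q_cut: float = 0.25,
    seed: int = 0,
) -> list[RecurrentRegion]:
    """Call recurrent regions by permutation FDR on the recurrence score.

    Null: each sample's contribution vector is cyclically shifted within
    each chromosome by an independent uniform offset.  p per bin is the
    fraction of permuted scores >= the observed score (add-one
    estimator); BH across usable bins within each direction; maximal
    contiguous runs with q < ``q_cut`` become regions (region g = max
    member g, region q = min member q).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-value resolution")
    usable = bins["usable"].to_numpy()
    n_samples = calls.shape[0]
    contrib = {
        "amp": amps * (calls == 1),
        "del": amps * (calls == -1),
    }
    observed = {k: v.sum(axis=0) / n_samples for k, v in contrib.items()}
    blocks = _chrom_blocks(bins)
    exceed = {k: np.zeros(calls.shape[1], dtype=np.int64) for k in contrib}

    # each sample's shift stream is seeded by a digest of its own calls, so
    # the null (hence the region list) does not depend on sample order
    import hashlib

    shifts = np.empty((n_samples, n_perm, len(blocks)), dtype=np.int64)
    for s in range(n_samples):
        digest = hashlib.blake2b(
            calls[s].tobytes() + amps[s].tobytes(), digest_size=8
        ).digest()
        rng_s = np.random.default_rng([seed, int.from_bytes(digest, "little")])
        for bi, block in enumerate(blocks):
            L = max(len(block), 1)
            shifts[s, :, bi] = rng_s.integers(0, L, size=n_perm)

    for perm in range(n_perm):
        g_perm = {k: np.zeros(calls.shape[1]) for k in contrib}
        for bi, block in enumerate(blocks):
            L = len(block)
            if L == 0:
                continue
            gather = (np.arange(L)[None, :] - shifts[:, perm, bi][:, None]) % L
            for k in contrib:
                sub = contrib[k][:, block]
                g_perm[k][block] = sub[np.arange(n_samples)[:, None], gather].sum(axis=0) / n_samples
        for k in contrib:
            exceed[k] += g_perm[k] >= observed[k]

    regions: list[RecurrentRegion] = []
    for kind in ("amp", "del"):
        p = np.ones(calls.shape[1])
        p[usable] = (1 + exceed[kind][usable]) / (n_perm + 1)
        q = np.ones(calls.shape[1])
        # no signal at all in this direction -> nothing to test
        if observed[kind][usable].max() <= 0:
            continue
        q[usable] = multipletests(p[usable], method="fdr_bh")[1]
        for block in blocks:
            sig = q[block] < q_cut
            if not sig.any():
                continue
            edges = np.flatnonzero(np.diff(np.concatenate(([0], sig.view(np.int8), [0]))))
            for a, b in zip(edges[::2], edges[1::2]):
                members = block[a:b]
                regions.append(
                    RecurrentRegion(
                        type=kind,
                        chrom=str(bins.loc[members[0], "chrom"]),
                        start=int(bins.loc[members[0], "start"]),
                        end=int(bins.loc[members[-1], "end"]),
                        g_score=float(observed[kind][members].max()),
                        q_value=float(q[members].min()),
                        member_bins=members,
                    )
                )
    return regions


def regions_table(regions: list[RecurrentRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "type": [r.type for r in regions],
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "g_score": [r.g_score for r in regions],
            "q_value": [r.q_value for r in regions],
        }
    )


def load_curated_genes() -> pd.DataFrame:
    """Bundled curated pancreatic-cancer gene intervals (hg19, 1-based).

    Columns: symbol, chrom, start, end, curated_type (OCG oncogene,
    TSG tumor suppressor, PPA poor prognosis when amplified).
    """
    with resources.files("cfgi.data").joinpath("curated_genes_hg19.bed").open() as fh:
        tab = pd.read_csv(fh, sep="\t", header=None,
                          names=["chrom", "start", "end", "symbol", "curated_type"])
    tab["start"] = tab["start"] + 1  # BED 0-based half-open -> 1-based inclusive
    return tab[["symbol", "chrom", "start", "end", "curated_type"]]


def load_recurrent_regions() -> pd.DataFrame:
    """Bundled cohort-level recurrent amp/del region coordinates (hg19)."""
    with resources.files("cfgi.data").joinpath("recurrent_regions_hg19.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def gene_overlap(regions: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign genes to regions by >= 1 bp interval overlap (1-based inclusive).

    ``regions`` needs columns type, chrom, start, end (a
    :func:`regions_table` output or the bundled coordinates); returns one
    row per (region, gene) pair.
    """
    rows = []
    for ri, reg in regions.reset_index(drop=True).iterrows():
        hit = genes[
            (genes["chrom"] == reg["chrom"])
            & (genes["start"] <= reg["end"])
            & (genes["end"] >= reg["start"])
        ]
        for _, g in hit.iterrows():
            rows.append(
                {
                    "region_index": ri,
                    "region_type": reg["type"],
                    "chrom": reg["chrom"],
                    "region_start": reg["start"],
                    "region_end": reg["end"],
                    "symbol": g["symbol"],
                    "curated_type": g.get("curated_type", "none"),
                }
            )
    return pd.DataFrame(rows, columns=[
        "region_index", "region_type", "chrom", "region_start", "region_end",
        "symbol", "curated_type",
    ])
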
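"""Gene sum score (GSS): gene-level 0/1 scoring and prognostic selection.

Genes inside recurrent amplification regions score 1 when their
length-weighted mean Z exceeds +2; genes inside recurrent deletion
regions score 1 when it falls below -2; everything else scores 0.  Genes
are ranked by the log-rank p-value of overall survival between score-1
and score-0 patients, and k-fold cross-validation picks, per training
fold, the best (top-N gene set, integer GSS cutoff) pair by the most
significant training-set log-rank split.  The consensus sets are the
genes selected in every fold (overlap) and in at least one fold (union).

External gene-level thresholded copy-number calls (GISTIC-style
-2..2 integers) can be scored with the same rule: only high-level
amplification (+2) or homozygous deletion (-2) scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import RiskSets, logrank_p


def gene_z(z: np.ndarray, genes: pd.DataFrame, bins: pd.DataFrame) -> pd.Series:
    """Length-weighted mean Z per gene (weights = bp overlap with usable bins).

    ``genes`` has 1-based inclusive columns symbol, chrom, start, end.
    Genes overlapping no usable bin get NaN.
    """
    usable = bins["usable"].to_numpy() & np.isfinite(z)
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    ends = bins["end"].to_numpy()
    out = {}
    for _, g in genes.iterrows():
        sel = usable & (chroms == g["chrom"]) & (starts <= g["end"]) & (ends >= g["start"])
        if not sel.any():
            out[g["symbol"]] = np.nan
            continue
        ov = np.minimum(ends[sel], g["end"]) - np.maximum(starts[sel], g["start"]) + 1
        out[g["symbol"]] = float(np.average(z[sel], weights=ov))
    return pd.Series(out, name="gene_z")


def score_genes(
    gene_z_mat: pd.DataFrame,
    region_type: pd.Series,
    amp_thresh: float = 2.0,
    del_thresh: float = -2.0,
) -> pd.DataFrame:
    """Binary score matrix (samples x genes) from gene-level Z-scores.

    ``region_type`` maps gene symbol -> "amp" or "del" (the direction of
    its recurrent region).  Strict inequalities; genes with missing Z
    score 0 (flagged via a warning).
    """
    missing_type = [g for g in gene_z_mat.columns if g not in region_type.index]
    if missing_type:
        raise ValueError(f"genes without a region type: {missing_type}")
    bad = set(region_type.loc[list(gene_z_mat.columns)]) - {"amp", "del"}
    if bad:
        raise ValueError(f"unknown region types: {bad}")
    n_missing = int(gene_z_mat.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(f"{n_missing} missing gene-level Z values scored 0")
    scores = pd.DataFrame(0, index=gene_z_mat.index, columns=gene_z_mat.columns, dtype=int)
    for g in gene_z_mat.columns:
        col = gene_z_mat[g]
        if region_type[g] == "amp":
            scores[g] = (col > amp_thresh).astype(int)
        else:
            scores[g] = (col < del_thresh).astype(int)
    return scores


def rank_genes(scores: pd.DataFrame, times, events) -> pd.DataFrame:
    """Rank genes by two-group log-rank p between score-1 and score-0 patients.

    Genes with a degenerate score column (all 0 or all 1) get the
    sentinel p = 1.  Ties in p are broken by gene symbol so the ordering
    is deterministic.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    rows = []
    for g in scores.columns:
        mask = scores[g].to_numpy().astype(bool)
        rows.append({"symbol": g, "p": logrank_p(times, events, mask)})
    tab = pd.DataFrame(rows)
    return tab.sort_values(["p", "symbol"], kind="mergesort").reset_index(drop=True)


#: smallest admissible fraction of the cohort on either side of a GSS split;
#: mirrors the 10% trim used for continuous-marker cutpoints and keeps the
#: asymptotic log-rank p honest on the held-out folds
MIN_GROUP_FRAC = 0.10


def _best_cutoff(gss: np.ndarray, times, events,
                 min_group_frac: float = MIN_GROUP_FRAC) -> tuple[int, float]:
    """Integer cutoff minimizing the log-rank p of gss > c (ties -> smaller c)."""
    rs = RiskSets(times, events)
    floor = max(1, int(np.ceil(min_group_frac * len(gss))))
    best_p, best_c = np.inf, 0
    for c in range(0, int(gss.max())):
        mask = gss > c
        if mask.sum() < floor or (~mask).sum() < floor:
            continue
        p = rs.statistic(mask)[1]
        if p < best_p - 1e-15:
            best_p, best_c = p, c
    if not np.isfinite(best_p):
        return 0, 1.0
    return best_c, best_p


@dataclass
class GSSModel:
    folds: list[dict] = field(default_factory=list)
    overlap_genes: list[str] = field(default_factory=list)
    union_genes: list[str] = field(default_factory=list)
    seed: int | None = None


def cv_select(
    scores: pd.DataFrame,
    times,
    events,
    k: int = 5,
    n_range: range = range(1, 51),
    seed: int = 0,
) -> GSSModel:
    """K-fold cross-validated selection of prognostic gene sets.

    Folds are simple random (seeded).  Per training fold: genes are
    ranked by log-rank p; for each N in ``n_range`` the GSS is the
    row-sum over the top-N genes and integer cutoffs are scanned; the
    (N, cutoff) pair with the most significant training log-rank split
    wins (ties -> smaller cutoff, then smaller N).  The winning model is
    evaluated on the held-out fold.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    n = len(scores)
    if n < 5 * k:
        raise ValueError("cohort too small for the requested folds")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % k
        if all(events[fold_of == f].sum() > 0 for f in range(k)):
            break
    else:
        raise ValueError("could not build folds with events in every fold")

    model = GSSModel(seed=seed)
    for f in range(k):
        test = fold_of == f
        train = ~test
        ranked = rank_genes(scores.loc[train], times[train], events[train])
        best = None  # (p, cutoff, N, gene list)
        for N in n_range:
            if N > len(ranked):
                break
            top = ranked["symbol"].iloc[:N].tolist()
            gss_train = scores.loc[train, top].sum(axis=1).to_numpy()
            if gss_train.max() == 0:
                continue
            c, p = _best_cutoff(gss_train, times[train], events[train])
            cand = (p, c, N, top)
            if best is None or (p < best[0] - 1e-15) or (
                abs(p - best[0]) <= 1e-15 and (c, N) < (best[1], best[2])
            ):
                best = cand
        if best is None:
            warnings.warn(f"fold {f}: no informative gene set; skipped")
            continue
        p_train, cutoff, top_n, genes = best
        gss_test = scores.loc[test, genes].sum(axis=1).to_numpy()
        p_test = logrank_p(times[test], events[test], gss_test > cutoff)
        model.folds.append(
            {
                "fold": f,
                "selected_genes": genes,
                "top_n": top_n,
                "cutoff": cutoff,
                "train_p": p_train,
                "test_p": p_test,
            }
        )
    sets = [set(fd["selected_genes"]) for fd in model.folds]
    if sets:
        model.overlap_genes = sorted(set.intersection(*sets))
        model.union_genes = sorted(set.union(*sets))
    return model


def gss_apply(
    scores: pd.DataFrame, gene_set: list[str], cutoff: int
) -> pd.DataFrame:
    """Per-sample gene sum score and low/high call (high iff gss > cutoff).

    Genes in ``gene_set`` missing from the score matrix contribute 0
    (their count is reported in the ``n_missing_genes`` column).
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    present = [g for g in gene_set if g in scores.columns]
    n_missing = len(gene_set) - len(present)
    if n_missing:
        warnings.warn(f"{n_missing} selected genes absent from the score matrix")
    gss = scores[present].sum(axis=1) if present else pd.Series(0, index=scores.index)
    return pd.DataFrame(
        {
            "gss": gss.astype(int),
            "group": np.where(gss > cutoff, "high", "low"),
            "n_missing_genes": n_missing,
        }
    )


def score_external(calls: pd.DataFrame) -> pd.DataFrame:
    """Score external GISTIC-thresholded calls (genes x samples, -2..2).

    Only high-level amplification (+2) or homozygous deletion (-2)
    scores 1.  Returns a samples x genes binary matrix.
    """
    if not calls.isin([-2, -1, 0, 1, 2]).all().all():
        raise ValueError("external calls must be integers in -2..2")
    return (calls.abs() == 2).astype(int).T
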
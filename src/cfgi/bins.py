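"""Genomic bin backbone for low-pass WGS copy-number profiling.

The genome (autosomes chr1-chr22 for the default hg19 table) is tiled into
fixed-size bins — 1 Mb by default, which yields 2897 bins on hg19 — and every
downstream quantity (read counts, relative frequencies, Z-scores) lives on
this backbone.  Coordinates are 1-based closed intervals internally; BED
input/output converts from 0-based half-open.

A bin set is a :class:`pandas.DataFrame` with columns ``chrom`` (str),
``start``/``end`` (int, 1-based inclusive), ``gc`` (float fraction or NaN)
and ``usable`` (bool).  Bins overlapping an exclusion list (low-mappability
regions, telomeres) are flagged unusable rather than dropped, so every
profile stays aligned to the same rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 1_000_000

BIN_COLUMNS = ["chrom", "start", "end", "gc", "usable"]


def load_hg19_autosomes() -> pd.DataFrame:
    """Chromosome-size table for hg19 chr1-chr22 (columns chrom, length)."""
    with resources.files("cfgi.data").joinpath("hg19.chrom.sizes").open() as fh:
        return read_chrom_sizes(fh)


def read_chrom_sizes(source) -> pd.DataFrame:
    """Read a UCSC chrom.sizes two-column TSV."""
    tab = pd.read_csv(source, sep="\t", header=None, names=["chrom", "length"])
    if tab.empty:
        raise ValueError("empty chromosome table")
    if tab["chrom"].duplicated().any():
        raise ValueError("duplicate chromosome names")
    if (tab["length"] <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    return tab


def build_bins(chrom_table: pd.DataFrame, bin_size: int = DEFAULT_BIN_SIZE) -> pd.DataFrame:
    """Tile each chromosome into consecutive fixed-size bins.

    Bin *i* on a chromosome covers ``[(i-1)*bin_size + 1, min(i*bin_size, L)]``;
    the last bin of a chromosome may be shorter than ``bin_size``.  The
    number of bins is ``sum(ceil(L/bin_size))`` over chromosomes, which is
    2897 for the hg19 autosomes at 1 Mb.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(chrom_table) == 0:
        raise ValueError("empty chromosome table")
    rows = []
    for chrom, length in zip(chrom_table["chrom"], chrom_table["length"]):
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        n = math.ceil(length / bin_size)
        for i in range(n):
            start = i * bin_size + 1
            end = min((i + 1) * bin_size, int(length))
            rows.append((chrom, start, end))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["gc"] = np.nan
    bins["usable"] = True
    return bins


def apply_exclusion(bins: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Flag bins overlapping any blacklist interval (>= 1 bp) as unusable.

    ``blacklist`` has 1-based inclusive columns ``chrom, start, end``
    (use :func:`read_bed` for BED input).  Intervals on chromosomes absent
    from the bin set are ignored with a warning.
    """
    out = bins.copy()
    if len(blacklist) == 0:
        return out
    known = set(out["chrom"])
    missing = sorted(set(blacklist["chrom"]) - known)
    if missing:
        warnings.warn(f"blacklist chromosomes not in bin set, ignored: {missing}")
    for chrom, grp in blacklist.groupby("chrom"):
        if chrom not in known:
            continue
        sel = out["chrom"] == chrom
        starts = out.loc[sel, "start"].to_numpy()
        ends = out.loc[sel, "end"].to_numpy()
        hit = np.zeros(len(starts), dtype=bool)
        for s, e in zip(grp["start"], grp["end"]):
            hit |= (starts <= e) & (ends >= s)
        out.loc[sel, "usable"] = out.loc[sel, "usable"].to_numpy() & ~hit
    return out


def read_bed(source) -> pd.DataFrame:
    """Read a BED (0-based half-open) file into 1-based inclusive intervals."""
    tab = pd.read_csv(source, sep="\t", header=None, comment="#")
    tab = tab.iloc[:, :3]
    tab.columns = ["chrom", "start", "end"]
    tab["start"] = tab["start"].astype(int) + 1
    tab["end"] = tab["end"].astype(int)
    return tab


@dataclass
class BinnedCounts:
    """Per-bin read counts for one sample, aligned to a bin set."""

    sample_id: str
    counts: np.ndarray  # int, len == n_bins
    n_unassigned: int = 0  # reads on chromosomes outside the bin set

    def total_usable(self, bins: pd.DataFrame) -> int:
        return int(self.counts[bins["usable"].to_numpy()].sum())


def _bin_index_lookup(bins: pd.DataFrame):
    """Map (chrom, 1-based pos) -> row index, exploiting fixed-size tiling."""
    sizes = (bins["end"] - bins["start"] + 1).to_numpy()
    bin_size = int(sizes.max())
    table = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        table[chrom] = (int(grp.index[0]), len(grp))
    return table, bin_size


def count_reads(
    alignment_source,
    bins: pd.DataFrame,
    sample_id: str | None = None,
    mapq_min: int = 60,
    drop_duplicates: bool = True,
) -> BinnedCounts:
    """Count aligned reads per bin from a SAM/BAM file or an open pysam file.

    A read is assigned to the bin containing its leftmost aligned position.
    Reads below ``mapq_min``, duplicate-flagged reads (when
    ``drop_duplicates``), and unmapped/secondary/supplementary records are
    not counted.  Reads on chromosomes outside the bin set are tallied in
    ``n_unassigned``.
    """
    import pysam

    if isinstance(alignment_source, (str, bytes)) or hasattr(alignment_source, "__fspath__"):
        af = pysam.AlignmentFile(str(alignment_source), check_sq=False)
        close = True
    else:
        af = alignment_source
        close = False
    lookup, bin_size = _bin_index_lookup(bins)
    counts = np.zeros(len(bins), dtype=np.int64)
    unassigned = 0
    try:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < mapq_min:
                continue
            if drop_duplicates and read.is_duplicate:
                continue
            loc = lookup.get(read.reference_name)
            if loc is None:
                unassigned += 1
                continue
            offset, n = loc
            i = read.reference_start // bin_size  # reference_start is 0-based
            if i >= n:
                unassigned += 1
                continue
            counts[offset + i] += 1
    finally:
        if close:
            af.close()
    if sample_id is None:
        name = getattr(af, "filename", None)
        sample_id = name.decode() if isinstance(name, bytes) else (name or "sample")
    return BinnedCounts(sample_id=str(sample_id), counts=counts, n_unassigned=unassigned)


def relative_frequency(counts: BinnedCounts, bins: pd.DataFrame) -> np.ndarray:
    """Per-bin relative read frequency over usable bins.

    Returns an array aligned to the bin set with NaN at unusable bins;
    values over usable bins sum to 1.
    """
    usable = bins["usable"].to_numpy()
    total = counts.counts[usable].sum()
    if total <= 0:
        raise ValueError("empty profile: zero usable reads")
    rf = np.full(len(bins), np.nan)
    rf[usable] = counts.counts[usable] / total
    return rf


def read_counts_table(source, bins: pd.DataFrame) -> list[BinnedCounts]:
    """Read a long-format counts TSV (sample_id, chrom, start, end, count).

    Rows are matched to bins by (chrom, start); every sample must cover all
    bins listed for it, missing bins count 0.
    """
    tab = pd.read_csv(source, sep="\t")
    key = pd.MultiIndex.from_frame(bins[["chrom", "start"]])
    pos = pd.Series(np.arange(len(bins)), index=key)
    out = []
    for sid, grp in tab.groupby("sample_id", sort=False):
        idx = pos.reindex(pd.MultiIndex.from_frame(grp[["chrom", "start"]]))
        if idx.isna().any():
            raise ValueError(f"sample {sid}: rows not matching the bin set")
        counts = np.zeros(len(bins), dtype=np.int64)
        counts[idx.to_numpy(dtype=int)] = grp["count"].to_numpy()
        out.append(BinnedCounts(sample_id=str(sid), counts=counts))
    return out


def write_counts_table(path, samples: list[BinnedCounts], bins: pd.DataFrame) -> None:
    frames = []
    for s in samples:
        f = bins[["chrom", "start", "end"]].copy()
        f.insert(0, "sample_id", s.sample_id)
        f["count"] = s.counts
        frames.append(f)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def gc_from_fasta(bins: pd.DataFrame, fasta_path) -> pd.DataFrame:
    """Fill the ``gc`` column from a reference FASTA (requires pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    out = bins.copy()
    gc = np.full(len(bins), np.nan)
    for i, (chrom, start, end) in enumerate(zip(bins["chrom"], bins["start"], bins["end"])):
        if chrom not in fa:
            continue
        seq = str(fa[chrom][start - 1 : end]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt:
            gc[i] = (seq.count("G") + seq.count("C")) / acgt
    out["gc"] = gc
    return out
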
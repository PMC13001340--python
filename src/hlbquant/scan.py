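"""Genome-wide bin scans, gene-body matrices, clustering, DE merging.

The scan subdivides every chromosome into non-overlapping repeat-unit-sized
bins (5,080 bp by default, the size of the consensus histone repeat) anchored
at coordinate 0, sums the normalized signal within each, and ranks bins by
that sum; plotted with a cumulative genome coordinate and the consensus
chromosome last this reproduces the Manhattan layout in which the collapsed
repeat unit stands out against every single-copy bin.

Gene-level summaries scale every gene body to a fixed length (2,000 bp) with
fixed flanks (500 bp before the TSS and after the TES), aggregate into
10-bp columns, and cluster the resulting rows by Ward-linkage agglomerative
clustering on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.stats import rankdata

from .coverage import CoverageTrack

__all__ = [
    "bin_scan",
    "manhattan_table",
    "gene_matrix",
    "GeneSignalMatrix",
    "cluster_rows",
    "merge_signal_with_de",
]

logger = logging.getLogger(__name__)


def bin_scan(track: CoverageTrack, bin_len: int = 5080, require_hgc: bool = True) -> pd.DataFrame:
    """Sum signal in non-overlapping ``bin_len``-bp bins and rank the sums.

    Returns a table with chrom, start, end, signal, masked, partial and rank
    columns.  Bins tile each chromosome from position 0; a trailing partial
    bin is retained and flagged.  Bins containing any masked track bin are
    flagged masked, excluded from ranking, and their sums cover only the
    unmasked bases.  Ties share the minimum rank; rank 1 is the largest sum.
    """
    if require_hgc and track.state != "hgc":
        raise ValueError("bin scan expects an HGC-normalized track")
    b = track.bin_size
    if bin_len < b:
        raise ValueError("bin_len must be >= track bin size")
    if bin_len % b:
        raise ValueError("bin_len must be a multiple of the track bin size")
    per = bin_len // b

    frames = []
    for chrom, vals in track.values.items():
        length = track.chrom_lengths[chrom]
        n_bins = -(-len(vals) // per)
        pad = n_bins * per - len(vals)
        padded = np.concatenate([vals, np.zeros(pad)]) if pad else vals
        grid = padded.reshape(n_bins, per)
        sums = np.nansum(grid, axis=1) * b
        masked = np.isnan(grid).any(axis=1)
        starts = np.arange(n_bins, dtype=np.int64) * bin_len
        ends = np.minimum(starts + bin_len, length)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "signal": sums,
                    "masked": masked,
                    "partial": ends - starts < bin_len,
                }
            )
        )
    scan = pd.concat(frames, ignore_index=True)
    scan["rank"] = pd.array([pd.NA] * len(scan), dtype="Int64")
    unmasked = ~scan["masked"]
    ranks = rankdata(-scan.loc[unmasked, "signal"].to_numpy(), method="min")
    scan.loc[unmasked, "rank"] = ranks.astype(np.int64)
    return scan


def manhattan_table(
    scan: pd.DataFrame,
    consensus: str = "chrHis",
    chrom_order: list[str] | None = None,
    top_k: int = 5,
) -> pd.DataFrame:
    """Plot-ready table with a cumulative genome coordinate.

    Chromosomes keep assembly order with the consensus placed last, so the
    collapsed repeat unit appears at the far right.  The ``label`` column
    names the ``top_k`` highest-signal unmasked bins.
    """
    if scan.empty:
        raise ValueError("empty scan")
    if chrom_order is None:
        chrom_order = [c for c in dict.fromkeys(scan["chrom"]) if c != consensus]
        if (scan["chrom"] == consensus).any():
            chrom_order.append(consensus)
    offsets, cum = {}, 0
    for chrom in chrom_order:
        offsets[chrom] = cum
        cum += int(scan.loc[scan["chrom"] == chrom, "end"].max())
    out = scan[scan["chrom"].isin(chrom_order)].copy()
    out["cum_pos"] = out["start"] + out["chrom"].map(offsets)
    out.sort_values("cum_pos", inplace=True, ignore_index=True)
    out["label"] = ""
    top = out.loc[~out["masked"]].nlargest(top_k, "signal").index
    out.loc[top, "label"] = [
        f"{r.chrom}:{r.start}-{r.end}" for r in out.loc[top].itertuples()
    ]
    return out


# ---------------------------------------------------------------------------
# gene-body matrices


@dataclass
class GeneSignalMatrix:
    """Rows of flank + scaled-body + flank signal, sorted by total signal."""

    matrix: np.ndarray  # genes x (n_flank + n_body + n_flank)
    genes: list[str]
    totals: np.ndarray
    n_body_bins: int
    n_flank_bins: int
    labels: np.ndarray | None = None  # cluster labels, 1..k

    def to_frame(self) -> pd.DataFrame:
        cols = (
            [f"up_{i}" for i in range(self.n_flank_bins)]
            + [f"body_{i}" for i in range(self.n_body_bins)]
            + [f"down_{i}" for i in range(self.n_flank_bins)]
        )
        df = pd.DataFrame(self.matrix, index=self.genes, columns=cols)
        df.insert(0, "total", self.totals)
        if self.labels is not None:
            df.insert(1, "cluster", self.labels)
        return df


def _per_base(track: CoverageTrack, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-base signal over [start, end); positions off the chromosome are 0."""
    vals = track.values[chrom]
    length = track.chrom_lengths[chrom]
    out = np.zeros(end - start)
    lo, hi = max(start, 0), min(end, length)
    if hi > lo:
        idx = np.arange(lo, hi) // track.bin_size
        out[lo - start : hi - start] = vals[idx]
    return out


def _rescale(values: np.ndarray, n_cols: int) -> np.ndarray:
    """Aggregate per-base values into n_cols columns by (nan)mean.

    The body is linearly rescaled: column j averages source positions
    [j*n/n_cols, (j+1)*n/n_cols).  Bodies shorter than the column count are
    sampled by interpolation at column centres.
    """
    n = len(values)
    if n == 0:
        return np.zeros(n_cols)
    if n < n_cols:
        src = (np.arange(n_cols) + 0.5) * n / n_cols
        filled = np.nan_to_num(values)
        return np.interp(src, np.arange(n) + 0.5, filled)
    edges = np.floor(np.arange(n_cols + 1) * n / n_cols).astype(int)
    out = np.empty(n_cols)
    for j in range(n_cols):
        seg = values[edges[j] : edges[j + 1]]
        m = np.nanmean(seg) if np.isfinite(seg).any() else 0.0
        out[j] = m
    return out


def gene_matrix(
    track: CoverageTrack,
    genes: pd.DataFrame,
    body_length: int = 2000,
    flank: int = 500,
    n_body_bins: int = 200,
    n_flank_bins: int = 50,
) -> GeneSignalMatrix:
    """Scaled gene-body signal matrix (flank | scaled body | flank).

    ``genes`` is BED6-like (chrom, start, end, name, score, strand).  Bodies
    are rescaled to ``body_length`` via mean aggregation into
    ``n_body_bins`` columns; flanks use ``n_flank_bins`` columns each.
    Minus-strand rows are reversed so every row reads TSS-left.  Rows are
    sorted by descending total signal.
    """
    rows, names, totals = [], [], []
    for g in genes.itertuples():
        if g.chrom not in track.values:
            raise ValueError(f"gene {g.name} on unknown chromosome {g.chrom!r}")
        if g.start < 0 or g.end > track.chrom_lengths[g.chrom] or g.end <= g.start:
            raise ValueError(f"gene {g.name} outside chromosome bounds")
        up = _rescale(_per_base(track, g.chrom, g.start - flank, g.start), n_flank_bins)
        body = _rescale(_per_base(track, g.chrom, g.start, g.end), n_body_bins)
        down = _rescale(_per_base(track, g.chrom, g.end, g.end + flank), n_flank_bins)
        row = np.concatenate([up, body, down])
        strand = getattr(g, "strand", "+")
        if strand == "-":
            row = row[::-1]
        rows.append(row)
        names.append(g.name)
        totals.append(np.nansum(_per_base(track, g.chrom, g.start, g.end)))
    matrix = np.vstack(rows) if rows else np.empty((0, n_body_bins + 2 * n_flank_bins))
    totals = np.asarray(totals)
    order = np.argsort(-totals, kind="stable")
    return GeneSignalMatrix(
        matrix=matrix[order],
        genes=[names[i] for i in order],
        totals=totals[order],
        n_body_bins=n_body_bins,
        n_flank_bins=n_flank_bins,
    )


def cluster_rows(matrix: GeneSignalMatrix | np.ndarray, k: int = 3) -> np.ndarray:
    """Ward-linkage agglomerative clustering of matrix rows.

    Returns labels 1..k.  Labels are canonicalized by descending cluster mean
    row sum (cluster 1 carries the strongest signal), so the partition and
    its labelling are invariant to row order.
    """
    X = matrix.matrix if isinstance(matrix, GeneSignalMatrix) else np.asarray(matrix)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError("k cannot exceed the number of rows")
    if k == n:
        labels = np.arange(1, n + 1)
    else:
        Z = _hier.linkage(X, method="ward")
        labels = _hier.fcluster(Z, t=k, criterion="maxclust")
    # canonical numbering: order clusters by descending mean row sum
    sums = X.sum(axis=1)
    means = {lab: sums[labels == lab].mean() for lab in np.unique(labels)}
    order = sorted(means, key=lambda lab: (-means[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    labels = np.array([remap[lab] for lab in labels])
    if isinstance(matrix, GeneSignalMatrix):
        matrix.labels = labels
    return labels


def merge_signal_with_de(signal: pd.DataFrame, de: pd.DataFrame) -> pd.DataFrame:
    """Inner-join per-gene summed signal with a differential-expression table.

    ``signal`` needs gene/signal columns; ``de`` needs gene/log2fc/padj.
    Unmatched genes on either side are reported to the module logger; zero
    overlap is an error.  The result is sorted by descending signal.
    """
    merged = signal.merge(de, on="gene", how="inner")
    only_sig = len(signal) - len(merged)
    only_de = len(de) - len(merged)
    if merged.empty:
        raise ValueError(
            f"no shared gene identifiers (signal-only: {only_sig}, DE-only: {only_de})"
        )
    if only_sig or only_de:
        logger.info("merge_signal_with_de: %d signal-only, %d DE-only genes dropped", only_sig, only_de)
    return merged.sort_values("signal", ascending=False, ignore_index=True)
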
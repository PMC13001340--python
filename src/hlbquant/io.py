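"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, TIFF via tifffile, BAM fragment input via pysam,
tables (BED/TSV/bedGraph) via pandas.  All interval tables use 0-based
half-open coordinates in memory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coverage import CoverageTrack

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def write_fasta(sequences: Mapping[str, bytes | str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq.decode() if isinstance(seq, bytes) else seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, bytes]:
    return {rec.id: bytes(str(rec.seq), "ascii") for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLS[: df.shape[1]] + list(df.columns[6:])
    return df


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Fragment intervals from BED3/TSV or BAM (coordinates only)."""
    path = Path(path)
    if path.suffix.lower() in {".bam", ".sam", ".cram"}:
        import pysam

        rows = []
        with pysam.AlignmentFile(str(path), check_sq=False) as bam:
            for read in bam:
                if read.is_unmapped or read.reference_start is None:
                    continue
                rows.append((read.reference_name, read.reference_start, read.reference_end))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])
    first = open(path).readline()
    header = 0 if first.lower().startswith("chrom") else None
    df = pd.read_csv(path, sep="\t", header=header)
    if header is None:
        df.columns = ["chrom", "start", "end"] + list(df.columns[3:])
    return df


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """4-column bedGraph, one line per constant-value run; masked bins skipped."""
    with open(path, "w") as fh:
        for chrom, vals in track.values.items():
            length = track.chrom_lengths[chrom]
            b = track.bin_size
            change = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if np.isnan(v):
                    continue
                fh.write(f"{chrom}\t{s * b}\t{min(e * b, length)}\t{v:.10g}\n")


def read_bedgraph(path: str | Path, chrom_lengths: Mapping[str, int], bin_size: int, state: str = "raw") -> CoverageTrack:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    values = {}
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_size)
        arr = np.full(n_bins, np.nan)
        sub = df[df["chrom"] == chrom]
        for row in sub.itertuples():
            arr[row.start // bin_size : -(-row.end // bin_size)] = row.value
        values[chrom] = arr
    return CoverageTrack(values=values, chrom_lengths=dict(chrom_lengths), bin_size=bin_size, state=state)


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), stack)


def read_stack(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
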
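"""Binned fragment coverage with CPM and per-gene-copy (HGC) normalization.

A :class:`CoverageTrack` stores, per chromosome, one value per fixed-size
bin.  The bin value is the summed per-base fragment depth in the bin divided
by the (nominal) bin size, i.e. the mean per-base depth with off-end bases of
a trailing partial bin counted as zero.  That convention makes the mass
identity ``sum(bin values) * bin_size == total fragment bases`` exact, which
downstream bin scans rely on.

Normalization states form a one-way chain raw -> CPM -> HGC:

CPM
    counts per million mapped fragments: every value is scaled by
    ``1e6 / total_fragments`` (paired-end fragment-count semantics).
HGC
    per-histone-gene-copy: values on the consensus repeat chromosome are
    divided by the array copy number (100 by default) so that multi-copy
    signal is comparable in scale to single-copy loci.  Also written "HCG"
    in places; this package standardizes on HGC.  The normalization is
    losslessly invertible: because IEEE-754 guarantees no float64 ``y``
    with ``fl(y * 100) == x`` for roughly one value of ``x`` in ten, an HGC
    track retains the pre-division CPM array of the consensus chromosome,
    and :meth:`CoverageTrack.hgc_times_copy_number` returns it bit-exactly.

Blacklisted regions are masked to NaN at bin resolution (any overlap masks
the bin) and are excluded from every downstream sum.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "compute_coverage",
    "to_cpm",
    "apply_hgc",
    "mask_blacklist",
]


@dataclass
class CoverageTrack:
    values: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    bin_size: int
    state: str = "raw"  # raw | cpm | hgc
    total_fragments: float | None = None
    hgc_chrom: str | None = None
    copy_number: int | None = None
    n_masked_bins: int = 0
    _consensus_cpm: np.ndarray | None = None

    def copy(self) -> "CoverageTrack":
        new = _copy.copy(self)
        new.values = {c: v.copy() for c, v in self.values.items()}
        return new

    def hgc_times_copy_number(self) -> np.ndarray:
        """Exact inverse of the HGC scaling: the consensus CPM values.

        Returned from the stored pre-division representation, so the
        identity HGC x copy_number == CPM holds bit for bit; recomputing
        ``values * copy_number`` in floats would re-round and lose it.
        """
        if self.state != "hgc" or self._consensus_cpm is None:
            raise ValueError("track is not HGC-normalized")
        return self._consensus_cpm.copy()

    def mass(self) -> float:
        """Total signal mass: sum(bin values) * bin_size over unmasked bins."""
        return float(sum(np.nansum(v) for v in self.values.values()) * self.bin_size)


def _bin_sums(depth: np.ndarray, bin_size: int) -> np.ndarray:
    n_bins = -(-len(depth) // bin_size)
    pad = n_bins * bin_size - len(depth)
    if pad:
        depth = np.concatenate([depth, np.zeros(pad)])
    return depth.reshape(n_bins, bin_size).sum(axis=1)


def compute_coverage(
    fragments: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    bin_size: int = 2,
) -> CoverageTrack:
    """Binned mean per-base depth from fragment intervals.

    ``fragments`` needs chrom/start/end columns (0-based half-open) and may
    carry a ``weight`` column; each piece of a junction-wrapped fragment
    contributes depth at its own location only.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    unknown = set(fragments["chrom"].unique()) - set(chrom_lengths)
    if unknown:
        raise ValueError(f"fragments on unknown chromosomes: {sorted(unknown)}")

    weights = (
        fragments["weight"].to_numpy(dtype=np.float64)
        if "weight" in fragments.columns
        else np.ones(len(fragments))
    )
    values: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        sel = (fragments["chrom"] == chrom).to_numpy()
        starts = fragments["start"].to_numpy(dtype=np.int64)[sel]
        ends = fragments["end"].to_numpy(dtype=np.int64)[sel]
        if len(starts) and (starts.min() < 0 or ends.max() > length):
            raise ValueError(f"fragment outside chromosome {chrom}")
        diff = np.zeros(length + 1)
        np.add.at(diff, starts, weights[sel])
        np.add.at(diff, ends, -weights[sel])
        depth = np.cumsum(diff[:-1])
        values[chrom] = _bin_sums(depth, bin_size) / bin_size
    return CoverageTrack(
        values=values,
        chrom_lengths=dict(chrom_lengths),
        bin_size=bin_size,
        state="raw",
    )


def to_cpm(track: CoverageTrack, total_fragments: float) -> CoverageTrack:
    """Counts-per-million scaling: multiply every bin by 1e6/total_fragments."""
    if track.state != "raw":
        raise ValueError(f"CPM requires a raw track, got state {track.state!r}")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be > 0")
    out = track.copy()
    scale = 1e6 / total_fragments
    for chrom in out.values:
        out.values[chrom] = out.values[chrom] * scale
    out.state = "cpm"
    out.total_fragments = float(total_fragments)
    return out


def apply_hgc(track: CoverageTrack, consensus: str = "chrHis", copy_number: int = 100) -> CoverageTrack:
    """Per-gene-copy scaling of the consensus chromosome (CPM -> HGC).

    Consensus values are divided by ``copy_number`` exactly once; all other
    chromosomes are untouched.  The pre-division CPM array is retained so
    the scaling can be inverted without floating-point re-rounding (see
    :meth:`CoverageTrack.hgc_times_copy_number`).
    """
    if track.state != "cpm":
        raise ValueError(f"HGC requires a CPM track, got state {track.state!r}")
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")
    if consensus not in track.values:
        raise ValueError(f"consensus chromosome {consensus!r} absent from track")
    out = track.copy()
    out._consensus_cpm = out.values[consensus].copy()
    out.values[consensus] = out.values[consensus] / float(copy_number)
    out.state = "hgc"
    out.hgc_chrom = consensus
    out.copy_number = copy_number
    return out


def mask_blacklist(track: CoverageTrack, intervals: Iterable[tuple[str, int, int]] | pd.DataFrame) -> CoverageTrack:
    """Mask (NaN) every bin overlapping a blacklist interval.

    Any overlap at bin resolution masks the whole bin (conservative
    exclusion).  Intervals are 0-based half-open (chrom, start, end).
    """
    if isinstance(intervals, pd.DataFrame):
        intervals = intervals[["chrom", "start", "end"]].itertuples(index=False)
    out = track.copy()
    n_masked = 0
    b = out.bin_size
    for chrom, start, end in intervals:
        if chrom not in out.values:
            raise ValueError(f"blacklist interval on unknown chromosome {chrom!r}")
        if not (0 <= start < end <= out.chrom_lengths[chrom]):
            raise ValueError(f"malformed blacklist interval {chrom}:{start}-{end}")
        lo = start // b
        hi = -(-end // b)
        vals = out.values[chrom]
        n_masked += int(np.isfinite(vals[lo:hi]).sum())
        vals[lo:hi] = np.nan
    out.n_masked_bins = out.n_masked_bins + n_masked
    return out
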
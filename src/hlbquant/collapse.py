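"""Collapsed-repeat reference construction and fragment projection.

A tandem array of C copies of an L-bp unit cannot be mapped uniquely, so the
reference is rebuilt with the whole array interval excised and a single
consensus unit appended as its own chromosome (named ``chrHis`` by default).
Fragments simulated (or aligned) against the *expanded* genome are then
projected deterministically onto this collapsed assembly:

* fragments wholly inside the array map to consensus offset
  ``(position - array start) mod L``;
* fragments spanning a copy-copy junction wrap across the consensus end and
  are emitted as two pieces flagged ``wrapped`` (the repeat is head-to-tail,
  so the consensus unit is treated as circular; switchable);
* fragments upstream of the array are unchanged; fragments downstream shift
  left by the expanded array span;
* fragments straddling the array's outer boundary have no unambiguous
  collapsed location and are dropped (counted).

Internal fragment coordinates are 0-based half-open; printed intervals are
1-based inclusive and converted only at this I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .simulate import SimulatedGenome

__all__ = [
    "CollapsedAssembly",
    "ArrayLocation",
    "ProjectionResult",
    "build_collapsed_reference",
    "project_fragments",
]


@dataclass(frozen=True)
class ArrayLocation:
    """Expanded-genome location of the tandem array (0-based half-open)."""

    chrom: str
    start: int
    end: int
    unit_length: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.unit_length * self.copy_number:
            raise ValueError("array span must equal unit_length * copy_number")

    @classmethod
    def from_genome(cls, genome: SimulatedGenome) -> "ArrayLocation":
        return cls(
            chrom=genome.array_chrom,
            start=genome.array_start0,
            end=genome.array_end0,
            unit_length=genome.spec.unit_length,
            copy_number=genome.spec.copy_number,
        )


@dataclass(frozen=True)
class CollapsedAssembly:
    """Reference with the array excised and one consensus unit appended.

    ``excised_start``/``excised_end`` record the printed (1-based inclusive)
    native interval.  ``copy_number`` is an independent parameter and never
    inferred from the excised span, which may be under-assembled.
    """

    chrom_lengths: Mapping[str, int]  # post-excision, consensus included last
    consensus_name: str
    unit_length: int
    excised_chrom: str
    excised_start: int  # 1-based inclusive
    excised_end: int  # 1-based inclusive
    copy_number: int

    @property
    def excised_span(self) -> int:
        return self.excised_end - self.excised_start + 1

    @property
    def downstream_shift(self) -> int:
        """How far native coordinates downstream of the array move left."""
        return self.excised_span


def build_collapsed_reference(
    sequences: Mapping[str, bytes | str],
    array_chrom: str,
    array_start: int,
    array_end: int,
    unit_seq: bytes | str,
    copy_number: int,
    consensus_name: str = "chrHis",
) -> tuple[CollapsedAssembly, dict[str, bytes]]:
    """Excise the printed array interval and append one consensus unit.

    ``array_start``/``array_end`` are 1-based inclusive, as printed.  Returns
    the assembly description and the new sequence set (consensus last).
    """
    if array_chrom not in sequences:
        raise ValueError(f"chromosome {array_chrom!r} not in assembly")
    if not unit_seq:
        raise ValueError("unit sequence must be non-empty")
    if copy_number < 1:
        raise ValueError("copy_number must be >= 1")

    def as_bytes(s: bytes | str) -> bytes:
        return s.encode() if isinstance(s, str) else bytes(s)

    unit = as_bytes(unit_seq)
    src = as_bytes(sequences[array_chrom])
    if not (1 <= array_start <= array_end <= len(src)):
        raise ValueError("array interval outside chromosome")

    out: dict[str, bytes] = {}
    for name, seq in sequences.items():
        if name == array_chrom:
            out[name] = src[: array_start - 1] + src[array_end:]
        else:
            out[name] = as_bytes(seq)
    out[consensus_name] = unit

    assembly = CollapsedAssembly(
        chrom_lengths={name: len(seq) for name, seq in out.items()},
        consensus_name=consensus_name,
        unit_length=len(unit),
        excised_chrom=array_chrom,
        excised_start=array_start,
        excised_end=array_end,
        copy_number=copy_number,
    )
    return assembly, out


@dataclass
class ProjectionResult:
    """Projected fragments plus bookkeeping counters.

    ``fragments`` holds one row per emitted piece (chrom, start, end, weight,
    wrapped, frag_id); a junction-wrapping fragment contributes two rows with
    the same ``frag_id``.  ``n_projected`` counts distinct projected
    fragments (the denominator for CPM normalization).
    """

    fragments: pd.DataFrame
    n_input: int
    n_projected: int
    dropped_boundary: int
    dropped_junction: int

    @property
    def total_bases(self) -> int:
        if self.fragments.empty:
            return 0
        return int((self.fragments["end"] - self.fragments["start"]).sum())


def project_fragments(
    fragments: pd.DataFrame,
    array: ArrayLocation,
    consensus_name: str = "chrHis",
    wrap: bool = True,
) -> ProjectionResult:
    """Project expanded-coordinate fragments onto the collapsed assembly.

    Vectorised modulo arithmetic; see the module docstring for the mapping
    rules.  Fragments longer than the unit cannot be represented on the
    consensus and are rejected.
    """
    chrom = fragments["chrom"].to_numpy()
    start = fragments["start"].to_numpy(dtype=np.int64)
    end = fragments["end"].to_numpy(dtype=np.int64)
    if (start < 0).any() or (end <= start).any():
        raise ValueError("malformed fragment intervals")
    n = len(fragments)
    frag_id = np.arange(n, dtype=np.int64)
    L = array.unit_length
    span = array.end - array.start

    on_chrom = chrom == array.chrom
    upstream = on_chrom & (end <= array.start)
    downstream = on_chrom & (start >= array.end)
    inside = on_chrom & (start >= array.start) & (end <= array.end)
    boundary = on_chrom & ~upstream & ~downstream & ~inside
    off = ~on_chrom

    if ((end[inside] - start[inside]) > L).any():
        raise ValueError("fragment longer than the repeat unit cannot be projected")

    pieces = []

    def emit(chroms, s, e, wrapped, ids):
        pieces.append(
            pd.DataFrame(
                {"chrom": chroms, "start": s, "end": e, "weight": 1.0, "wrapped": wrapped, "frag_id": ids}
            )
        )

    if off.any():
        emit(chrom[off], start[off], end[off], False, frag_id[off])
    if upstream.any():
        emit(chrom[upstream], start[upstream], end[upstream], False, frag_id[upstream])
    if downstream.any():
        emit(chrom[downstream], start[downstream] - span, end[downstream] - span, False, frag_id[downstream])

    dropped_junction = 0
    if inside.any():
        off0 = (start[inside] - array.start) % L
        flen = end[inside] - start[inside]
        end_off = off0 + flen
        plain = end_off <= L
        emit(
            np.full(int(plain.sum()), consensus_name, dtype=object),
            off0[plain],
            end_off[plain],
            False,
            frag_id[inside][plain],
        )
        crossing = ~plain
        if crossing.any():
            if wrap:
                ids = frag_id[inside][crossing]
                emit(np.full(len(ids), consensus_name, dtype=object), off0[crossing], np.full(len(ids), L), True, ids)
                emit(np.full(len(ids), consensus_name, dtype=object), np.zeros(len(ids), dtype=np.int64), end_off[crossing] - L, True, ids)
            else:
                dropped_junction = int(crossing.sum())

    out = (
        pd.concat(pieces, ignore_index=True)
        if pieces
        else pd.DataFrame(columns=["chrom", "start", "end", "weight", "wrapped", "frag_id"])
    )
    n_projected = out["frag_id"].nunique()
    return ProjectionResult(
        fragments=out,
        n_input=n,
        n_projected=int(n_projected),
        dropped_boundary=int(boundary.sum()),
        dropped_junction=dropped_junction,
    )
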
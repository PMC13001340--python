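"""Synthetic-data generators with known ground truth.

Every downstream stage of the package can be exercised without any external
download: this module fabricates (i) genomes carrying an expanded tandem
array of a repeat unit, (ii) aligned sequencing-like fragments with a
configurable per-copy enrichment over uniform background, (iii) ventral
nerve cord (VNC)-like fluorescence z-stacks whose cytoplasmic histone-mRNA
signal depends on cell-cycle phase and genotype mode, and (iv) RT-qPCR Ct
tables with a reference gene.

All generators are deterministic for a fixed seed.  Sub-seeds for pipeline
stages are derived from one root seed via ``numpy.random.SeedSequence`` with
a fixed per-stage spawn key (see :func:`stage_rng`), so stages can be re-run
independently and still reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "SimGenomeSpec",
    "SimulatedGenome",
    "FragmentSimParams",
    "ImageSimParams",
    "CtSimParams",
    "stage_rng",
    "simulate_genome",
    "simulate_fragments",
    "simulate_vnc_stack",
    "simulate_ct_table",
    "DEFAULT_PROBES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Named stages hash to fixed spawn keys so that e.g. the fragment generator
# for replicate 3 always sees the same stream regardless of what else ran.
_STAGE_KEYS = {"genome": 0, "fragments": 1, "image": 2, "ct": 3}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Deterministic per-stage generator derived from one root seed.

    The stream is ``default_rng(SeedSequence(seed, spawn_key=(stage_key,
    index)))`` where ``stage_key`` is a fixed small integer per stage name.
    """
    key = _STAGE_KEYS[stage]
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key, index)))


# ---------------------------------------------------------------------------
# genomes


@dataclass(frozen=True)
class SimGenomeSpec:
    """Layout of a genome containing one tandem repeat array.

    ``array_start``/``array_end`` use the 1-based inclusive convention of
    printed genome-browser coordinates and describe the *native* (possibly
    under-assembled) array interval; the expanded genome replaces that
    interval with exactly ``copy_number`` head-to-tail copies of the unit.
    """

    chrom_lengths: Mapping[str, int]
    array_chrom: str
    array_start: int  # 1-based inclusive
    array_end: int  # 1-based inclusive
    unit_length: int = 5080
    copy_number: int = 100
    unit_seq: str | None = None  # random (seeded) when None

    def __post_init__(self) -> None:
        if self.array_chrom not in self.chrom_lengths:
            raise ValueError(f"array chromosome {self.array_chrom!r} not in genome")
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if not (1 <= self.array_start <= self.array_end <= self.chrom_lengths[self.array_chrom]):
            raise ValueError("array interval must lie within its chromosome")
        if self.unit_seq is not None and len(self.unit_seq) != self.unit_length:
            raise ValueError("unit sequence length must equal unit_length")

    @property
    def native_span(self) -> int:
        """Length of the declared (native) array interval in bp."""
        return self.array_end - self.array_start + 1


@dataclass(frozen=True)
class SimulatedGenome:
    """Expanded genome: array interval replaced by ``copy_number`` unit copies.

    Coordinates of the expanded array are 0-based half-open.  ``copies`` is a
    BED-like table of the true per-copy boundaries.
    """

    sequences: Mapping[str, bytes]
    spec: SimGenomeSpec
    array_start0: int
    array_end0: int
    copies: pd.DataFrame = field(repr=False)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def array_chrom(self) -> str:
        return self.spec.array_chrom


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def simulate_genome(spec: SimGenomeSpec, seed: int = 0, strict: bool = False) -> SimulatedGenome:
    """Build an expanded genome with ``copy_number`` tandem copies of the unit.

    Parameters
    ----------
    spec : SimGenomeSpec
    seed : int
        Seeds background (and, if unspecified, unit) sequence content.
    strict : bool
        Require the declared native interval length to equal
        ``copy_number * unit_length``.  The native histone locus is only
        partially assembled, so by default the expanded array is allowed to
        be longer than the declared interval.
    """
    C, L = spec.copy_number, spec.unit_length
    if strict and spec.native_span != C * L:
        raise ValueError(
            f"strict mode: native span {spec.native_span} != copy_number*unit_length {C * L}"
        )
    rng = stage_rng(seed, "genome")
    if spec.unit_seq is None:
        unit = _random_sequence(rng, L)
    else:
        unit = np.frombuffer(spec.unit_seq.upper().encode(), dtype=np.uint8)

    sequences: dict[str, bytes] = {}
    for name, length in spec.chrom_lengths.items():
        bg = _random_sequence(rng, length)
        if name == spec.array_chrom:
            left = bg[: spec.array_start - 1]
            right = bg[spec.array_end :]
            arr = np.tile(unit, C)
            sequences[name] = np.concatenate([left, arr, right]).tobytes()
        else:
            sequences[name] = bg.tobytes()

    start0 = spec.array_start - 1
    end0 = start0 + C * L
    copies = pd.DataFrame(
        {
            "chrom": spec.array_chrom,
            "start": start0 + L * np.arange(C),
            "end": start0 + L * (np.arange(C) + 1),
            "name": [f"copy_{i + 1:04d}" for i in range(C)],
            "score": 0,
            "strand": "+",
        }
    )
    return SimulatedGenome(sequences=sequences, spec=spec, array_start0=start0, array_end0=end0, copies=copies)


# ---------------------------------------------------------------------------
# fragments


@dataclass(frozen=True)
class FragmentSimParams:
    """Sampling law for sequencing-like fragments.

    Start positions are drawn with per-bp weight ``background_rate``
    everywhere, multiplied by ``enrichment`` inside the (expanded) array and
    by ``fold`` inside each optional off-target peak.  Fragment lengths are
    truncated-normal; the default Normal(150, 30) truncated to [50, 700]
    reflects typical nuclease-released chromatin fragments bounded by the
    common 700-bp upper alignment limit for paired ends.
    """

    n_fragments: int
    enrichment: float = 1.0
    length_mean: float = 150.0
    length_sd: float = 30.0
    length_min: int = 50
    length_max: int = 700
    background_rate: float = 1.0
    off_target_peaks: Sequence[tuple[str, int, int, float]] = ()  # chrom, start0, end0, fold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")
        if self.enrichment < 0:
            raise ValueError("enrichment must be >= 0")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("invalid fragment length bounds")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be > 0")


def start_weights(genome: SimulatedGenome, params: FragmentSimParams) -> dict[str, np.ndarray]:
    """Per-bp fragment-start sampling weights for each chromosome."""
    weights = {}
    for name, length in genome.chrom_lengths.items():
        w = np.full(length, params.background_rate)
        if name == genome.array_chrom:
            w[genome.array_start0 : genome.array_end0] *= params.enrichment
        for chrom, s, e, fold in params.off_target_peaks:
            if chrom == name:
                w[s:e] *= fold
        weights[name] = w
    return weights


def simulate_fragments(
    genome: SimulatedGenome,
    params: FragmentSimParams,
    _cumweights: tuple[list[str], np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Sample fragments (chrom, start, end; 0-based half-open) from the genome.

    ``_cumweights`` may carry a precomputed ``(chrom_order, offsets, cumsum)``
    triple (from repeated calls with identical genome/weights) purely as a
    speed-up; results are identical with or without it.
    """
    if params.n_fragments == 0:
        return pd.DataFrame({"chrom": pd.Series([], dtype=str), "start": pd.Series([], dtype=np.int64), "end": pd.Series([], dtype=np.int64)})

    if _cumweights is None:
        _cumweights = fragment_sampler_state(genome, params)
    chrom_order, offsets, cum = _cumweights

    rng = stage_rng(params.seed, "fragments")
    total = cum[-1]
    u = rng.random(params.n_fragments) * total
    pos = np.searchsorted(cum, u, side="right")
    chrom_idx = np.searchsorted(offsets[1:], pos, side="right")
    start = pos - offsets[chrom_idx]

    a = (params.length_min - params.length_mean) / params.length_sd
    b = (params.length_max - params.length_mean) / params.length_sd
    lengths = _st.truncnorm.rvs(
        a, b, loc=params.length_mean, scale=params.length_sd, size=params.n_fragments, random_state=rng
    )
    lengths = np.maximum(np.rint(lengths).astype(np.int64), 1)

    chrom_lens = np.array([genome.chrom_lengths[c] for c in chrom_order])
    end = np.minimum(start + lengths, chrom_lens[chrom_idx])
    chroms = np.array(chrom_order, dtype=object)[chrom_idx]
    return pd.DataFrame({"chrom": chroms, "start": start, "end": end})


def fragment_sampler_state(
    genome: SimulatedGenome, params: FragmentSimParams
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Precompute the concatenated cumulative start-weight table."""
    weights = start_weights(genome, params)
    chrom_order = list(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chrom_order], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    cum = np.cumsum(np.concatenate([weights[c] for c in chrom_order]))
    return chrom_order, offsets, cum


# ---------------------------------------------------------------------------
# VNC-like image stacks


@dataclass(frozen=True)
class ImageSimParams:
    """Rendering law for a VNC-like field of cells.

    In ``wildtype`` mode only S-phase cells accumulate cytoplasmic signal,
    drawn around ``max_intensity``; in ``mutant`` mode every cell in an
    expressing phase (default S, G2 and M: expression uncoupled from S phase)
    accumulates signal around ``mutant_factor * max_intensity``.  Cytoplasmic
    signal is rendered as an annulus around each nucleus; sub-cellular
    realism beyond that is deliberately out of scope because the histogram
    quantification uses whole-field pixels.

    Defaults describe the study conditions: a 100x100 um field at 0.2 um
    pixels, six 0.3-um z-slices (the stack spans exactly the 1.8-um analysis
    window), 250 cells of radius 2.5 um on a jittered grid, and phase
    fractions S=0.4, G2=0.4, M=0.2 (condensed S-G2-M cycle; no G1).
    """

    max_intensity: float
    intensity_range: int  # histogram upper bin; pixels never exceed it
    mutant_factor: float = 1.0
    genotype_mode: str = "wildtype"
    field_size_um: tuple[float, float] = (100.0, 100.0)
    pixel_size_um: float = 0.2
    z_step_um: float = 0.3
    n_slices: int = 6
    n_cells: int = 250
    cell_radius_um: float = 2.5
    phase_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"G1": 0.0, "S": 0.4, "G2": 0.4, "M": 0.2}
    )
    expressing_phases: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "wildtype": frozenset({"S"}),
            "mutant": frozenset({"S", "G2", "M"}),
        }
    )
    background_mean: float = 5.0
    background_sd: float = 2.0
    amplitude_cv: float = 0.1  # cell-to-cell spread of signal amplitude
    pixel_cv: float = 0.15  # within-annulus per-pixel texture
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.phase_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("phase fractions must sum to 1")
        if not (0.0 < self.mutant_factor <= 1.0):
            raise ValueError("mutant_factor must be in (0, 1]")
        if self.genotype_mode not in self.expressing_phases:
            raise ValueError(f"unknown genotype mode {self.genotype_mode!r}")
        if self.intensity_range < 1:
            raise ValueError("intensity_range must be >= 1")


# Per-probe defaults: (max sum-projection intensity, mutant max-output factor,
# histogram range).  Max intensities follow the printed per-probe display
# maxima; the reduced-max probes use factor 0.4 = d_S/(d_S+d_G2+d_M) so that
# extending expression over the whole condensed cycle conserves total output.
DEFAULT_PROBES: dict[str, tuple[float, float, int]] = {
    "H3": (450.0, 1.0, 699),
    "H2a": (375.0, 0.4, 699),
    "H1": (615.0, 0.4, 1399),
    "CDS": (615.0, 1.0, 1399),
}


def _place_cells(rng: np.random.Generator, params: ImageSimParams, ny: int, nx: int) -> np.ndarray:
    """Jittered-grid cell centres (y, x) in pixels; rejects unpackable fields."""
    r_px = params.cell_radius_um / params.pixel_size_um
    spacing = math.sqrt(ny * nx / max(params.n_cells, 1))
    if spacing < 2.0 * r_px * 0.9 or params.n_cells > (ny * nx) / (math.pi * r_px**2):
        raise ValueError(
            f"cannot pack {params.n_cells} cells of radius {r_px:.1f} px into a {ny}x{nx} field"
        )
    gy = max(int(ny // spacing), 1)
    gx = max(int(nx // spacing), 1)
    while gy * gx < params.n_cells:
        gx += 1
    cell_y = (np.arange(gy) + 0.5) * (ny / gy)
    cell_x = (np.arange(gx) + 0.5) * (nx / gx)
    centers = np.stack(np.meshgrid(cell_y, cell_x, indexing="ij"), axis=-1).reshape(-1, 2)
    idx = rng.choice(len(centers), size=params.n_cells, replace=False)
    jitter_amp = max(min(ny / gy, nx / gx) / 2.0 - r_px, 0.0)
    jitter = rng.uniform(-jitter_amp, jitter_amp, size=(params.n_cells, 2))
    pts = centers[idx] + jitter
    pts[:, 0] = np.clip(pts[:, 0], r_px, ny - r_px - 1)
    pts[:, 1] = np.clip(pts[:, 1], r_px, nx - r_px - 1)
    return pts


def annulus_offsets(params: ImageSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Pixel offsets of the cytoplasmic annulus (between 0.5r and r)."""
    r = params.cell_radius_um / params.pixel_size_um
    rad = int(math.ceil(r))
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    d2 = dy**2 + dx**2
    mask = (d2 <= r**2) & (d2 >= (0.5 * r) ** 2)
    return dy[mask], dx[mask]


def simulate_vnc_stack(params: ImageSimParams) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a z-stack of a VNC-like field plus its ground-truth cell table.

    Returns
    -------
    stack : uint16 array, shape (n_slices, ny, nx)
        Pixel sums over the full stack never exceed ``intensity_range``.
    cells : DataFrame
        One row per cell: y, x (pixels), phase, expressing, amplitude
        (expected contribution of the cell to the summed projection).
    """
    rng = stage_rng(params.seed, "image")
    ny = int(round(params.field_size_um[0] / params.pixel_size_um))
    nx = int(round(params.field_size_um[1] / params.pixel_size_um))
    k = params.n_slices

    centers = _place_cells(rng, params, ny, nx) if params.n_cells else np.empty((0, 2))
    phases = list(params.phase_fractions)
    probs = np.array([params.phase_fractions[p] for p in phases])
    phase_of = rng.choice(len(phases), size=params.n_cells, p=probs / probs.sum()) if params.n_cells else np.array([], int)
    expressing_set = params.expressing_phases[params.genotype_mode]
    expressing = np.array([phases[i] in expressing_set for i in phase_of], dtype=bool)

    level = params.max_intensity
    if params.genotype_mode == "mutant":
        level = params.mutant_factor * params.max_intensity
    amplitudes = np.zeros(params.n_cells)
    n_exp = int(expressing.sum())
    if n_exp:
        draw = rng.normal(level, params.amplitude_cv * level, size=n_exp)
        amplitudes[expressing] = np.clip(draw, 0.0, None)

    # signal budget: the summed projection must stay within intensity_range
    # even on top of (truncated) background noise in every slice
    bg_cap = params.background_mean + 6.0 * params.background_sd
    signal_cap = max(params.intensity_range - k * bg_cap, 0.0)

    signal = np.zeros((ny, nx))
    dy, dx = annulus_offsets(params)
    for (cy, cx), amp in zip(centers, amplitudes):
        if amp <= 0:
            continue
        yy = np.rint(cy + dy).astype(int)
        xx = np.rint(cx + dx).astype(int)
        ok = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
        vals = amp * np.clip(rng.normal(1.0, params.pixel_cv, size=ok.sum()), 0.0, None)
        np.maximum.at(signal, (yy[ok], xx[ok]), vals)
    np.clip(signal, 0.0, signal_cap, out=signal)

    stack = np.empty((k, ny, nx), dtype=np.uint16)
    per_slice = signal / k
    for z in range(k):
        noise = rng.normal(params.background_mean, params.background_sd, size=(ny, nx))
        np.clip(noise, 0.0, bg_cap, out=noise)
        stack[z] = np.rint(per_slice + noise).astype(np.uint16)

    cells = pd.DataFrame(
        {
            "cell": np.arange(params.n_cells),
            "y": centers[:, 0] if params.n_cells else np.array([]),
            "x": centers[:, 1] if params.n_cells else np.array([]),
            "phase": [phases[i] for i in phase_of],
            "expressing": expressing,
            "amplitude": amplitudes,
        }
    )
    return stack, cells


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass(frozen=True)
class CtSimParams:
    """Design of a synthetic RT-qPCR experiment.

    ``log2fc`` maps genotype -> gene -> true log2 fold change relative to the
    control genotype.  Ct values are ``baseline - log2(relative expression) +
    noise``; the reference gene has log2FC 0 in every genotype by
    construction, and a shared per-(genotype, biological replicate) offset
    models RNA-input variation that the ddCt normalization removes.
    """

    genes: Sequence[str]
    reference_gene: str = "aTub84D"
    control_genotype: str = "control"
    genotypes: Sequence[str] = ("control", "mutant")
    log2fc: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_bio: int = 3
    n_tech: int = 3
    noise_sd: float = 0.2
    input_offset_sd: float = 0.3
    baseline_ct: float = 22.0
    reference_baseline_ct: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_gene not in self.genes:
            raise ValueError("reference gene must be in the gene list")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")


def simulate_ct_table(params: CtSimParams) -> pd.DataFrame:
    """Simulate a long-format Ct table (gene, genotype, bio_rep, tech_rep, ct)."""
    rng = stage_rng(params.seed, "ct")
    rows = []
    for genotype in params.genotypes:
        gmap = params.log2fc.get(genotype, {})
        for b in range(1, params.n_bio + 1):
            offset = rng.normal(0.0, params.input_offset_sd) if params.input_offset_sd else 0.0
            for gene in params.genes:
                lfc = 0.0 if gene == params.reference_gene else float(gmap.get(gene, 0.0))
                base = params.reference_baseline_ct if gene == params.reference_gene else params.baseline_ct
                true_ct = base - lfc + offset
                noise = rng.normal(0.0, params.noise_sd, size=params.n_tech) if params.noise_sd else np.zeros(params.n_tech)
                for t in range(1, params.n_tech + 1):
                    rows.append((gene, genotype, b, t, true_ct + noise[t - 1]))
    return pd.DataFrame(rows, columns=["gene", "genotype", "bio_rep", "tech_rep", "ct"])
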
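"""Composed simulation-to-measurement experiments.

These functions wire the generators to the measurement pipeline for the
package's calibration studies: per-copy enrichment recovery through the
collapse -> coverage -> CPM -> HGC chain, genome bin-scan rank detection and
null calibration, the clustering-singleton property of tandem-array genes,
and the FISH direction study comparing wildtype and mutant expression modes.
They are used both by the test suite and by the acceptance script, and are
deterministic for fixed seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import fish
from .collapse import ArrayLocation, project_fragments
from .coverage import CoverageTrack, apply_hgc, compute_coverage, to_cpm
from .scan import bin_scan, cluster_rows
from .simulate import (
    DEFAULT_PROBES,
    FragmentSimParams,
    ImageSimParams,
    SimGenomeSpec,
    SimulatedGenome,
    fragment_sampler_state,
    simulate_fragments,
    simulate_genome,
    simulate_vnc_stack,
)

__all__ = [
    "toy_genome_spec",
    "collapsed_lengths",
    "coverage_pipeline",
    "enrichment_recovery",
    "consensus_rank",
    "rank_experiment",
    "synthetic_gene_matrix",
    "clustering_singleton_experiment",
    "fish_replicate_stats",
    "fish_direction_experiment",
]

CONSENSUS = "chrHis"


def toy_genome_spec(
    chrom_length: int = 1_000_000,
    unit_length: int = 5080,
    copy_number: int = 100,
    array_start: int = 200_001,
) -> SimGenomeSpec:
    """Three ~1-Mb chromosomes; chr2 carries a fully assembled tandem array."""
    span = unit_length * copy_number
    return SimGenomeSpec(
        chrom_lengths={"chr1": chrom_length, "chr2": chrom_length, "chr3": chrom_length},
        array_chrom="chr2",
        array_start=array_start,
        array_end=array_start + span - 1,
        unit_length=unit_length,
        copy_number=copy_number,
    )


def collapsed_lengths(genome: SimulatedGenome, consensus: str = CONSENSUS) -> dict[str, int]:
    """Chromosome lengths of the collapsed assembly (consensus last)."""
    spec = genome.spec
    out = {}
    for name, length in genome.chrom_lengths.items():
        if name == genome.array_chrom:
            out[name] = length - (genome.array_end0 - genome.array_start0)
        else:
            out[name] = length
    out[consensus] = spec.unit_length
    return out


def coverage_pipeline(
    genome: SimulatedGenome,
    fragments: pd.DataFrame,
    bin_size: int = 2,
    consensus: str = CONSENSUS,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Project fragments and return the (CPM, HGC) track pair."""
    proj = project_fragments(fragments, ArrayLocation.from_genome(genome), consensus_name=consensus)
    lengths = collapsed_lengths(genome, consensus)
    raw = compute_coverage(proj.fragments, lengths, bin_size=bin_size)
    cpm = to_cpm(raw, proj.n_projected)
    hgc = apply_hgc(cpm, consensus=consensus, copy_number=genome.spec.copy_number)
    return cpm, hgc


def enrichment_recovery(
    genome: SimulatedGenome,
    enrichment: float,
    n_fragments: int = 1_000_000,
    seed: int = 0,
    bin_size: int = 2,
) -> float:
    """Recovered per-copy enrichment: mean consensus HGC / mean background CPM."""
    params = FragmentSimParams(n_fragments=n_fragments, enrichment=enrichment, seed=seed)
    frags = simulate_fragments(genome, params)
    cpm, hgc = coverage_pipeline(genome, frags, bin_size=bin_size)
    consensus_mean = float(np.nanmean(hgc.values[CONSENSUS]))
    background = np.concatenate([v for c, v in cpm.values.items() if c != CONSENSUS])
    return consensus_mean / float(np.nanmean(background))


def consensus_rank(hgc: CoverageTrack, bin_len: int = 5080, consensus: str = CONSENSUS) -> int:
    scanned = bin_scan(hgc, bin_len=bin_len)
    return int(scanned.loc[scanned["chrom"] == consensus, "rank"].iloc[0])


def rank_experiment(
    genome: SimulatedGenome,
    enrichment: float,
    n_seeds: int,
    base_seed: int = 0,
    n_fragments: int = 1_000_000,
    bin_size: int = 2,
    bin_len: int = 5080,
) -> list[int]:
    """Consensus-bin scan rank across independent fragment seeds."""
    params0 = FragmentSimParams(n_fragments=n_fragments, enrichment=enrichment, seed=base_seed)
    state = fragment_sampler_state(genome, params0)
    ranks = []
    for i in range(n_seeds):
        params = replace(params0, seed=base_seed + i)
        frags = simulate_fragments(genome, params, _cumweights=state)
        _, hgc = coverage_pipeline(genome, frags, bin_size=bin_size)
        ranks.append(consensus_rank(hgc, bin_len=bin_len))
    return ranks


# ---------------------------------------------------------------------------
# clustering singleton


def synthetic_gene_matrix(
    n_genes: int = 400,
    n_array: int = 5,
    n_cols: int = 300,
    background_mean: float = 1.0,
    fold: float = 10.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-body matrix with ``n_array`` high rows over a low background.

    Returns (matrix, is_array) with array rows at fold * background_mean.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(background_mean, noise_sd, size=(n_genes, n_cols))
    X[:n_array] = rng.normal(fold * background_mean, noise_sd, size=(n_array, n_cols))
    np.clip(X, 0.0, None, out=X)
    is_array = np.zeros(n_genes, dtype=bool)
    is_array[:n_array] = True
    perm = rng.permutation(n_genes)
    return X[perm], is_array[perm]


def clustering_singleton_experiment(n_seeds: int = 20, k: int = 3, base_seed: int = 0, **kw) -> int:
    """How many seeds put the array genes alone in one cluster."""
    hits = 0
    for i in range(n_seeds):
        X, is_array = synthetic_gene_matrix(seed=base_seed + i, **kw)
        labels = cluster_rows(X, k=k)
        arr_labels = set(labels[is_array])
        if len(arr_labels) == 1 and not (set(labels[~is_array]) & arr_labels):
            hits += 1
    return hits


# ---------------------------------------------------------------------------
# FISH direction study


def _probe_params(probe: str, genotype_mode: str, seed: int, **overrides) -> ImageSimParams:
    max_int, factor, range_max = DEFAULT_PROBES[probe]
    return ImageSimParams(
        max_intensity=max_int,
        intensity_range=range_max,
        mutant_factor=factor,
        genotype_mode=genotype_mode,
        seed=seed,
        **overrides,
    )


def fish_replicate_stats(
    probe: str,
    genotype_mode: str,
    n_replicates: int,
    seeds: np.ndarray,
    **overrides,
) -> pd.DataFrame:
    """Skewness and 90th-percentile bin for n replicate simulated fields."""
    rows = []
    for rep in range(n_replicates):
        params = _probe_params(probe, genotype_mode, int(seeds[rep]), **overrides)
        stack, _ = simulate_vnc_stack(params)
        proj = fish.sum_projection(stack, z_window_um=params.n_slices * params.z_step_um, z_step_um=params.z_step_um)
        hist = fish.intensity_histogram(proj, params.intensity_range, probe=probe, genotype=genotype_mode, replicate=rep)
        rows.append(
            {
                "probe": probe,
                "genotype": genotype_mode,
                "replicate": rep,
                "skewness": fish.histogram_skewness(hist),
                "pct90": fish.percentile_bin(hist),
            }
        )
    return pd.DataFrame(rows)


def fish_direction_experiment(
    n_families: int = 20,
    n_replicates: int = 5,
    base_seed: int = 0,
    probes: dict | None = None,
    **overrides,
) -> pd.DataFrame:
    """Wildtype-vs-mutant comparisons of FISH statistics per seed family.

    For every family (an independent batch of paired simulated experiments)
    and probe, simulates ``n_replicates`` fields per genotype mode, then runs
    exact Mann-Whitney tests (BH-adjusted within the family) on skewness and
    on the 90th-percentile bin.  Returns one row per (family, statistic,
    probe) with group means, the mutant-minus-wildtype difference, p and
    adjusted p.
    """
    probes = probes or DEFAULT_PROBES
    n_per_family = len(probes) * 2 * n_replicates
    all_seeds = np.random.SeedSequence(base_seed).generate_state(n_families * n_per_family) % (2**31)
    out = []
    for fam in range(n_families):
        fam_seeds = all_seeds[fam * n_per_family : (fam + 1) * n_per_family]
        stats = {}
        for pi, probe in enumerate(probes):
            for gi, mode in enumerate(("wildtype", "mutant")):
                seeds = fam_seeds[(pi * 2 + gi) * n_replicates : (pi * 2 + gi + 1) * n_replicates]
                stats[(probe, mode)] = fish_replicate_stats(probe, mode, n_replicates, seeds, **overrides)
        for statistic in ("skewness", "pct90"):
            wt = {p: stats[(p, "wildtype")][statistic].to_numpy() for p in probes}
            mut = {p: stats[(p, "mutant")][statistic].to_numpy() for p in probes}
            res = fish.compare_genotypes(wt, mut, statistic=statistic, group_a="wildtype", group_b="mutant")
            res.insert(0, "family", fam)
            res["delta"] = res["mean_mutant"] - res["mean_wildtype"]
            out.append(res)
    return pd.concat(out, ignore_index=True)
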
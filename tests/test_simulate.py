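"""Generator contracts: arithmetic, determinism, and sampling laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from hlbquant import simulate
from hlbquant.simulate import (
    CtSimParams,
    FragmentSimParams,
    ImageSimParams,
    SimGenomeSpec,
    simulate_ct_table,
    simulate_fragments,
    simulate_genome,
    simulate_vnc_stack,
)


class TestSimulateGenome:
    def test_array_occupies_copies_times_unit(self):
        spec = SimGenomeSpec(
            chrom_lengths={"chr1": 10_000}, array_chrom="chr1",
            array_start=2_001, array_end=3_500, unit_length=500, copy_number=3,
        )
        g = simulate_genome(spec, seed=0, strict=True)
        assert g.array_end0 - g.array_start0 == 1_500
        assert list(g.copies["start"] - g.array_start0) == [0, 500, 1000]
        assert list(g.copies["end"] - g.array_start0) == [500, 1000, 1500]
        # tandem copies are byte-identical
        seq = g.sequences["chr1"]
        unit = seq[g.array_start0 : g.array_start0 + 500]
        assert seq[g.array_start0 : g.array_end0] == unit * 3

    def test_single_copy_is_identity_layout(self):
        spec = SimGenomeSpec(
            chrom_lengths={"chr1": 5_000}, array_chrom="chr1",
            array_start=1_001, array_end=1_500, unit_length=500, copy_number=1,
        )
        g = simulate_genome(spec, seed=0, strict=True)
        assert len(g.sequences["chr1"]) == 5_000
        assert len(g.copies) == 1

    def test_expanded_span_differs_from_underassembled_interval(self):
        # a native interval shorter than C*L grows when expanded
        spec = SimGenomeSpec(
            chrom_lengths={"chr1": 600_000}, array_chrom="chr1",
            array_start=100_001, array_end=272_580, unit_length=5080, copy_number=100,
        )
        g = simulate_genome(spec, seed=0)
        assert spec.native_span == 172_580
        assert g.array_end0 - g.array_start0 == 508_000
        assert len(g.sequences["chr1"]) == 600_000 - 172_580 + 508_000
        with pytest.raises(ValueError, match="strict"):
            simulate_genome(spec, seed=0, strict=True)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SimGenomeSpec(chrom_lengths={"c": 100}, array_chrom="c", array_start=50, array_end=200)
        with pytest.raises(ValueError):
            SimGenomeSpec(chrom_lengths={"c": 100}, array_chrom="missing", array_start=1, array_end=10)
        with pytest.raises(ValueError):
            SimGenomeSpec(
                chrom_lengths={"c": 1000}, array_chrom="c", array_start=1, array_end=10,
                unit_length=5, copy_number=2, unit_seq="ACGT",
            )


class TestSimulateFragments:
    def test_same_seed_is_byte_identical(self, tiny_genome):
        params = FragmentSimParams(n_fragments=5_000, enrichment=7.0, seed=42)
        a = simulate_fragments(tiny_genome, params)
        b = simulate_fragments(tiny_genome, params)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_fragments_empty_not_error(self, tiny_genome):
        out = simulate_fragments(tiny_genome, FragmentSimParams(n_fragments=0))
        assert out.empty

    def test_negative_enrichment_rejected(self):
        with pytest.raises(ValueError):
            FragmentSimParams(n_fragments=10, enrichment=-1.0)

    @pytest.mark.parametrize("enrichment", [1.0, 50.0])
    def test_start_density_ratio_recovers_enrichment(self, toy_genome, enrichment):
        """Per-bp start density inside/outside the array recovers E.

        The check uses the exact binomial law of the inside-start count:
        with array fraction f of the genome and weight factor E, the
        probability a start lands inside is p = fE / (fE + (1-f)).
        """
        n = 1_000_000
        params = FragmentSimParams(n_fragments=n, enrichment=enrichment, seed=5)
        frags = simulate_fragments(toy_genome, params)
        g = toy_genome
        on = frags["chrom"] == g.array_chrom
        inside = int(
            ((frags["start"] >= g.array_start0) & (frags["start"] < g.array_end0) & on).sum()
        )
        array_bp = g.array_end0 - g.array_start0
        total_bp = sum(g.chrom_lengths.values())
        f = array_bp / total_bp
        p = f * enrichment / (f * enrichment + (1 - f))
        lo, hi = st.binom.ppf([0.0005, 0.9995], n, p)
        assert lo <= inside <= hi
        ratio = (inside / array_bp) / ((n - inside) / (total_bp - array_bp))
        assert ratio == pytest.approx(enrichment, rel=0.05)

    def test_fragment_lengths_respect_bounds(self, tiny_genome):
        params = FragmentSimParams(
            n_fragments=20_000, length_mean=150, length_sd=60, length_min=50, length_max=300, seed=9
        )
        frags = simulate_fragments(tiny_genome, params)
        lens = frags["end"] - frags["start"]
        assert lens.max() <= 300 and lens.min() >= 1  # chromosome-end clipping may shorten

    def test_off_target_peak_enriched(self, tiny_genome):
        params = FragmentSimParams(
            n_fragments=100_000, enrichment=1.0,
            off_target_peaks=[("chrB", 1000, 2000, 20.0)], seed=3,
        )
        frags = simulate_fragments(tiny_genome, params)
        on_b = frags[frags["chrom"] == "chrB"]
        in_peak = ((on_b["start"] >= 1000) & (on_b["start"] < 2000)).mean()
        assert in_peak > 0.5  # 20x weight on 1/8 of chrB dominates


class TestSimulateVncStack:
    def test_zero_cells_background_only(self):
        params = ImageSimParams(
            max_intensity=450, intensity_range=699, n_cells=0,
            field_size_um=(20, 20), seed=0,
        )
        stack, cells = simulate_vnc_stack(params)
        assert cells.empty
        assert stack.sum(axis=0).max() <= 699

    def test_expressing_count_binomial(self):
        """Wildtype with S fraction 0.3 and 200 cells expresses ~60."""
        fractions = {"G1": 0.2, "S": 0.3, "G2": 0.3, "M": 0.2}
        counts = []
        for seed in range(8):
            params = ImageSimParams(
                max_intensity=450, intensity_range=699, n_cells=200,
                phase_fractions=fractions, genotype_mode="wildtype", seed=seed,
            )
            _, cells = simulate_vnc_stack(params)
            counts.append(int(cells["expressing"].sum()))
        lo, hi = st.binom.ppf([0.005, 0.995], 200, 0.3)
        assert lo <= np.mean(counts) <= hi

    def test_mutant_full_factor_expresses_all_cycling_phases(self):
        params = ImageSimParams(
            max_intensity=450, intensity_range=699, mutant_factor=1.0,
            genotype_mode="mutant", seed=2,
        )
        _, cells = simulate_vnc_stack(params)
        # condensed S-G2-M cycle: every cell is in an expressing phase
        assert cells["expressing"].all()

    def test_ground_truth_matches_rendered_pixels(self):
        """Cells flagged expressing carry signal in the rendered projection."""
        params = ImageSimParams(max_intensity=450, intensity_range=699, seed=4)
        stack, cells = simulate_vnc_stack(params)
        proj = stack.astype(np.int64).sum(axis=0)
        dy, dx = simulate.annulus_offsets(params)
        bg = params.n_slices * params.background_mean
        for cell in cells.itertuples():
            yy = np.clip(np.rint(cell.y + dy).astype(int), 0, proj.shape[0] - 1)
            xx = np.clip(np.rint(cell.x + dx).astype(int), 0, proj.shape[1] - 1)
            mean = proj[yy, xx].mean()
            if cell.expressing:
                assert mean > bg + 50
            else:
                assert mean < bg + 20

    def test_intensities_within_declared_range(self):
        params = ImageSimParams(max_intensity=615, intensity_range=1399, mutant_factor=1.0,
                                genotype_mode="mutant", seed=6)
        stack, _ = simulate_vnc_stack(params)
        assert stack.sum(axis=0).max() <= 1399

    def test_unpackable_field_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            params = ImageSimParams(
                max_intensity=450, intensity_range=699, n_cells=500,
                field_size_um=(20, 20), seed=0,
            )
            simulate_vnc_stack(params)

    def test_invalid_phase_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ImageSimParams(
                max_intensity=450, intensity_range=699,
                phase_fractions={"G1": 0.5, "S": 0.2, "G2": 0.2, "M": 0.2},
            )


class TestSimulateCtTable:
    def test_reference_gene_required(self):
        with pytest.raises(ValueError, match="reference"):
            CtSimParams(genes=["H3"], reference_gene="aTub84D")

    def test_table_shape_and_determinism(self):
        params = CtSimParams(genes=["aTub84D", "H3"], log2fc={"mutant": {"H3": 1.7}}, seed=3)
        a = simulate_ct_table(params)
        b = simulate_ct_table(params)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 2 * 3 * 3 * 2  # genotypes x bio x tech x genes

    def test_noise_free_encoding_inverts_exactly(self):
        """At zero noise, Ct differences encode the true log2FC exactly."""
        params = CtSimParams(
            genes=["aTub84D", "H3", "H1"],
            log2fc={"mutant": {"H3": 2.0, "H1": 0.0}},
            noise_sd=0.0, input_offset_sd=0.0, seed=0,
        )
        tab = simulate_ct_table(params)
        piv = tab.groupby(["gene", "genotype"])["ct"].mean().unstack()
        assert piv.loc["H3", "control"] - piv.loc["H3", "mutant"] == pytest.approx(2.0)
        assert piv.loc["H1", "control"] - piv.loc["H1", "mutant"] == pytest.approx(0.0)
        assert piv.loc["aTub84D", "control"] == piv.loc["aTub84D", "mutant"]
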
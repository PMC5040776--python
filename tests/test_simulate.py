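import numpy as np
import pytest
from scipy import stats

from sncrnakit.context import classify_locus
from sncrnakit.io import read_gff3_genes, write_gff3_genes
from sncrnakit.simulate import (
    CladeSpec,
    DivergenceSpec,
    PlantSpec,
    default_clade_panel,
    default_plant_specs,
    diverge_genome,
    make_clade_panel,
    make_species_panel,
    plant_genes,
    plant_sncrnas,
    random_genome,
)


class TestRandomGenome:
    def test_gc_content_hits_target_on_long_contig(self):
        (contig,) = random_genome(1, 100000, gc_fraction=0.4954, seed=7)
        gc = sum(contig.sequence.count(b) for b in "GC") / contig.length
        assert 0.485 <= gc <= 0.505

    def test_same_seed_is_bit_identical(self):
        a = random_genome(2, 5000, seed=3)
        b = random_genome(2, 5000, seed=3)
        assert [c.sequence for c in a] == [c.sequence for c in b]

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.2])
    def test_degenerate_gc_rejected(self, gc):
        with pytest.raises(ValueError):
            random_genome(1, 2000, gc_fraction=gc)

    def test_sub_kilobase_contigs_rejected(self):
        with pytest.raises(ValueError):
            random_genome(1, 500)


class TestPlantGenes:
    def test_intron_count_is_genes_times_exons_minus_one(self, small_genome):
        genes = plant_genes(small_genome, 10, exons_per_gene=3, seed=1)
        assert sum(len(g.introns) for g in genes) == 20

    def test_intergenic_gaps_respect_minimum(self, small_genome):
        genes = plant_genes(small_genome, 4, min_intergenic_gap=3000, seed=2,
                            edge_margin=1000)
        by_contig = {}
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            by_contig.setdefault(g.contig, []).append(g)
        for gs in by_contig.values():
            for a, b in zip(gs, gs[1:]):
                assert b.start - a.end >= 3000

    def test_requested_intron_lengths_are_honoured(self, small_genome):
        genes = plant_genes(
            small_genome, 5, exons_per_gene=3, intron_lengths=(120, 250), seed=3
        )
        for g in genes:
            assert [e - s for s, e in g.introns] == [120, 250]

    def test_annotation_round_trips_through_gff3(self, tmp_path, small_genes):
        p = tmp_path / "x.gff3"
        write_gff3_genes(small_genes, p)
        assert read_gff3_genes(p) == small_genes

    def test_space_exhaustion_raises_helpful_error(self, small_genome):
        with pytest.raises(ValueError, match="fewer genes"):
            plant_genes(small_genome, 500, seed=4)


class TestPlantSncrnas:
    def test_truth_calls_match_real_classifier_exactly(self, planted, small_genes):
        for locus, want in zip(planted.loci, planted.truth):
            got = classify_locus(locus, small_genes)
            assert (got.category, got.distance, got.neighbor) == (
                want.category,
                want.distance,
                want.neighbor,
            )

    def test_spec_targets_are_realised(self, small_genome, small_genes):
        specs = [
            PlantSpec("miRNA", "intron", None, 21),
            PlantSpec("tRNA", "pseudo_utr", 450, 75),
            PlantSpec("miRNA", "intergenic", 2094, 23),
        ]
        res = plant_sncrnas(small_genome, small_genes, specs, seed=5)
        assert [t.category for t in res.truth] == [
            "intron",
            "pseudo_utr",
            "intergenic",
        ]
        assert res.truth[1].distance == 450
        assert res.truth[2].distance == 2094

    def test_planted_sequence_is_written_into_genome(self, planted):
        from sncrnakit.homology import reverse_complement

        seq_by_id = {c.id: c.sequence for c in planted.genome}
        for locus in planted.loci:
            genomic = seq_by_id[locus.contig][locus.start : locus.end]
            rna = planted.sequences[locus.id]
            want = rna if locus.strand == "+" else reverse_complement(rna)
            assert genomic == want

    def test_unplaceable_spec_is_named(self, small_genome, small_genes):
        spec = PlantSpec("snRNA", "intron", None, 10000)
        with pytest.raises(ValueError, match="plant1_snRNA"):
            plant_sncrnas(small_genome, small_genes, [spec], seed=6)


class TestDivergeGenome:
    def test_zero_rate_is_identity(self, planted):
        dv = diverge_genome(
            planted.genome, DivergenceSpec(substitution_rate=0.0, seed=1)
        )
        assert [c.sequence for c in dv.genome] == [
            c.sequence for c in planted.genome
        ]

    def test_realised_substitutions_within_binomial_bounds(self, planted):
        locus = max(planted.loci, key=lambda l: l.length)
        rate = 0.05
        lo = stats.binom.ppf(0.005, locus.length, rate)
        hi = stats.binom.ppf(0.995, locus.length, rate)
        counts = []
        for seed in range(20):
            dv = diverge_genome(
                planted.genome,
                DivergenceSpec(substitution_rate=rate, seed=seed),
                planted_loci=[locus],
            )
            counts.append(dv.substitutions[locus.id])
        assert all(lo <= c <= hi for c in counts)
        assert np.mean(counts) == pytest.approx(rate * locus.length, rel=0.5)

    def test_same_seed_is_bit_identical(self, planted):
        spec = DivergenceSpec(substitution_rate=0.1, indel_rate=0.01, seed=9)
        a = diverge_genome(planted.genome, spec, planted_loci=planted.loci)
        b = diverge_genome(planted.genome, spec, planted_loci=planted.loci)
        assert [c.sequence for c in a.genome] == [c.sequence for c in b.genome]

    def test_realised_identity_matches_aligner_for_indel_free(self, planted):
        from sncrnakit.homology import reverse_complement

        dv = diverge_genome(
            planted.genome,
            DivergenceSpec(substitution_rate=0.1, seed=21),
            planted_loci=planted.loci,
        )
        div_seq = {c.id: c.sequence for c in dv.genome}
        checked = 0
        for locus in planted.loci:
            if locus.length < 70:
                continue
            rna = planted.sequences[locus.id]
            oriented = rna if locus.strand == "+" else reverse_complement(rna)
            region = div_seq[locus.contig][locus.start : locus.end]
            runs, cur = [0], 0
            for a, b in zip(oriented, region):
                cur = cur + 1 if a == b else 0
                runs.append(cur)
            if max(runs) < 19:
                continue  # no seed survived; the word-seeded search is blind
            expected = 100.0 * (1 - dv.substitutions[locus.id] / locus.length)
            from sncrnakit.homology import search

            hits = search(rna, dv.genome)
            assert hits
            got = hits[0].identity
            if hits[0].aln_len >= locus.length:
                # full-span alignment: identity is the realised fraction
                assert got == pytest.approx(expected, abs=2.0)
            else:
                # local alignment may trim mismatch-dense edges, which can
                # only raise identity relative to the whole-locus figure
                assert got >= expected - 2.0
            checked += 1
        assert checked >= 8

    def test_indel_protection_keeps_planted_spans_intact(self, planted):
        dv = diverge_genome(
            planted.genome,
            DivergenceSpec(substitution_rate=0.0, indel_rate=0.02, seed=33),
            planted_loci=planted.loci,
        )
        assert all(v == 0 for v in dv.substitutions.values())
        # with substitutions off, protected spans must still exist verbatim
        seqs = {c.id: c.sequence for c in dv.genome}
        ref = {c.id: c.sequence for c in planted.genome}
        for locus in planted.loci:
            assert ref[locus.contig][locus.start : locus.end] in seqs[locus.contig]


class TestSpeciesPanels:
    def test_flat_panel_rates_and_determinism(self, planted):
        spec = {
            "a": DivergenceSpec(substitution_rate=0.02),
            "b": DivergenceSpec(substitution_rate=0.2),
        }
        p1 = make_species_panel(planted.genome, spec, seed=4, planted_loci=planted.loci)
        p2 = make_species_panel(planted.genome, spec, seed=4, planted_loci=planted.loci)
        assert p1.rates == {"a": 0.02, "b": 0.2}
        assert [c.sequence for c in p1.genomes["a"]] == [
            c.sequence for c in p2.genomes["a"]
        ]

    def test_empty_panel_rejected(self, planted):
        with pytest.raises(ValueError):
            make_species_panel(planted.genome, {}, seed=1)

    def test_clade_panel_species_counts_and_rates(self, planted):
        panel = make_clade_panel(
            planted.genome, default_clade_panel(), seed=2, planted_loci=planted.loci
        )
        assert len(panel.genomes) == 7
        assert panel.rates["conspecific"] < min(
            r for n, r in panel.rates.items() if n != "conspecific"
        )
        assert max(panel.rates, key=panel.rates.get) == "outgroup"

    def test_clade_panel_substitution_counts_are_exact_hamming(self, planted):
        panel = make_clade_panel(
            planted.genome, default_clade_panel(), seed=3, planted_loci=planted.loci
        )
        ref = {c.id: c.sequence for c in planted.genome}
        for name, genome in panel.genomes.items():
            fin = {c.id: c.sequence for c in genome}
            for locus in planted.loci:
                a = ref[locus.contig][locus.start : locus.end]
                b = fin[locus.contig][locus.start : locus.end]
                want = sum(1 for x, y in zip(a, b) if x != y)
                assert panel.substitutions[name][locus.id] == want

    def test_duplicate_species_across_clades_rejected(self, planted):
        clades = {
            "c1": CladeSpec(
                ancestor=DivergenceSpec(substitution_rate=0.01),
                members={"x": DivergenceSpec(substitution_rate=0.01)},
            ),
            "c2": CladeSpec(
                ancestor=DivergenceSpec(substitution_rate=0.01),
                members={"x": DivergenceSpec(substitution_rate=0.02)},
            ),
        }
        with pytest.raises(ValueError, match="duplicate"):
            make_clade_panel(planted.genome, clades, seed=1)

    def test_indels_rejected_in_clade_mode(self):
        with pytest.raises(ValueError, match="substitution-only"):
            CladeSpec(
                ancestor=DivergenceSpec(substitution_rate=0.01, indel_rate=0.01),
                members={"x": DivergenceSpec(substitution_rate=0.01)},
            )


def test_default_plant_specs_cover_all_classes_and_categories():
    specs = default_plant_specs(n_per_class=6, seed=0)
    assert {s.rna_class for s in specs} == {
        "miRNA", "tRNA", "snoRNA", "snRNA", "ribozyme", "other",
    }
    assert {s.target_category for s in specs} == {
        "intron", "pseudo_utr", "intergenic",
    }
    assert all(s.length >= 19 for s in specs)
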
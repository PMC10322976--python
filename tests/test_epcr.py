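"""Electronic PCR: word index, exact amplicon search, cross-genome screening."""

import pytest

from citrosat import Genome
from citrosat.epcr import (
    build_allele_matrix,
    classify_amplification,
    cross_genome_screen,
    index_genome,
    run_epcr,
)
from citrosat.genome import revcomp
from citrosat.mining import find_perfect_ssrs
from citrosat.primers import PrimerPair, design_primers
from citrosat.simulate import PlantSpec, generate_genome, mutate_related_genomes
from conftest import random_sequence
from oracles import naive_epcr


def _pair(forward, reverse, expected=0, pid="P1"):
    return PrimerPair(
        id=pid, locus_ref="L", chrom="c", forward_seq=forward, reverse_seq=reverse,
        forward_tm=55, reverse_tm=55, forward_gc=50, reverse_gc=50,
        expected_product_bp=expected, forward_start=0, reverse_end=0,
    )


def _planted_template(rng, product, fwd="ACGTTGCAGGTACCATGTCA", rev="TGCATCCGGTATGCAACTGA"):
    """Background with one forward site and one reverse-complement site giving
    the requested 5'-to-5' product size."""
    left = random_sequence(rng, 300)
    right = random_sequence(rng, 300)
    gap = product - len(fwd) - len(rev)
    middle = random_sequence(rng, gap)
    return left + fwd + middle + revcomp(rev) + right, fwd, rev


class TestSeedIndex:
    def test_position_count_on_n_free_sequence(self, rng):
        seq = random_sequence(rng, 1000)
        idx = index_genome(Genome({"c": seq}), word_size=12)
        assert sum(len(v) for v in idx._index.values()) == 1000 - 11

    def test_absent_word_has_no_hits(self, rng):
        seq = "ACGT" * 250
        idx = index_genome(Genome({"c": seq}), word_size=12)
        assert idx.word_positions("A" * 12) == []

    def test_planted_word_found_at_all_occurrences(self, rng):
        word = "GATTACAGATTA"
        seq = (random_sequence(rng, 100) + word + random_sequence(rng, 80)
               + word + random_sequence(rng, 60) + word)
        idx = index_genome(Genome({"c": seq}), word_size=12)
        naive = [i for i in range(len(seq) - 11) if seq[i : i + 12] == word]
        assert [p for _, p in idx.word_positions(word)] == naive
        assert len(naive) >= 3

    def test_primer_shorter_than_word_size_rejected(self, rng):
        idx = index_genome(Genome({"c": random_sequence(rng, 100)}), word_size=12)
        with pytest.raises(ValueError, match="shorter"):
            idx.find_exact("ACGTACGT")


class TestRunEpcr:
    def test_single_planted_site_product_250(self, rng):
        seq, fwd, rev = _planted_template(rng, 250)
        amps = run_epcr(_pair(fwd, rev), Genome({"c": seq}))
        assert len(amps) == 1 and amps[0].size == 250

    def test_product_over_size_cap_discarded(self, rng):
        seq, fwd, rev = _planted_template(rng, 1100)
        assert run_epcr(_pair(fwd, rev), Genome({"c": seq})) == []

    def test_sites_on_two_chromosomes(self, rng):
        s1, fwd, rev = _planted_template(rng, 200)
        s2, _, _ = _planted_template(rng, 300)
        g = Genome({"c1": s1, "c2": s2})
        amps = run_epcr(_pair(fwd, rev), g)
        assert [(a.chrom, a.size) for a in amps] == [("c1", 200), ("c2", 300)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_full_text_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        seq, fwd, rev = _planted_template(rng, 180)
        # duplicate the template, flip one copy to exercise both orientations
        seq = seq + random_sequence(rng, 200) + revcomp(seq)
        g = Genome({"c": seq})
        got = {(a.start, a.end) for a in run_epcr(_pair(fwd, rev), g)}
        assert got == naive_epcr(fwd, rev, seq)

    def test_strand_symmetry_of_size_multiset(self, rng):
        seq, fwd, rev = _planted_template(rng, 240)
        g = Genome({"c": seq})
        sizes = sorted(a.size for a in run_epcr(_pair(fwd, rev), g))
        sizes_rc = sorted(a.size for a in run_epcr(_pair(fwd, rev), g.reverse_complement()))
        assert sizes == sizes_rc == [240]

    def test_widening_size_window_is_monotone(self, rng):
        seq, fwd, rev = _planted_template(rng, 450)
        g = Genome({"c": seq})
        narrow = set(run_epcr(_pair(fwd, rev), g, params={"amplicon_min": 400,
                                                          "amplicon_max": 500}))
        wide = set(run_epcr(_pair(fwd, rev), g, params={"amplicon_min": 100,
                                                        "amplicon_max": 1000}))
        assert narrow <= wide

    def test_margin_filters_far_from_designed_size(self, rng):
        seq, fwd, rev = _planted_template(rng, 600)
        g = Genome({"c": seq})
        kept = run_epcr(_pair(fwd, rev, expected=250), g, params={"margin": 3000})
        dropped = run_epcr(_pair(fwd, rev, expected=250), g, params={"margin": 100})
        assert len(kept) == 1 and dropped == []


class TestClassification:
    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 1), (2, 2), (4, 3)])
    def test_amplicon_count_bins(self, n, expected):
        amps = ["x"] * n
        assert classify_amplification(amps) == expected


class TestCrossGenomeScreen:
    @pytest.fixture
    def panel(self):
        genome, truth = generate_genome(
            {"chr1": 8000},
            [PlantSpec("AT", 25, "chr1", 2001), PlantSpec("AAG", 14, "chr1", 6001)],
            gc_background=0.5, seed=21,
        )
        loci = find_perfect_ssrs(genome)
        pairs = [design_primers(l, genome, k=1)[0] for l in loci]
        return genome, truth, pairs

    def test_planted_deltas_recovered_as_distinct_sizes(self, panel):
        genome, truth, pairs = panel
        at_locus = [t for t in truth if t.motif == "AT"][0]
        related, _ = mutate_related_genomes(
            genome, truth, {at_locus.locus_id: [0, 2, -3]}, seed=2
        )
        results = cross_genome_screen(pairs, [genome] + related, genome.genome_id)
        at_result = [r for r in results
                     if r.primer_id.startswith(f"SSR_chr1_{at_locus.start}")][0]
        sizes = {g: s[0] for g, s in at_result.sizes().items() if s}
        base = sizes[genome.genome_id]
        assert sorted(sizes.values()) == sorted([base, base, base + 4, base - 6])
        assert at_result.polymorphic
        assert at_result.single_locus

    def test_all_zero_deltas_monomorphic(self, panel):
        genome, truth, pairs = panel
        related, _ = mutate_related_genomes(genome, truth, {}, n_genomes=3, seed=2)
        results = cross_genome_screen(pairs, [genome] + related, genome.genome_id)
        assert all(not r.polymorphic for r in results)
        assert all(r.transferable and r.transferable_genomes == 4 for r in results)

    def test_destroyed_site_scores_class_zero(self, panel):
        genome, truth, pairs = panel
        related, _ = mutate_related_genomes(genome, truth, {}, n_genomes=2, seed=2)
        # knock out the forward primer site of pair 0 in related[0]
        target = pairs[0]
        seq = related[0]["chr1"]
        i = seq.find(target.forward_seq)
        broken = seq[:i] + revcomp(target.forward_seq[:4]) + seq[i + 4:]
        damaged = Genome({"chr1": broken}, genome_id=related[0].genome_id)
        results = cross_genome_screen(
            [target], [genome, damaged, related[1]], genome.genome_id
        )
        r = results[0]
        assert r.locus_count_class[damaged.genome_id] == 0
        assert r.transferable_genomes == 2

    def test_duplicate_primer_ids_rejected(self, panel):
        genome, _, pairs = panel
        with pytest.raises(ValueError, match="duplicate"):
            cross_genome_screen([pairs[0], pairs[0]], [genome], genome.genome_id)


class TestBuildAlleleMatrix:
    def test_frequencies_by_direct_counting(self):
        genome, truth = generate_genome(
            {"chr1": 6000}, [PlantSpec("AT", 25, "chr1", 3001)],
            gc_background=0.5, seed=31,
        )
        locus = find_perfect_ssrs(genome)[0]
        pair = design_primers(locus, genome, k=1)[0]
        related, _ = mutate_related_genomes(
            genome, truth, {truth[0].locus_id: [0, 2]}, seed=3
        )
        panel = [genome] + related
        results = cross_genome_screen([pair], panel, genome.genome_id)
        m = build_allele_matrix(results, panel)
        freqs = m.allele_frequencies(pair.id)
        base = pair.expected_product_bp
        assert freqs == {base: pytest.approx(2 / 3), base + 4: pytest.approx(1 / 3)}

    def test_non_amplifying_genome_is_missing(self):
        from citrosat.epcr import Amplicon, EPCRResult

        r = EPCRResult(
            primer_id="P", reference_id="g1",
            amplicons={"g1": [Amplicon("g1", "c", 1, 250)], "g2": []},
        )
        m = build_allele_matrix([r], [Genome({"c": "ACGT"}, "g1"),
                                      Genome({"c": "ACGT"}, "g2")])
        assert m.genotype("P", "g2") is None
        assert m.non_missing("P") == [(250, 250)]
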
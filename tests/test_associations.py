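import numpy as np
import pytest

from syntenymap.associations import (
    build_association_string,
    count_autosomal_fragments,
    extract_associations,
    format_pair,
    fragment_count_table,
    genome_associations,
    infer_ancestral,
    match_across_species,
)
from syntenymap.model import (
    BlockSet,
    GenomeMismatchError,
    Orientation,
    SyntenyBlock,
    UnknownChromosomeError,
)

from conftest import make_block

MB = 1_000_000


def labelled_blockset(
    labels, query_chrom="c1", target_genome="HSA", block_len=6 * MB, footprint_starts=None
):
    """Blocks along one query chromosome whose target labels read off in order.

    Each occurrence gets its own target footprint; by default successive
    occurrences of a label sit at increasing offsets on that target
    chromosome, or explicit start positions may be given.
    """
    blocks = []
    cursors = {}
    for i, label in enumerate(labels):
        if footprint_starts is not None:
            t_start = footprint_starts[i]
        else:
            t_start = cursors.get(label, 0)
            cursors[label] = t_start + block_len + 10 * MB
        blocks.append(
            SyntenyBlock(
                target_chrom=str(label),
                target_start=t_start,
                target_end=t_start + block_len,
                query_chrom=query_chrom,
                query_start=i * (block_len + MB),
                query_end=i * (block_len + MB) + block_len,
            )
        )
    return BlockSet(target_genome, "QRY", tuple(blocks))


class TestAssociationStrings:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["7", "6", "11", "6"], "7/6/11/6"),
            (["20", "1", "20", "15", "20"], "20/1/20/15/20"),
            (["1", "5", "1", "8", "4", "8"], "1/5/1/8/4/8"),
            (["8", "4", "8"], "8/4/8"),
            (["19", "1", "10"], "19/1/10"),
            (["15", "14", "15", "3", "21"], "15/14/15/3/21"),
            (["4", "4"], "4"),
        ],
    )
    def test_labels_read_off_in_query_order(self, labels, expected):
        bs = labelled_blockset(labels)
        s = build_association_string(bs, "c1")
        assert str(s) == expected

    def test_no_two_consecutive_labels_equal(self):
        s = build_association_string(labelled_blockset(["4", "4", "8", "8", "4"]), "c1")
        assert all(a != b for a, b in zip(s.labels, s.labels[1:]))

    def test_segments_ordered_by_query_start(self):
        s = build_association_string(labelled_blockset(["8", "4", "8"]), "c1")
        starts = [b.query_start for r in s.runs for b in r.blocks]
        assert starts == sorted(starts)

    def test_unknown_chromosome_rejected(self, query_genome):
        bs = BlockSet("T", "Q", (make_block("t1", 0, 6 * MB, q_chrom="q1"),))
        with pytest.raises(UnknownChromosomeError):
            build_association_string(bs, "nope", query_genome)

    def test_invariant_under_uniform_coordinate_scaling(self):
        labels = ["7", "6", "11", "6"]
        bs = labelled_blockset(labels)
        scaled = bs.with_blocks(
            SyntenyBlock(
                b.target_chrom, b.target_start * 3, b.target_end * 3,
                b.query_chrom, b.query_start * 3, b.query_end * 3, b.orientation,
            )
            for b in bs
        )
        assert str(build_association_string(scaled, "c1")) == str(
            build_association_string(bs, "c1")
        )


class TestExtractAssociations:
    def test_single_label_gives_no_association(self):
        s = build_association_string(labelled_blockset(["4"]), "c1")
        assert extract_associations(s) == ()

    def test_inversion_string_gives_one_pair_two_witnesses(self):
        s = build_association_string(labelled_blockset(["8", "4", "8"]), "c1")
        assocs = extract_associations(s)
        assert len(assocs) == 1
        assert assocs[0].pair == frozenset({"8", "4"})
        assert len(assocs[0].witnesses) == 2

    def test_three_label_string_gives_two_pairs(self):
        s = build_association_string(labelled_blockset(["19", "1", "10"]), "c1")
        pairs = {a.pair for a in extract_associations(s)}
        assert pairs == {frozenset({"19", "1"}), frozenset({"1", "10"})}

    def test_reversed_string_yields_same_pair_set(self):
        labels = ["15", "14", "15", "3", "21"]
        fwd = extract_associations(build_association_string(labelled_blockset(labels), "c1"))
        rev = extract_associations(
            build_association_string(labelled_blockset(labels[::-1]), "c1")
        )
        assert {a.pair for a in fwd} == {a.pair for a in rev}

    def test_multiplicity_kept_across_query_chromosomes(self):
        b1 = labelled_blockset(["12", "22"], query_chrom="c1")
        b2 = labelled_blockset(["12", "22"], query_chrom="c2")
        bs = BlockSet("HSA", "QRY", b1.blocks + b2.blocks)
        assocs = genome_associations(bs)
        assert [a.pair for a in assocs] == [frozenset({"12", "22"})] * 2


def association_of(labels, query_chrom, footprint_starts=None, genome="HSA"):
    bs = labelled_blockset(
        labels, query_chrom=query_chrom, target_genome=genome,
        footprint_starts=footprint_starts,
    )
    (assoc,) = extract_associations(
        build_association_string(bs, query_chrom), target_genome=genome
    )
    return assoc


class TestMatching:
    def test_identical_footprints_match_with_fraction_one(self):
        a = association_of(["12", "22"], "cA")
        b = association_of(["12", "22"], "cB")
        (m,) = match_across_species([a], [b])
        assert m.overlap_fractions == {"12": 1.0, "22": 1.0}

    def test_disjoint_reference_footprints_do_not_match(self):
        a = association_of(["12", "22"], "cA", footprint_starts=[0, 0])
        b = association_of(["12", "22"], "cB", footprint_starts=[30 * MB, 30 * MB])
        assert match_across_species([a], [b]) == ()

    def test_three_vs_four_occurrences_three_overlapping(self):
        # three occurrences in species A, four in B; three of them share
        # reference footprints, the fourth B occurrence lies elsewhere
        a_assocs = [
            association_of(["12", "22"], f"cA{i}", footprint_starts=[i * 20 * MB] * 2)
            for i in range(3)
        ]
        b_assocs = [
            association_of(["12", "22"], f"cB{i}", footprint_starts=[i * 20 * MB] * 2)
            for i in range(3)
        ]
        b_assocs.append(
            association_of(["12", "22"], "cB9", footprint_starts=[200 * MB] * 2)
        )
        matches = match_across_species(a_assocs, b_assocs)
        assert len(matches) == 3
        assert all(m.b.query_chrom != "cB9" for m in matches)

    def test_mismatched_target_genomes_rejected(self):
        a = association_of(["12", "22"], "cA", genome="HSA")
        b = association_of(["12", "22"], "cB", genome="MMU")
        with pytest.raises(GenomeMismatchError):
            match_across_species([a], [b])


class TestInferAncestral:
    def test_eutherian_example_recovers_shared_pairs(self):
        shared = [["3", "21"], ["4", "8"], ["12", "22"], ["14", "15"]]
        a_assocs = [association_of(p, f"cA{i}") for i, p in enumerate(shared)]
        a_assocs.append(association_of(["7", "16"], "cA9"))
        b_assocs = [association_of(p, f"cB{i}") for i, p in enumerate(shared)]
        b_assocs.append(association_of(["16", "19"], "cB9"))
        matches = match_across_species(a_assocs, b_assocs)
        report = infer_ancestral(a_assocs, b_assocs, matches)
        assert report.ancestral_labels == ("3/21", "4/8", "12/22", "14/15")
        assert report.only_a == frozenset({frozenset({"7", "16"})})
        assert report.only_b == frozenset({frozenset({"16", "19"})})

    def test_disjoint_association_sets_give_empty_ancestral(self):
        a = [association_of(["1", "2"], "cA")]
        b = [association_of(["3", "4"], "cB")]
        report = infer_ancestral(a, b, match_across_species(a, b))
        assert report.ancestral == frozenset()

    def test_pair_in_both_species_included(self):
        a = [association_of(["9", "11"], "cA")]
        b = [association_of(["9", "11"], "cB")]
        report = infer_ancestral(a, b, match_across_species(a, b))
        assert report.ancestral == frozenset({frozenset({"9", "11"})})

    def test_symmetric_in_species_order(self):
        a_assocs = [association_of(["3", "21"], "cA"), association_of(["1", "5"], "cA2")]
        b_assocs = [association_of(["3", "21"], "cB")]
        fwd = infer_ancestral(
            a_assocs, b_assocs, match_across_species(a_assocs, b_assocs)
        )
        rev = infer_ancestral(
            b_assocs, a_assocs, match_across_species(b_assocs, a_assocs)
        )
        assert fwd.ancestral == rev.ancestral
        assert fwd.only_a == rev.only_b


class TestAutosomalCounts:
    def test_blocks_on_sex_chromosome_not_counted(self, query_genome):
        bs = BlockSet("T", "Q", (make_block("t1", 0, 10 * MB, q_chrom="qX"),))
        assert count_autosomal_fragments(bs, query_genome, MB) == 0

    def test_ten_six_mbp_blocks_at_five_mbp_cutoff(self, query_genome):
        blocks = tuple(
            make_block("t1", i * 10 * MB, i * 10 * MB + 6 * MB, q_chrom="q1")
            for i in range(5)
        ) + tuple(
            make_block("t2", i * 10 * MB, i * 10 * MB + 6 * MB, q_chrom="q2")
            for i in range(5)
        )
        bs = BlockSet("T", "Q", blocks)
        assert count_autosomal_fragments(bs, query_genome, 5 * MB, inclusive=True) == 10

    def test_matches_brute_force_and_monotone_in_threshold(self, rng, query_genome):
        from conftest import random_blockset

        for _ in range(10):
            bs = random_blockset(rng, 60, n_query_chroms=3)
            # add some blocks on the sex chromosome
            extra = tuple(
                make_block("t1", i * 2 * MB, i * 2 * MB + int(rng.integers(1, 7)) * MB,
                           q_chrom="qX")
                for i in range(5)
            )
            bs = bs.with_blocks(bs.blocks + extra)
            brute = sum(
                1
                for b in bs
                if query_genome[b.query_chrom].is_autosome
                and (b.target_end - b.target_start) > MB
            )
            assert count_autosomal_fragments(bs, query_genome, MB) == brute
            counts = [
                count_autosomal_fragments(bs, query_genome, t)
                for t in (MB, 2 * MB, 5 * MB)
            ]
            assert counts == sorted(counts, reverse=True)

    def test_unknown_chromosome_rejected(self, query_genome):
        bs = BlockSet("T", "Q", (make_block("t1", 0, 2 * MB, q_chrom="q9"),))
        with pytest.raises(UnknownChromosomeError):
            count_autosomal_fragments(bs, query_genome, MB)

    def test_per_chromosome_table_sums_to_total(self, rng, query_genome):
        from conftest import random_blockset

        bs = random_blockset(rng, 50)
        table = fragment_count_table(bs, query_genome, MB)
        total_autosomal = table[table.is_autosome].n_blocks.sum()
        assert total_autosomal == count_autosomal_fragments(bs, query_genome, MB)


def test_format_pair_uses_natural_order():
    assert format_pair(frozenset({"21", "3"})) == "3/21"
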
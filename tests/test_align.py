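"""Mapper correctness against brute-force oracles: k-mer index completeness,
placement accuracy for clean and mutated reads, multi-mapper handling,
insert-size estimation, CIGAR accounting and SAM round-tripping."""

import numpy as np
import pytest

from strainforge._util import revcomp
from strainforge.align import (ReferenceIndex, Scoring, assign_multimappers,
                               cigar_query_len, estimate_insert_stats,
                               map_read_pairs, parse_cigar, read_sam, write_sam)
from strainforge.simulate import AncestorConfig, ReadSimConfig, build_ancestor
from strainforge.simulate.reads import ReadSet, SimRead, simulate_short_reads

from conftest import short_lib


def brute_force_affine(query, target, scoring=Scoring()):
    """Exhaustive semi-global affine-gap DP (free target end gaps):
    independent oracle for the mapper's best score."""
    n, m = len(query), len(target)
    NEG = -10 ** 9
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    Y = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    M[0, :] = 0
    for i in range(1, n + 1):
        for j in range(0, m + 1):
            if j > 0:
                s = scoring.match if query[i - 1] == target[j - 1] \
                    else scoring.mismatch
                M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                              Y[i - 1, j - 1]) + s
                X[i, j] = max(M[i, j - 1] + scoring.gap_open,
                              X[i, j - 1] + scoring.gap_extend)
            Y[i, j] = max(M[i - 1, j] + scoring.gap_open,
                          Y[i - 1, j] + scoring.gap_extend)
    return int(max(M[n, :].max(), X[n, :].max(), Y[n, :].max()))


class TestIndex:
    def test_small_example_positions(self):
        idx = ReferenceIndex("r", "ACGTACGT", k=4, circular=False)
        assert sorted(idx.positions("ACGT")) == [0, 4]
        assert idx.positions("TTTT") == []

    def test_all_kmers_found_at_true_positions(self, plain_ancestor):
        seq = plain_ancestor.sequence[:10_000]
        idx = ReferenceIndex("r", seq, k=17, circular=False)
        rng = np.random.default_rng(3)
        for start in rng.integers(0, len(seq) - 17, size=200):
            kmer = seq[start:start + 17]
            # brute-force scan oracle
            truth = [i for i in range(len(seq) - 16) if seq[i:i + 17] == kmer]
            assert sorted(idx.positions(kmer)) == truth

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndex("r", "ACGT" * 100, k=3)
        with pytest.raises(ValueError):
            ReferenceIndex("r", "ACGTAC", k=17)


class TestMapping:
    def test_error_free_reads_place_exactly(self, plain_ancestor, mapped_plain):
        reads, index, records, _ = mapped_plain
        L = len(plain_ancestor.sequence)
        by_read = {}
        for r in reads.reads:
            by_read[(r.read_id, r.mate)] = r
        correct = 0
        for rec in records:
            assert rec.mapped
            assert rec.nm == 0
            assert rec.cigar == f"{len(rec.seq)}M"
            true = by_read[(rec.read_id, rec.mate)]
            if rec.start == true.true_start % L:
                correct += 1
        assert correct == len(records)   # unique placement outside repeats

    def test_cigar_query_length_conservation(self, mapped_plain):
        _, _, records, _ = mapped_plain
        for rec in records:
            if rec.mapped:
                assert cigar_query_len(rec.cigar) == len(rec.seq)

    def test_substituted_reads_match_dp_oracle(self, plain_ancestor):
        """Reported affine score equals exhaustive DP over the true locus."""
        seq = plain_ancestor.sequence
        idx = ReferenceIndex("r", seq, k=17)
        rng = np.random.default_rng(5)
        for _ in range(20):
            start = int(rng.integers(0, len(seq) - 200))
            read = list(seq[start:start + 100])
            for pos in rng.choice(100, size=int(rng.integers(0, 3)),
                                  replace=False):
                read[pos] = "ACGT"[(("ACGT".index(read[pos])) + 1) % 4]
            if rng.random() < 0.5:  # also exercise deletions in the read
                cut = int(rng.integers(20, 70))
                read = read[:cut] + read[cut + 3:]
            read = "".join(read)
            rs = ReadSet("o", "pyro", False,
                         [SimRead("q", read, "I" * len(read))])
            rec = map_read_pairs(rs, idx)[0]
            assert rec.mapped
            window = seq[max(0, start - 20):start + len(read) + 20]
            assert rec.score == brute_force_affine(read, window)

    def test_two_copy_repeat_yields_multimap_two(self, small_ancestor):
        el = small_ancestor.is_elements[0]
        inner = small_ancestor.sequence[el.start + 100:el.start + 200]
        rs = ReadSet("o", "pyro", False, [SimRead("q", inner, "I" * 100)])
        idx = ReferenceIndex("r", small_ancestor.sequence, k=17)
        rec = map_read_pairs(rs, idx)[0]
        assert rec.multimap_count == 2

    def test_multimapper_assignment_uniform_and_reproducible(self, small_ancestor):
        el = small_ancestor.is_elements
        idx = ReferenceIndex("r", small_ancestor.sequence, k=17)
        inner = small_ancestor.sequence[el[0].start + 50: el[0].end - 50]
        rng = np.random.default_rng(8)
        reads = []
        n = 4_000
        for i in range(n):
            s = int(rng.integers(0, len(inner) - 60))
            reads.append(SimRead(f"q{i}", inner[s:s + 60], "I" * 60))
        rs = ReadSet("o", "pyro", False, reads)
        records = map_read_pairs(rs, idx)
        r1 = assign_multimappers([r for r in records], seed=13)
        first_copy = sum(1 for r in r1
                         if el[0].start <= r.start < el[0].end)
        # binomial 3-sigma bound around 50/50
        sigma = 0.5 * np.sqrt(n)
        assert abs(first_copy - n / 2) <= 3 * sigma
        r2 = map_read_pairs(rs, idx)
        assign_multimappers(r2, seed=13)
        assert [r.start for r in r1] == [r.start for r in r2]

    def test_reads_spanning_circular_origin_map(self, plain_ancestor):
        L = len(plain_ancestor.sequence)
        frag = (plain_ancestor.sequence * 2)[L - 50:L + 50]
        rs = ReadSet("o", "pyro", False, [SimRead("q", frag, "I" * 100)])
        idx = ReferenceIndex("r", plain_ancestor.sequence, k=17, circular=True)
        rec = map_read_pairs(rs, idx)[0]
        assert rec.mapped and rec.start == L - 50 and rec.nm == 0


class TestInsertStats:
    def test_recovers_simulation_parameters(self, plain_ancestor):
        reads = short_lib(plain_ancestor.sequence, seed=17, depth=40,
                          insert_mean=400.0, insert_sd=40.0)
        idx = ReferenceIndex("r", plain_ancestor.sequence, k=17)
        records = map_read_pairs(reads, idx)
        stats = estimate_insert_stats(records)
        assert 390 <= stats.insert_mean <= 410
        assert 25 <= stats.insert_sd <= 55

    def test_degenerate_identical_inserts_flagged(self, mapped_plain):
        _, _, records, _ = mapped_plain
        import copy

        fixed = []
        for r in records[:400]:
            c = copy.copy(r)
            c.insert = 400
            fixed.append(c)
        stats = estimate_insert_stats(fixed)
        assert stats.degenerate and stats.insert_sd == 0.0

    def test_robust_to_deletion_spanning_pairs(self, mapped_plain):
        """A minority of grossly inflated inserts (pairs straddling an
        undetected deletion) must not drag the location estimate."""
        import copy

        _, _, records, _ = mapped_plain
        contaminated = []
        for i, r in enumerate(records):
            c = copy.copy(r)
            if c.mate == 1 and c.proper and i % 10 == 0:
                c.insert = c.insert + 5_000
            contaminated.append(c)
        stats = estimate_insert_stats(contaminated)
        assert abs(stats.insert_mean - 700) < 30
        naive = np.mean([r.insert for r in contaminated
                         if r.mate == 1 and r.proper])
        assert naive - stats.insert_mean > 200  # the naive mean IS dragged

    def test_no_proper_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="no proper pairs"):
            estimate_insert_stats([])


class TestSAMRoundTrip:
    def test_primary_fields_survive(self, plain_ancestor, mapped_plain,
                                    tmp_path):
        _, index, records, _ = mapped_plain
        path = tmp_path / "out.sam"
        write_sam(records[:200], index, path)
        back = read_sam(path)
        assert len(back) == 200
        for orig, rt in zip(records[:200], back):
            assert (rt.read_id, rt.mate, rt.mapped) == \
                   (orig.read_id, orig.mate, orig.mapped)
            assert (rt.start, rt.strand, rt.cigar) == \
                   (orig.start, orig.strand, orig.cigar)
            assert rt.seq == orig.seq
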
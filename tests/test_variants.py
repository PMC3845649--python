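"""Pileup, filtered calling, consensus, assembly diffing and reciprocal
cross-strain confirmation — including the printed-allele-table worked
example of the eight variants separating the lab-stock and wild-derived
donor-strain isolates."""

import numpy as np
import pytest

from strainforge.align import AlignmentRecord, ReferenceIndex, \
    assign_multimappers, map_read_pairs
from strainforge.simulate import MutationEvent, apply_events
from strainforge.variants import (CallFilters, Pileup, allele_table_differences,
                                  call_variants, consensus_genome, cross_check,
                                  diff_assemblies, load_allele_table, pileup)

from conftest import short_lib


def synth_record(ref_name, start, seq, qual_phred=30, mate=None, nm=0):
    q = chr(33 + qual_phred) * len(seq)
    rec = AlignmentRecord(f"r{start}", mate, ref_name, mapped=True,
                          seq=seq, qual=q)
    rec.start = start
    rec.cigar = f"{len(seq)}M"
    rec.nm = nm
    return rec


class TestPileup:
    def test_counts_match_brute_force_recount(self, plain_ancestor,
                                              mapped_plain):
        _, _, records, pile = mapped_plain
        L = len(plain_ancestor.sequence)
        rng = np.random.default_rng(2)
        from strainforge.align import parse_cigar

        for pos in rng.integers(0, L, size=50):
            pos = int(pos)
            depth = 0
            for rec in records:
                if not rec.mapped:
                    continue
                p, consumed = rec.start, 0
                for op, n in parse_cigar(rec.cigar):
                    if op == "M":
                        if p <= pos < p + n or p <= pos + L < p + n:
                            depth += 1
                        p += n
                    elif op == "D":
                        p += n
            assert depth == int(pile.depth[pos])

    def test_allele_fraction_arithmetic(self):
        ref = "ACGTAGGCTA" * 10
        pile = Pileup("r", ref, circular=False)
        for i in range(7):
            pile.add_record(synth_record("r", 0, ref[:50]))
        alt_read = ref[:20] + ("A" if ref[20] != "A" else "C") + ref[21:50]
        for i in range(3):
            pile.add_record(synth_record("r", 0, alt_read, nm=1))
        col = pile.column(20)
        assert col.depth == 10
        assert col.counts[alt_read[20]] == 3
        assert col.counts[ref[20]] == 7

    def test_wrong_reference_rejected(self):
        pile = Pileup("a", "ACGT" * 100)
        with pytest.raises(ValueError, match="against"):
            pile.add_record(synth_record("b", 0, "ACGT"))


class TestCallVariants:
    def _pile_with_alt(self, depth, alt_count, qual):
        ref = "ACGTAGGCTA" * 30
        pile = Pileup("r", ref, circular=False)
        alt = "A" if ref[100] != "A" else "C"
        alt_read = ref[60:100] + alt + ref[101:160]
        for _ in range(depth - alt_count):
            pile.add_record(synth_record("r", 60, ref[60:160], qual))
        for _ in range(alt_count):
            pile.add_record(synth_record("r", 60, alt_read, qual, nm=1))
        return pile

    def test_quality_boundary_at_ten(self):
        filters = CallFilters.preset_published()
        assert call_variants(self._pile_with_alt(30, 30, 9), filters) == []
        calls = call_variants(self._pile_with_alt(30, 30, 10), filters)
        assert len(calls) == 1 and calls[0].position == 101

    def test_depth_bounds_suppress_collapsed_repeats(self):
        filters = CallFilters.preset_published()
        assert call_variants(self._pile_with_alt(221, 221, 30), filters) == []
        assert len(call_variants(self._pile_with_alt(220, 220, 30),
                                 filters)) == 1
        assert call_variants(self._pile_with_alt(9, 9, 30), filters) == []

    def test_error_free_matched_reads_give_zero_calls(self, mapped_plain):
        _, _, _, pile = mapped_plain
        calls = call_variants(pile, CallFilters.scaled(pile.mean_depth()))
        assert calls == []


class TestConsensus:
    def test_depth_window_boundaries(self):
        ref = "ACGTAGGCTA" * 30
        filters = CallFilters.preset_published()
        for depth, expected_n in ((9, True), (10, False), (100, False),
                                  (101, True)):
            pile = Pileup("r", ref, circular=False)
            for _ in range(depth):
                pile.add_record(synth_record("r", 100, ref[100:160]))
            cons = consensus_genome(pile, filters)
            assert (cons[120] == "N") is expected_n
            if not expected_n:
                assert cons[120] == ref[120]

    def test_error_free_consensus_equals_reference_where_covered(
            self, plain_ancestor, mapped_plain):
        _, _, _, pile = mapped_plain
        cons = consensus_genome(pile, CallFilters.scaled(pile.mean_depth()))
        assert len(cons) == len(plain_ancestor.sequence)
        for i, base in enumerate(cons):
            if base != "N":
                assert base == plain_ancestor.sequence[i]

    def test_monotone_in_coverage(self, plain_ancestor):
        """Adding error-free reads never flips a correct base to N or to a
        wrong base."""
        idx = ReferenceIndex(plain_ancestor.name, plain_ancestor.sequence)
        filters = CallFilters(d_min=10, d_max=10_000, c_min=10, c_max=10_000)
        half = short_lib(plain_ancestor.sequence, seed=31, depth=12,
                         eps_sub=0.0)
        more = short_lib(plain_ancestor.sequence, seed=32, depth=12,
                         eps_sub=0.0)
        rec1 = map_read_pairs(half, idx)
        rec2 = rec1 + map_read_pairs(more, idx)
        c1 = consensus_genome(pileup(rec1, plain_ancestor.name,
                                     plain_ancestor.sequence), filters)
        c2 = consensus_genome(pileup(rec2, plain_ancestor.name,
                                     plain_ancestor.sequence), filters)
        for b1, b2 in zip(c1, c2):
            if b1 != "N":
                assert b2 == b1


class TestDiffAssemblies:
    def test_identical_and_single_substitution(self, plain_ancestor):
        seq = plain_ancestor.sequence
        assert diff_assemblies(seq, seq) == []
        mutant = seq[:5_000] + ("A" if seq[5_000] != "A" else "G") + seq[5_001:]
        records = diff_assemblies(seq, mutant)
        assert len(records) == 1
        assert records[0].kind == "sub" and records[0].pos_a == 5_000

    def test_planted_difference_count_recovered(self, small_ancestor):
        """156 planted substitutions/small indels -> 156 records."""
        rng = np.random.default_rng(41)
        positions = sorted(int(p) for p in
                           rng.choice(19_000, size=156, replace=False) + 500)
        # enforce >= 12 bp spacing so adjacent events stay distinct records
        spaced, last = [], -100
        for p in positions:
            if p - last >= 12:
                spaced.append(p)
                last = p
        events = []
        for i, p in enumerate(spaced):
            if i % 10 == 0:
                events.append(MutationEvent(kind="small_indel", position=p,
                                            deletion_length=int(rng.integers(1, 9))))
            else:
                base = small_ancestor.sequence[p]
                alt = "ACGT"[("ACGT".index(base) + 1) % 4]
                events.append(MutationEvent(kind="snp", position=p, alt=alt))
        truth = apply_events(small_ancestor, events)
        records = diff_assemblies(small_ancestor.sequence, truth.sequence)
        assert len(records) == len(events)

    def test_n_positions_excluded(self):
        a = "ACGTACGTAC"
        b = "ACGTNCGTAC"
        assert diff_assemblies(a, b) == []

    def test_grossly_divergent_inputs_rejected(self):
        with pytest.raises(ValueError, match="divergent"):
            diff_assemblies("A" * 900 + "C" * 100, "G" * 500)


class TestCrossCheck:
    def _strain_pileups(self, plain_ancestor, planted_pos):
        seq = plain_ancestor.sequence
        alt = "A" if seq[planted_pos] != "A" else "G"
        mutant = seq[:planted_pos] + alt + seq[planted_pos + 1:]
        idx = ReferenceIndex(plain_ancestor.name, seq)
        out = {}
        for name, template, seed in (("A", mutant, 51), ("B", seq, 52)):
            reads = short_lib(template, seed=seed, depth=25)
            records = map_read_pairs(reads, idx)
            assign_multimappers(records, seed)
            out[name] = pileup(records, plain_ancestor.name, seq)
        return out, alt

    def test_confirmed_difference_requires_support_and_refutation(
            self, plain_ancestor):
        piles, alt = self._strain_pileups(plain_ancestor, 6_000)
        filters = CallFilters.scaled(25)
        calls = {name: call_variants(p, filters, name)
                 for name, p in piles.items()}
        confirmed, audit = cross_check(calls, piles, filters)
        assert len(confirmed) == 1
        d = confirmed[0]
        assert d.cls == "snp" and d.start == 6_000
        assert d.statuses == {"A": "supports", "B": "refutes"}

    def test_insufficient_depth_blocks_confirmation(self, plain_ancestor):
        piles, alt = self._strain_pileups(plain_ancestor, 6_000)
        filters = CallFilters.scaled(25)
        calls = {name: call_variants(p, filters, name)
                 for name, p in piles.items()}
        # degrade strain B's coverage at the site below d_min
        piles["B"].depth[5_990:6_010] = filters.d_min - 6
        confirmed, audit = cross_check(calls, piles, filters)
        assert confirmed == []
        assert any("insufficient" in entry["reason"] for entry in audit)


class TestAlleleTableWorkedExample:
    def test_bundled_table_pairwise_differences(self):
        table = load_allele_table()
        assert len(table) == 8
        dgrp_pop = allele_table_differences(table, "DGRP335", "wMelPop")
        assert len(dgrp_pop) == 8
        assert len(allele_table_differences(table, "DGRP338", "wMelPop")) == 8
        assert allele_table_differences(table, "CantonS", "wMelPop") == []
        # the two multi-base rows are indel-class differences
        assert sum(d.cls == "small_indel" for d in dgrp_pop) == 2

    def test_unknown_strain_rejected(self):
        with pytest.raises(KeyError):
            allele_table_differences(load_allele_table(), "nope", "wMelPop")
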
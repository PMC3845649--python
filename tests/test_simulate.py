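"""Generator correctness: genome construction, event application with exact
truth bookkeeping, and the two read-technology error models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainforge._util import gc_content, revcomp
from strainforge.simulate import (AncestorConfig, LayoutInfeasibleError,
                                  MutationEvent, ReadSimConfig, apply_events,
                                  build_ancestor, read_truth,
                                  simulate_pyro_reads, simulate_short_reads,
                                  write_truth)
from strainforge.simulate.reads import _hp_distort

from conftest import short_lib


class TestBuildAncestor:
    def test_deterministic_and_valid(self):
        cfg = AncestorConfig(length=30_000, gc=0.36, placements=[
            ("is", {"family": "IS5", "length": 900, "copies": 3}),
            ("direct_pair", {"length": 500, "gap": 3_000}),
            ("inverted_pair", {"length": 500, "gap": 3_000})])
        g1 = build_ancestor(cfg, seed=1)
        g2 = build_ancestor(cfg, seed=1)
        assert g1.sequence == g2.sequence
        g1.validate()
        assert len(g1.is_elements) == 3
        assert build_ancestor(cfg, seed=2).sequence != g1.sequence

    def test_gc_within_two_points_of_target(self, small_ancestor):
        assert 0.34 <= gc_content(small_ancestor.sequence) <= 0.38

    def test_is_elements_have_terminal_inverted_repeats(self, small_ancestor):
        el = small_ancestor.is_elements[0]
        seq = small_ancestor.sequence[el.start:el.end]
        assert seq[:el.tir_len] == revcomp(seq[-el.tir_len:])

    def test_infeasible_layout_raises(self):
        cfg = AncestorConfig(length=10_000, placements=[
            ("direct_pair", {"length": 500, "gap": 19_000})])
        with pytest.raises(LayoutInfeasibleError):
            build_ancestor(cfg, seed=1)


class TestApplyEvents:
    def test_triplication_adds_two_unit_lengths(self, small_ancestor):
        ev = MutationEvent(kind="tandem_amplification", interval=(2_000, 3_900), m=3)
        truth = apply_events(small_ancestor, [ev])
        assert len(truth.sequence) == len(small_ancestor.sequence) + 2 * 1_900

    def test_array_deletion_loses_three_unit_lengths(self):
        # amplified array flanked by direct repeats, then removed by a
        # single recombination: ~3 x 19 kb lost
        anc = build_ancestor(AncestorConfig(
            length=100_000, gc=0.36,
            placements=[("direct_pair",
                         {"length": 400, "gap": 18_600, "start": 30_000})]),
            seed=3)
        r1, r2 = anc.direct_repeat_pairs[0].first, anc.direct_repeat_pairs[0].second
        pop = apply_events(anc, [MutationEvent(
            kind="tandem_amplification", interval=(r1[1], r2[1]), m=3)], "pop")
        model = pop.to_model()
        from strainforge.simulate.genome import RepeatPair

        shift = 2 * (r2[1] - r1[1])
        model.direct_repeat_pairs = [
            RepeatPair(r1, (r2[0] + shift, r2[1] + shift))]
        cla = apply_events(model, [MutationEvent(
            kind="segmental_deletion",
            interval=(r1[1], r2[1] + shift))], "cla")
        lost = len(pop.sequence) - len(cla.sequence)
        assert lost == 57_000
        assert abs(lost - 57_000) <= 1_000

    def test_snp_changes_exactly_one_base(self, small_ancestor):
        pos, alt = 9_999, "A"
        anc_seq = small_ancestor.sequence
        if anc_seq[pos] == alt:
            alt = "C"
        truth = apply_events(small_ancestor, [
            MutationEvent(kind="snp", position=pos, alt=alt)])
        # brute-force diff oracle
        diffs = [i for i, (a, b) in enumerate(zip(anc_seq, truth.sequence))
                 if a != b]
        assert diffs == [pos]

    def test_liftover_identity_on_unmutated_positions(self, small_ancestor):
        events = [MutationEvent(kind="snp", position=2_000, alt="A"
                                if small_ancestor.sequence[2_000] != "A" else "C"),
                  MutationEvent(kind="small_indel", position=6_000,
                                deletion_length=7),
                  MutationEvent(kind="small_indel", position=9_000,
                                insertion_seq="GATTACA")]
        truth = apply_events(small_ancestor, events)
        mutated = set(range(2_000, 2_001)) | set(range(6_000, 6_007))
        for pos in range(0, len(small_ancestor.sequence), 13):
            if pos in mutated:
                continue
            lifted = truth.liftover.lift(pos)
            assert lifted is not None
            assert truth.sequence[lifted] == small_ancestor.sequence[pos]

    def test_overlapping_events_rejected(self, small_ancestor):
        with pytest.raises(ValueError, match="overlap"):
            apply_events(small_ancestor, [
                MutationEvent(kind="small_indel", position=500, deletion_length=10),
                MutationEvent(kind="snp", position=505, alt="A")])

    def test_unbounded_deletion_rejected(self, small_ancestor):
        with pytest.raises(ValueError, match="direct repeat"):
            apply_events(small_ancestor, [
                MutationEvent(kind="segmental_deletion", interval=(100, 600))])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 18), st.integers(1, 30)),
                    min_size=1, max_size=6, unique_by=lambda t: t[0]))
    def test_length_accounting_property(self, small_ancestor, spots):
        """derived length - ancestor length == sum of event deltas."""
        events = []
        for slot, size in spots:
            pos = 500 + slot * 1_000  # disjoint 1-kb slots keep events apart
            if size % 2:
                events.append(MutationEvent(kind="small_indel", position=pos,
                                            deletion_length=size))
            else:
                events.append(MutationEvent(kind="small_indel", position=pos,
                                            insertion_seq="ACGT" * (size // 4 + 1)))
        truth = apply_events(small_ancestor, events)
        delta = sum(e.length_delta(small_ancestor) for e in events)
        assert len(truth.sequence) - len(small_ancestor.sequence) == delta


class TestReadSimulation:
    def test_error_free_short_reads_are_exact_substrings(self, plain_ancestor):
        reads = short_lib(plain_ancestor.sequence, seed=2, eps_sub=0.0)
        doubled = plain_ancestor.sequence * 2
        for r in reads.reads[:400]:
            assert (r.seq in doubled) or (revcomp(r.seq) in doubled)

    def test_error_free_pyro_reads_are_exact_substrings(self, plain_ancestor):
        cfg = ReadSimConfig(technology="pyro", paired=False, depth=10,
                            eps_hp=0.0, eps_sub=0.0)
        reads = simulate_pyro_reads(plain_ancestor.sequence, cfg, seed=2)
        doubled = plain_ancestor.sequence * 2
        for r in reads.reads:
            assert (r.seq in doubled) or (revcomp(r.seq) in doubled)

    def test_forced_homopolymer_error_never_preserves_run(self):
        template = "GCGT" + "A" * 6 + "TGCG"
        g = np.random.default_rng(0)
        for _ in range(50):
            out = _hp_distort(template, eps_hp=1.0, pmax=1.0, rng=g)
            run = max(len(s) for s in out.split("T") if set(s) <= {"A"})
            assert run in (5, 7)

    def test_pyro_depth_within_ten_percent(self, plain_ancestor):
        cfg = ReadSimConfig(technology="pyro", paired=False, depth=40)
        reads = simulate_pyro_reads(plain_ancestor.sequence, cfg, seed=9)
        target = 40 * len(plain_ancestor.sequence)
        assert 0.9 * target <= reads.total_bases() <= 1.1 * target

    def test_insert_mean_within_standard_error(self, plain_ancestor):
        reads = short_lib(plain_ancestor.sequence, seed=7, depth=60,
                          insert_mean=400.0, insert_sd=40.0, eps_sub=0.0)
        inserts = []
        for m1, m2 in reads.pairs():
            inserts.append((m2.true_start + 100 - m1.true_start)
                           % len(plain_ancestor.sequence))
        mean = float(np.mean(inserts))
        n = len(inserts)
        assert abs(mean - 400.0) <= 3 * 40.0 / np.sqrt(n) + 1.0

    def test_seeded_determinism(self, plain_ancestor):
        a = short_lib(plain_ancestor.sequence, seed=4)
        b = short_lib(plain_ancestor.sequence, seed=4)
        assert [(r.read_id, r.seq, r.qual) for r in a.reads] == \
               [(r.read_id, r.seq, r.qual) for r in b.reads]

    def test_insert_shorter_than_read_span_rejected(self, plain_ancestor):
        cfg = ReadSimConfig(technology="short", read_length=100, paired=True,
                            insert_mean=150, depth=5)
        with pytest.raises(ValueError, match="insert_mean"):
            simulate_short_reads(plain_ancestor.sequence, cfg, seed=1)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_pyro_reads("", ReadSimConfig(technology="pyro",
                                                  paired=False), seed=1)


class TestTruthFiles:
    def test_round_trip_reproduces_events(self, small_ancestor, tmp_path):
        alt = "A" if small_ancestor.sequence[1_000] != "A" else "G"
        events = [
            MutationEvent(kind="snp", position=1_000, alt=alt),
            MutationEvent(kind="snp", position=3_000,
                          alt="C" if small_ancestor.sequence[3_000] != "C" else "T"),
            MutationEvent(kind="small_indel", position=7_000, deletion_length=10),
            MutationEvent(kind="tandem_amplification", interval=(15_000, 16_000),
                          m=3),
        ]
        truth = apply_events(small_ancestor, events)
        write_truth(truth, tmp_path / "t.vcf", tmp_path / "t.bed")
        vcf_lines = [ln for ln in (tmp_path / "t.vcf").read_text().splitlines()
                     if not ln.startswith("#")]
        bed_lines = [ln for ln in (tmp_path / "t.bed").read_text().splitlines()
                     if not ln.startswith("#")]
        assert len(vcf_lines) == 3 and len(bed_lines) == 1
        back = read_truth(tmp_path / "t.vcf", tmp_path / "t.bed", small_ancestor)
        assert [(e.kind, e.span()) for e in back] == \
               [(e.kind, e.span()) for e in sorted(events, key=lambda e: e.span()[0])]

    def test_ten_bp_deletion_encoded_as_anchored_indel(self, small_ancestor,
                                                       tmp_path):
        truth = apply_events(small_ancestor, [MutationEvent(
            kind="small_indel", position=5_000, deletion_length=10)])
        write_truth(truth, tmp_path / "t.vcf", tmp_path / "t.bed")
        record = [ln for ln in (tmp_path / "t.vcf").read_text().splitlines()
                  if not ln.startswith("#")][0].split("\t")
        assert len(record[3]) == 11 and len(record[4]) == 1
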
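"""Discordant-pair classification, candidate clustering, split-read IS
detection and evidence reconciliation against planted structural truth."""

import numpy as np
import pytest

from strainforge.align import (AlignmentRecord, PairStats, ReferenceIndex,
                               assign_multimappers, estimate_insert_stats,
                               map_read_pairs)
from strainforge.cnv import segment_copy_number, window_coverage
from strainforge.simulate import (AncestorConfig, MutationEvent, apply_events,
                                  build_ancestor)
from strainforge.svscan import (SVParams, classify_pairs, cluster_candidates,
                                find_is_insertions, is_presence_matrix,
                                reconcile)
from strainforge.variants import pileup

from conftest import short_lib

STATS = PairStats(insert_mean=400.0, insert_sd=40.0, n=1_000)


def make_pair(rid, s1, strand1, s2, strand2, rlen=100, mapped1=True,
              mapped2=True, L=100_000):
    out = []
    for mate, (s, strand, mapped) in enumerate(
            [(s1, strand1, mapped1), (s2, strand2, mapped2)], start=1):
        rec = AlignmentRecord(rid, mate, "r", mapped=mapped,
                              seq="A" * rlen, qual="I" * rlen)
        if mapped:
            rec.start = s
            rec.strand = strand
            rec.cigar = f"{rlen}M"
            rec.nm = 0
        out.append(rec)
    out[0].mate_mapped, out[1].mate_mapped = out[1].mapped, out[0].mapped
    return out


class TestClassifyPairs:
    def test_each_class_and_exclusivity(self):
        records = (
            make_pair("far", 1_000, "+", 6_000, "-") +       # insert ~6 kb
            make_pair("same", 1_000, "+", 2_000, "+") +      # same strand
            make_pair("outward", 2_000, "-", 5_000, "+") +   # everted
            make_pair("half", 1_000, "+", 0, "+", mapped2=False) +
            make_pair("ok", 1_000, "+", 1_300, "-"))         # proper-ish
        pairs = classify_pairs(records, STATS, z=4.0, genome_length=100_000)
        by_id = {p.read_id: p.cls for p in pairs}
        assert by_id == {"far": "too_far", "same": "bad_orientation",
                         "outward": "bad_orientation",
                         "half": "one_end_unmapped"}
        # exclusivity: one classification per discordant pair
        assert len(pairs) == len(by_id)

    def test_gaussian_tail_quiet_on_clean_library(self, plain_ancestor,
                                                  mapped_plain):
        _, _, records, _ = mapped_plain
        stats = estimate_insert_stats(records)
        pairs = classify_pairs(records, stats, z=4.0,
                               genome_length=len(plain_ancestor.sequence))
        # expected Gaussian tail at z=4 is ~6e-5 per pair
        assert len(pairs) <= max(3, int(len(records) / 2 * 1e-3))


class TestClustering:
    def test_scattered_noise_yields_no_candidate(self):
        pairs = []
        for i, start in enumerate((5_000, 20_000, 40_000, 60_000)):
            p = make_pair(f"n{i}", start, "+", start + 6_000, "-")
            pairs += classify_pairs(p, STATS, genome_length=100_000)
        cands = cluster_candidates(pairs, None, SVParams(s_min=3), STATS)
        assert cands == []

    def test_concordant_deletion_cluster(self):
        records = []
        for i in range(6):
            records += make_pair(f"d{i}", 10_000 + i * 17, "+",
                                 15_300 + i * 13, "-")
        pairs = classify_pairs(records, STATS, genome_length=100_000)
        cands = cluster_candidates(pairs, None, SVParams(s_min=3), STATS)
        assert len(cands) == 1
        c = cands[0]
        assert c.type == "deletion" and c.support == 6
        assert 10_000 < c.interval[0] < 10_300
        assert abs(c.detail["insert_excess_estimate"] -
                   (15_400 - 10_040 - 400)) < 250


class TestInversionDetection:
    def test_planted_inversion_recovered_with_flank_annotation(self):
        anc = build_ancestor(AncestorConfig(
            length=40_000, gc=0.36,
            placements=[("inverted_pair",
                         {"length": 400, "gap": 6_000, "start": 15_000})]),
            seed=7)
        pair = anc.inverted_repeat_pairs[0]
        iv = (pair.first[1], pair.second[0])
        truth = apply_events(anc, [MutationEvent(kind="inversion", interval=iv)])
        idx = ReferenceIndex(anc.name, anc.sequence, k=17)
        reads = short_lib(truth.sequence, seed=71, depth=35)
        records = map_read_pairs(reads, idx)
        assign_multimappers(records, 71)
        stats = estimate_insert_stats(records)
        pairs = classify_pairs(records, stats, genome_length=len(anc.sequence))
        cands = cluster_candidates(pairs, records, SVParams(), stats, anc)
        inv = [c for c in cands if c.type == "inversion"]
        assert len(inv) == 1
        assert inv[0].flanking_repeat == "inverted"
        assert inv[0].support >= 10


class TestISInsertions:
    @pytest.fixture(scope="class")
    def is_setup(self, small_ancestor):
        idx = ReferenceIndex(small_ancestor.name, small_ancestor.sequence, k=17)
        catalog = dict(small_ancestor.is_family_seqs)
        insert_pos = 16_000
        truth = apply_events(small_ancestor, [MutationEvent(
            kind="is_insertion", position=insert_pos, family="IS5")])
        with_reads = short_lib(truth.sequence, seed=81, depth=35)
        without_reads = short_lib(small_ancestor.sequence, seed=82, depth=35)
        return idx, catalog, insert_pos, with_reads, without_reads

    def test_new_site_found_within_ten_bp_both_junctions(
            self, small_ancestor, is_setup):
        idx, catalog, insert_pos, with_reads, _ = is_setup
        sites = find_is_insertions(with_reads, catalog, idx,
                                   reference=small_ancestor)
        new = [s for s in sites if s.status == "new"]
        assert len(new) == 1
        s = new[0]
        assert abs(s.site[0] - insert_pos) <= 10
        assert s.support_left >= 2 and s.support_right >= 2
        # the two ancestral copies are seen as ancestral, not new
        assert sum(x.status == "ancestral" for x in sites) >= 2

    def test_strain_without_insertion_lacks_the_site(self, small_ancestor,
                                                     is_setup):
        idx, catalog, insert_pos, _, without_reads = is_setup
        sites = find_is_insertions(without_reads, catalog, idx,
                                   reference=small_ancestor)
        assert all(abs(s.site[0] - insert_pos) > 50 for s in sites
                   if s.status == "new")

    def test_presence_matrix_distinguishes_strains(self, small_ancestor,
                                                   is_setup):
        idx, catalog, insert_pos, with_reads, without_reads = is_setup
        piles = {}
        for name, rs in (("carrier", with_reads), ("empty", without_reads)):
            records = map_read_pairs(rs, idx)
            assign_multimappers(records, 9)
            piles[name] = pileup(records, small_ancestor.name,
                                 small_ancestor.sequence)
        sites = {name: find_is_insertions(rs, catalog, idx,
                                          reference=small_ancestor)
                 for name, rs in (("carrier", with_reads),
                                  ("empty", without_reads))}
        matrix = is_presence_matrix(sites, piles)
        new_rows = matrix[matrix.status == "new"]
        assert len(new_rows) == 1
        row = new_rows.iloc[0]
        assert row["carrier"] == "present" and row["empty"] == "absent"
        shared = matrix[matrix.status == "ancestral"]
        assert all((shared["carrier"] == "present") &
                   (shared["empty"] == "present"))

    def test_no_tir_reads_gives_empty_list(self, small_ancestor):
        from strainforge.simulate.reads import ReadSet, SimRead

        idx = ReferenceIndex(small_ancestor.name, small_ancestor.sequence, k=17)
        rs = ReadSet("x", "pyro", False,
                     [SimRead("q", small_ancestor.sequence[100:200], "I" * 100)])
        assert find_is_insertions(rs, small_ancestor.is_family_seqs, idx) == []

    def test_empty_catalog_is_an_error(self, small_ancestor, is_setup):
        idx, _, _, with_reads, _ = is_setup
        with pytest.raises(ValueError, match="catalog"):
            find_is_insertions(with_reads, {}, idx)


class TestReconcile:
    def test_ratio_below_copy_threshold_unconfirmed(self):
        from strainforge.cnv import CNSegment, CoverageProfile

        profile_a = CoverageProfile(50, np.full(200, 30.0), 30.0, 10_000)
        values_b = np.full(200, 30.0)
        values_b[40:80] = 36.0  # ratio 1.2: not an integer copy change
        profile_b = CoverageProfile(50, values_b, 30.0, 10_000)
        confirmed, audit = reconcile(
            {"A": [], "B": []}, {"A": profile_a, "B": profile_b},
            {"A": [], "B": []}, None, "A", "B")
        assert confirmed == []

    def test_is_site_in_both_strains_not_reported(self):
        import pandas as pd

        matrix = pd.DataFrame([{"family": "IS5", "start": 100, "end": 120,
                                "status": "ancestral",
                                "A": "present", "B": "present"}])
        from strainforge.cnv import CoverageProfile

        prof = CoverageProfile(50, np.full(200, 30.0), 30.0, 10_000)
        confirmed, _ = reconcile({"A": [], "B": []}, {"A": prof, "B": prof},
                                 {"A": [], "B": []}, matrix, "A", "B")
        assert confirmed == []


class TestFalsePositiveSuppression:
    def test_no_confirmed_svs_on_sv_free_libraries_over_seeds(
            self, plain_ancestor):
        """Twenty independent SV-free libraries: no cluster ever reaches
        the support threshold at z=4, s_min=3."""
        idx = ReferenceIndex(plain_ancestor.name, plain_ancestor.sequence, k=17)
        params = SVParams(z=4.0, s_min=3)
        for seed in range(20):
            reads = short_lib(plain_ancestor.sequence, seed=100 + seed,
                              depth=30)
            records = map_read_pairs(reads, idx)
            assign_multimappers(records, seed)
            stats = estimate_insert_stats(records)
            pairs = classify_pairs(records, stats, params.z,
                                   genome_length=len(plain_ancestor.sequence))
            cands = cluster_candidates(pairs, records, params, stats)
            assert cands == []
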
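"""Structural-difference discovery.

Three mutually exclusive discordant-pair classes, evaluated in declared
order, drive the scan:

1. ``one_end_unmapped`` — exactly one mate aligns to the reference
   (candidate insertion of novel material in the query strain);
2. ``bad_orientation`` — both mates align but violate the inward-facing
   convention (same-strand pairs flag inversions; outward/everted pairs
   flag tandem-duplication junctions);
3. ``too_far`` — inward pairs whose inferred fragment exceeds the robust
   insert mean by z standard deviations (candidate deletion).

Pairs whose implied intervals mutually overlap are clustered; clusters
reaching the support threshold become typed SV candidates, annotated with
any direct/inverted repeat pair flanking them in the reference catalog
(repeat-flanked deletions are recombination-compatible).

IS-element insertions are found independently of pair geometry, from split
reads: a read carrying a terminal-inverted-repeat (TIR) match plus enough
non-element flank is split, the flank is mapped, and flank placements are
clustered into insertion sites; sites at cataloged reference element edges
are labeled ancestral, all others new.  Per-strain presence/absence of each
site is what makes an insertion a strain difference.

``reconcile`` automates the final manual-inspection step as concordance
rules between coverage segments, discordant clusters and split-read sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp
from .align import (AlignmentRecord, PairStats, ReferenceIndex, Scoring,
                    _map_single, cigar_query_len, parse_cigar)
from .cnv import CNSegment, CoverageProfile
from .simulate.genome import GenomeModel
from .simulate.reads import ReadSet
from .variants import ConfirmedDifference, Pileup


@dataclass
class SVParams:
    z: float = 4.0                 # "significantly further apart" threshold
    s_min: int = 3                 # minimum supporting pairs per cluster
    tir_min_len: int = 15
    tir_min_ident: float = 0.9
    flank_min: int = 20
    cluster_window: int = 30       # IS junction clustering half-width
    min_junction_support: int = 2
    repeat_flank_tol: int = 2000   # breakpoint-to-repeat distance for annotation
    cnv_overlap_tol: int = 2000


@dataclass
class DiscordantPair:
    read_id: str
    cls: str                        # too_far | bad_orientation | one_end_unmapped
    interval: tuple[int, int]       # implied SV interval (reference coords)
    insert: int = 0
    orientation: str = ""           # same_strand | outward (bad_orientation only)
    ends: tuple = ()


@dataclass
class SVCandidate:
    type: str                       # deletion | inversion | novel_insertion | tandem_dup
    interval: tuple[int, int]
    support: int
    clipped_support: int = 0
    flanking_repeat: str = "none"   # direct | inverted | none
    detail: dict = field(default_factory=dict)


@dataclass
class ISInsertion:
    family: str
    site: tuple[int, int]           # reference coordinate interval of the junction
    orientation: str
    support_left: int
    support_right: int
    status: str = "new"             # new | ancestral

    @property
    def support(self) -> int:
        return self.support_left + self.support_right


# ---------------------------------------------------------------------------
# Discordant-pair classification
# ---------------------------------------------------------------------------

def classify_pairs(records: list[AlignmentRecord], stats: PairStats,
                   z: float = 4.0, genome_length: int | None = None,
                   circular: bool = True) -> list[DiscordantPair]:
    """Classify every non-proper read pair into exactly one discordance
    class.  Pairs where an ambiguous (multi-placement, unresolved) mate
    would have to be trusted are skipped rather than guessed."""
    out: list[DiscordantPair] = []
    cutoff = stats.insert_mean + z * max(stats.insert_sd, 1.0)
    pad = int(stats.insert_mean + 3 * max(stats.insert_sd, 1.0))
    i = 0
    while i < len(records):
        rec = records[i]
        if rec.mate is None:
            i += 1
            continue
        if i + 1 >= len(records) or records[i + 1].read_id != rec.read_id:
            raise ValueError("records are not in mate-adjacent order")
        mate = records[i + 1]
        i += 2
        if not rec.mapped and not mate.mapped:
            continue
        if rec.mapped != mate.mapped:
            m = rec if rec.mapped else mate
            if m.multimap_count > 1:
                continue
            s, e = m.start, m.ref_end()
            iv = (max(0, s - pad), e + pad)
            out.append(DiscordantPair(rec.read_id, "one_end_unmapped", iv,
                                      ends=((s, e, m.strand),)))
            continue
        if rec.proper and rec.insert <= cutoff:
            continue  # concordant
        if rec.multimap_count > 1 or mate.multimap_count > 1:
            continue  # ambiguous placement: no SV evidence
        if "S" in rec.cigar or "S" in mate.cigar:
            continue  # clipped mates carry junction, not pair-geometry, signal
        a, b = sorted((rec, mate), key=lambda r: r.start)
        gl = genome_length or max(a.ref_end(), b.ref_end())
        if rec.strand == mate.strand:
            iv = (a.start, max(a.ref_end(), b.ref_end()))
            out.append(DiscordantPair(rec.read_id, "bad_orientation", iv,
                                      orientation="same_strand",
                                      ends=((a.start, a.ref_end(), a.strand),
                                            (b.start, b.ref_end(), b.strand))))
            continue
        fwd, rev = (rec, mate) if rec.strand == "+" else (mate, rec)
        d = (rev.ref_end() - fwd.start) % gl if circular else rev.ref_end() - fwd.start
        inward = 0 < d <= (gl // 2 if circular else gl)
        if not inward:
            iv = (a.start, max(a.ref_end(), b.ref_end()))
            out.append(DiscordantPair(rec.read_id, "bad_orientation", iv,
                                      orientation="outward",
                                      ends=((a.start, a.ref_end(), a.strand),
                                            (b.start, b.ref_end(), b.strand))))
            continue
        if d > cutoff:
            iv = (fwd.ref_end() % gl, rev.start % gl)
            out.append(DiscordantPair(rec.read_id, "too_far", iv, insert=int(d),
                                      ends=((fwd.start, fwd.ref_end(), "+"),
                                            (rev.start, rev.ref_end(), "-"))))
    return out


# ---------------------------------------------------------------------------
# Clustering into SV candidates
# ---------------------------------------------------------------------------

def cluster_candidates(pairs: list[DiscordantPair],
                       clipped_records: list[AlignmentRecord] | None = None,
                       params: SVParams | None = None,
                       stats: PairStats | None = None,
                       reference: GenomeModel | None = None) -> list[SVCandidate]:
    params = params or SVParams()
    clip_edges: list[int] = []
    if clipped_records:
        for rec in clipped_records:
            if rec.mapped and "S" in rec.cigar:
                ops = parse_cigar(rec.cigar)
                if ops[0][0] == "S":
                    clip_edges.append(rec.start)
                if ops[-1][0] == "S":
                    clip_edges.append(rec.ref_end())
    candidates: list[SVCandidate] = []

    def clip_support(iv, tol=200):
        return sum(1 for p in clip_edges if iv[0] - tol <= p <= iv[1] + tol)

    groups: dict[str, list[DiscordantPair]] = {}
    for p in pairs:
        key = p.cls if p.cls != "bad_orientation" else f"bad_orientation:{p.orientation}"
        groups.setdefault(key, []).append(p)

    tol = int(stats.insert_mean + 3 * max(stats.insert_sd, 1.0)) if stats else 1000
    if reference is not None and reference.is_elements:
        # orientation evidence anchored inside a mobile element is a
        # junction artifact of element copies, not rearrangement signal
        is_ivs = [(el.start - 50, el.end + 50) for el in reference.is_elements]

        def in_element(p: DiscordantPair) -> bool:
            return any(s <= end[0] <= e or s <= end[1] <= e
                       for end in p.ends for s, e in is_ivs)

        for key in list(groups):
            if key.startswith("bad_orientation"):
                groups[key] = [p for p in groups[key] if not in_element(p)]
    for key, members in groups.items():
        for cluster in _cluster_by_endpoints(members, tol):
            if len(cluster) < params.s_min:
                continue
            ivs = np.array([p.interval for p in cluster])
            if key == "too_far":
                # deletion lies inside the intersection of implied intervals
                bp = (int(np.median(ivs[:, 0])), int(np.median(ivs[:, 1])))
                inserts = [p.insert for p in cluster]
                detail = {"insert_excess_estimate":
                          float(np.median(inserts)) - (stats.insert_mean if stats else 0.0)}
                cand = SVCandidate("deletion", bp, len(cluster),
                                   clip_support(bp), detail=detail)
            elif key == "bad_orientation:same_strand":
                bp = (int(np.median(ivs[:, 0])), int(np.median(ivs[:, 1])))
                cand = SVCandidate("inversion", bp, len(cluster), clip_support(bp))
            elif key == "bad_orientation:outward":
                bp = (int(ivs[:, 0].min()), int(ivs[:, 1].max()))
                cand = SVCandidate("tandem_dup", bp, len(cluster), clip_support(bp))
            else:  # one_end_unmapped
                bp = (int(np.median(ivs[:, 0])), int(np.median(ivs[:, 1])))
                cand = SVCandidate("novel_insertion", bp, len(cluster), clip_support(bp))
            if reference is not None:
                cand.flanking_repeat = _flank_annotation(cand, reference, params)
            candidates.append(cand)
    return sorted(candidates, key=lambda c: c.interval)


def _cluster_by_endpoints(members: list[DiscordantPair], tol: int
                          ) -> list[list[DiscordantPair]]:
    """Cluster pairs whose implied intervals agree at BOTH ends (within
    tol).  Overlap alone is not enough: two unrelated wide-spanning noise
    pairs can overlap hugely while describing nothing in common."""
    members = sorted(members, key=lambda p: p.interval)
    clusters: list[list[DiscordantPair]] = []
    for p in members:
        placed = False
        for cl in clusters:
            s0 = float(np.median([q.interval[0] for q in cl]))
            e0 = float(np.median([q.interval[1] for q in cl]))
            if abs(p.interval[0] - s0) <= tol and abs(p.interval[1] - e0) <= tol:
                cl.append(p)
                placed = True
                break
        if not placed:
            clusters.append([p])
    return clusters


def _flank_annotation(cand: SVCandidate, ref: GenomeModel, params: SVParams) -> str:
    s, e = cand.interval
    tol = params.repeat_flank_tol
    for pair in ref.direct_repeat_pairs:
        if abs(pair.first[1] - s) <= tol and abs(pair.second[1] - e) <= tol:
            return "direct"
        if abs(pair.first[0] - s) <= tol and abs(pair.second[0] - e) <= tol:
            return "direct"
    for pair in ref.inverted_repeat_pairs:
        if abs(pair.first[1] - s) <= tol and abs(pair.second[0] - e) <= tol:
            return "inverted"
    return "none"


# ---------------------------------------------------------------------------
# IS insertion discovery from TIR split reads
# ---------------------------------------------------------------------------

def _tir_of(element: str, max_len: int = 60) -> str:
    """Longest terminal inverted repeat of an element sequence."""
    n = min(max_len, len(element) // 2)
    best = 0
    for t in range(4, n + 1):
        if element[:t] == revcomp(element[-t:]):
            best = t
    return element[:best]


def _find_tir(seq: str, tir: str, min_ident: float) -> list[int]:
    """Start offsets of (near-)exact TIR occurrences in seq."""
    hits = []
    start = seq.find(tir)
    while start != -1:
        hits.append(start)
        start = seq.find(tir, start + 1)
    if hits:
        return hits
    # seed on the TIR prefix, verify overall identity
    seed = tir[:12]
    start = seq.find(seed)
    while start != -1:
        frag = seq[start:start + len(tir)]
        if len(frag) == len(tir):
            ident = sum(a == b for a, b in zip(frag, tir)) / len(tir)
            if ident >= min_ident:
                hits.append(start)
        start = seq.find(seed, start + 1)
    return hits


def find_is_insertions(readset: ReadSet, is_catalog: dict[str, str],
                       index: ReferenceIndex,
                       params: SVParams | None = None,
                       reference: GenomeModel | None = None,
                       scoring: Scoring | None = None) -> list[ISInsertion]:
    """Locate IS-element junctions from reads that contain a TIR match plus
    >= flank_min bp of non-element sequence; the flank is mapped back to the
    reference and flank placements are clustered into sites."""
    if not is_catalog:
        raise ValueError("IS catalog is empty")
    params = params or SVParams()
    scoring = scoring or Scoring()

    junction_hits: dict[str, list[tuple[int, str]]] = {fam: [] for fam in is_catalog}
    for fam, element in is_catalog.items():
        tir = _tir_of(element)
        if len(tir) < params.tir_min_len:
            raise ValueError(f"element {fam!r} TIR shorter than tir_min_len")
        rtir = revcomp(tir)
        for read in readset.reads:
            for seq in (read.seq, revcomp(read.seq)):
                found = False
                for off in _find_tir(seq, tir, params.tir_min_ident):
                    # element body extends rightward; unique flank on the left
                    flank = seq[:off]
                    if len(flank) >= params.flank_min:
                        pos = _place_flank(flank, index, scoring, side="left")
                        if pos is not None:
                            junction_hits[fam].append((pos, "left"))
                            found = True
                for off in _find_tir(seq, rtir, params.tir_min_ident):
                    end = off + len(rtir)
                    flank = seq[end:]
                    if len(flank) >= params.flank_min:
                        pos = _place_flank(flank, index, scoring, side="right")
                        if pos is not None:
                            junction_hits[fam].append((pos, "right"))
                            found = True
                if found:
                    break  # do not double-count the same read on both strands

    ancestral_edges: list[tuple[int, int]] = []
    if reference is not None:
        ancestral_edges = [(el.start, el.end) for el in reference.is_elements]
    else:
        for fam, element in is_catalog.items():
            doubled = index.seq + index.seq[:len(element)]
            start = doubled.find(element)
            while start != -1 and start < index.L:
                ancestral_edges.append((start, start + len(element)))
                start = doubled.find(element, start + 1)
            rev = revcomp(element)
            start = doubled.find(rev)
            while start != -1 and start < index.L:
                ancestral_edges.append((start, start + len(element)))
                start = doubled.find(rev, start + 1)

    sites: list[ISInsertion] = []
    for fam, hits in junction_hits.items():
        for cluster in _cluster_positions(hits, params.cluster_window):
            lefts = [p for p, s in cluster if s == "left"]
            rights = [p for p, s in cluster if s == "right"]
            if len(cluster) < params.min_junction_support:
                continue
            lo = int(min(p for p, _ in cluster))
            hi = int(max(p for p, _ in cluster))
            status = "new"
            for es, ee in ancestral_edges:
                if min(abs(lo - es), abs(hi - ee), abs(lo - ee), abs(hi - es)) \
                        <= params.cluster_window + 10:
                    status = "ancestral"
                    break
            sites.append(ISInsertion(fam, (lo, hi), "+",
                                     len(lefts), len(rights), status))
    return sorted(sites, key=lambda s: s.site)


def _place_flank(flank: str, index: ReferenceIndex, scoring: Scoring,
                 side: str) -> int | None:
    """Unique reference coordinate of the element-adjacent end of a flank."""
    placements = _map_single(index, flank, scoring, allow_clip=False)
    if len(placements) != 1:
        return None
    p = placements[0]
    qlen = cigar_query_len(p.cigar)
    if side == "left":
        # junction sits just after the flank in element orientation
        return (p.start + qlen) % index.L if p.strand == "+" else p.start
    return p.start if p.strand == "+" else (p.start + qlen) % index.L


def _cluster_positions(hits: list[tuple[int, str]], window: int
                       ) -> list[list[tuple[int, str]]]:
    hits = sorted(hits)
    clusters: list[list[tuple[int, str]]] = []
    for h in hits:
        if clusters and h[0] - clusters[-1][-1][0] <= window:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    return clusters


def is_presence_matrix(sites_by_strain: dict[str, list[ISInsertion]],
                       pileups_by_strain: dict[str, Pileup],
                       d_min: int = 10, tol: int = 60):
    """Merge per-strain IS sites into a site x strain presence table.

    present: junction detected; absent: no junction and adequate local
    coverage; insufficient: no junction but the strain lacks coverage to
    say."""
    import pandas as pd

    merged: list[tuple[str, int, int, str]] = []
    for strain, sites in sites_by_strain.items():
        for s in sites:
            placed = False
            for i, (fam, lo, hi, status) in enumerate(merged):
                if fam == s.family and not (s.site[1] + tol < lo or s.site[0] - tol > hi):
                    merged[i] = (fam, min(lo, s.site[0]), max(hi, s.site[1]),
                                 "ancestral" if "ancestral" in (status, s.status) else "new")
                    placed = True
                    break
            if not placed:
                merged.append((s.family, s.site[0], s.site[1], s.status))

    rows = []
    for fam, lo, hi, status in sorted(merged, key=lambda m: m[1]):
        row = {"family": fam, "start": lo, "end": hi, "status": status}
        for strain, sites in sites_by_strain.items():
            present = any(s.family == fam and not (s.site[1] + tol < lo or
                                                   s.site[0] - tol > hi)
                          for s in sites)
            if present:
                row[strain] = "present"
            else:
                pile = pileups_by_strain[strain]
                local = pile.depth[max(0, lo - tol):min(pile.L, hi + tol)]
                row[strain] = "absent" if local.size and local.mean() >= d_min \
                    else "insufficient"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evidence reconciliation
# ---------------------------------------------------------------------------

def reconcile(segments_by_strain: dict[str, list[CNSegment]],
              profiles_by_strain: dict[str, CoverageProfile],
              sv_by_strain: dict[str, list[SVCandidate]],
              is_matrix, strain_a: str, strain_b: str,
              params: SVParams | None = None,
              reference: GenomeModel | None = None
              ) -> tuple[list[ConfirmedDifference], list[dict]]:
    """Concordance rules between coverage, pair and split-read evidence for
    one strain pair.  A deletion needs a zero-copy segment plus an agreeing
    too_far cluster; an amplification needs only the segment (junction pairs
    optional); an IS insertion needs a strain-differential split-read site.
    Single-evidence or conflicting calls are emitted as unconfirmed audit
    entries with reasons."""
    params = params or SVParams()
    confirmed: list[ConfirmedDifference] = []
    audit: list[dict] = []
    consumed: set[int] = set()

    # strain-differential IS sites first: coverage shifts at repeat-family
    # copies are a side effect of a family gaining/losing a member and are
    # attributed to the insertion difference, not reported twice
    is_diffs: list[ConfirmedDifference] = []
    if is_matrix is not None and len(is_matrix):
        for _, row in is_matrix.iterrows():
            sa, sb = row[strain_a], row[strain_b]
            if {sa, sb} == {"present", "absent"}:
                carrier = strain_a if sa == "present" else strain_b
                is_diffs.append(ConfirmedDifference(
                    "is_insertion", int(row["start"]), int(row["end"]),
                    {carrier: "supports",
                     (strain_b if carrier == strain_a else strain_a): "refutes"},
                    detail={"family": row["family"], "status": row["status"]}))
            elif "insufficient" in (sa, sb) and sa != sb:
                audit.append({"interval": (int(row["start"]), int(row["end"])),
                              "kind": "is_insertion",
                              "reason": "coverage insufficient to call absence"})
    is_element_ivs: list[tuple[int, int, str]] = []
    if reference is not None:
        is_element_ivs = [(el.start, el.end, el.family)
                          for el in reference.is_elements]
    differential_families = {d.detail.get("family") for d in is_diffs}

    def _inside_is_element(s: int, e: int) -> str | None:
        for es, ee, fam in is_element_ivs:
            if _overlap(s, e, es, ee) >= 0.5 * (e - s):
                return fam
        return None

    intervals: list[tuple[int, int, str]] = []
    for strain in (strain_a, strain_b):
        for seg in segments_by_strain.get(strain, []):
            fam = _inside_is_element(seg.start, seg.end)
            if fam is not None:
                reason = ("coverage shift at a repeat-family copy, attributed "
                          f"to the {fam} insertion difference"
                          if fam in differential_families else
                          "repeat-family copy-ratio shift without locus evidence")
                audit.append({"interval": (seg.start, seg.end), "kind": "cnv",
                              "strain": strain, "reason": reason})
                continue
            intervals.append((seg.start, seg.end, strain))
    merged_ivs: list[tuple[int, int]] = []
    for s, e, _ in sorted(intervals):
        if merged_ivs and s <= merged_ivs[-1][1] + params.cnv_overlap_tol:
            merged_ivs[-1] = (merged_ivs[-1][0], max(merged_ivs[-1][1], e))
        else:
            merged_ivs.append((s, e))

    def state_of(strain: str, iv: tuple[int, int]) -> tuple[int, float]:
        for seg in segments_by_strain.get(strain, []):
            if _overlap(seg.start, seg.end, *iv) > 0.5 * (iv[1] - iv[0]):
                return seg.copy_estimate, seg.ratio
        prof = profiles_by_strain[strain]
        w = prof.window
        lo, hi = iv[0] // w, max(iv[0] // w + 1, iv[1] // w)
        ratio = float(np.mean(prof.ratios()[lo:hi]))
        return int(round(ratio)), ratio

    def overlapping_sv(strain: str, iv, types) -> SVCandidate | None:
        for j, cand in enumerate(sv_by_strain.get(strain, [])):
            if cand.type in types and id(cand) not in consumed and \
                    _overlap(cand.interval[0], cand.interval[1], *iv) > 0:
                consumed.add(id(cand))
                return cand
        return None

    for iv in merged_ivs:
        (ca, ra), (cb, rb) = state_of(strain_a, iv), state_of(strain_b, iv)
        if ca == cb:
            audit.append({"interval": iv, "kind": "cnv",
                          "reason": f"equal copy state {ca} in both strains"})
            continue
        zero_strain = strain_a if ca == 0 else strain_b if cb == 0 else None
        seg = next((s for strain in (strain_a, strain_b)
                    for s in segments_by_strain.get(strain, [])
                    if _overlap(s.start, s.end, *iv) > 0), None)
        if zero_strain is not None:
            cluster = overlapping_sv(zero_strain, iv, {"deletion"})
            length_kb = (seg.length if seg else iv[1] - iv[0]) / 1000.0
            if cluster is not None:
                detail = {"subtype": "deletion",
                          "deleted_length_kb": round(length_kb, 2),
                          "insert_excess_kb": round(
                              cluster.detail.get("insert_excess_estimate", 0.0) / 1000, 2),
                          "copy_states": {strain_a: ca, strain_b: cb},
                          "flanking_repeat": cluster.flanking_repeat,
                          "support_pairs": cluster.support}
                confirmed.append(ConfirmedDifference(
                    "sv", iv[0], iv[1],
                    {zero_strain: "supports",
                     (strain_b if zero_strain == strain_a else strain_a): "refutes"},
                    detail=detail))
            else:
                confirmed.append(ConfirmedDifference(
                    "cnv", iv[0], iv[1],
                    {strain_a: "supports" if ca == 0 else "refutes",
                     strain_b: "supports" if cb == 0 else "refutes"},
                    detail={"subtype": "deletion", "copy_states": {strain_a: ca, strain_b: cb},
                            "deleted_length_kb": round(length_kb, 2),
                            "note": "no junction-pair support"}))
            continue
        # amplification / other copy change
        amp_strain = strain_a if ca > cb else strain_b
        junction = overlapping_sv(amp_strain, iv, {"tandem_dup"})
        detail = {"subtype": "amplification",
                  "copy_states": {strain_a: ca, strain_b: cb},
                  "ratio": {strain_a: round(ra, 3), strain_b: round(rb, 3)},
                  "length_kb": round((seg.length if seg else iv[1] - iv[0]) / 1000, 2),
                  "junction_pairs": junction.support if junction else 0}
        confirmed.append(ConfirmedDifference(
            "cnv", iv[0], iv[1],
            {amp_strain: "supports",
             (strain_b if amp_strain == strain_a else strain_a): "refutes"},
            detail=detail))

    # SV candidates not explained by copy-number segments
    for strain, other in ((strain_a, strain_b), (strain_b, strain_a)):
        for cand in sv_by_strain.get(strain, []):
            if id(cand) in consumed:
                continue
            differential = not any(
                c.type == cand.type and _overlap(*c.interval, *cand.interval) > 0
                for c in sv_by_strain.get(other, []))
            if cand.type == "inversion" and differential:
                consumed.add(id(cand))
                confirmed.append(ConfirmedDifference(
                    "sv", cand.interval[0], cand.interval[1],
                    {strain: "supports", other: "refutes"},
                    detail={"subtype": "inversion", "support_pairs": cand.support,
                            "flanking_repeat": cand.flanking_repeat}))
            elif cand.type == "deletion":
                audit.append({"interval": cand.interval, "kind": "sv:deletion",
                              "strain": strain,
                              "reason": "no zero-copy coverage segment agrees"})
            elif cand.type in ("tandem_dup", "novel_insertion"):
                audit.append({"interval": cand.interval, "kind": f"sv:{cand.type}",
                              "strain": strain,
                              "reason": "single-evidence cluster (below copy threshold "
                                        "or no split-read corroboration)"})

    confirmed += is_diffs
    return confirmed, audit


def _overlap(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2))
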
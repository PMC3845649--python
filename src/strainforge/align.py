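"""Seed-and-extend read mapping against a (circular) reference.

Not a general-purpose aligner: it targets small bacterial genomes at modest
divergence (<~5%), which is all the strain-comparison pipeline needs.  The
contract is:

- exact k-mer seeds (both strands, circular-aware) vote for candidate
  diagonals;
- candidates are extended: an ungapped pass handles the common
  substitution-only case, and gapped extension (banded edit-distance via
  edlib, rescored with affine-gap penalties) handles indel-containing
  reads;
- soft-clipping at read ends is attempted when no full-length placement
  scores adequately — junction reads (IS-element edges, deletion
  breakpoints) must be allowed to align partially;
- all equally-best placements are retained so multi-mapping reads can be
  assigned to a random repeat copy downstream;
- mates are resolved jointly toward a plausible inward-facing insert, and a
  low-scoring mate is rescued by a targeted search near its anchor.

The circular chromosome is handled by extending the reference with a copy
of its first bases at index time and canonicalizing coordinates modulo the
genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
import numpy as np

from ._util import derive_seed, revcomp, seq_to_array
from .simulate.reads import ReadSet, SimRead


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1
    band: int = 16                  # padding for gapped extension windows
    min_score_frac: float = 0.4     # full-length acceptance threshold
    max_nm_frac: float = 0.07       # mismatch+gap-run cap for full placements
    max_nm_floor: int = 4           # (junction reads must clip, not limp)
    min_clip_anchor: int = 20       # smallest aligned part of a clipped read
    max_candidates: int = 60
    mapq_cap: int = 60


@dataclass(frozen=True)
class Placement:
    start: int          # 0-based canonical reference coordinate
    strand: str         # '+' or '-'
    cigar: str
    score: int
    nm: int


@dataclass
class AlignmentRecord:
    read_id: str
    mate: int | None
    ref_name: str
    mapped: bool
    start: int = -1
    strand: str = "+"
    cigar: str = "*"
    score: int = 0
    nm: int = -1
    mapq: int = 0
    multimap_count: int = 1
    placements: list[Placement] = field(default_factory=list)
    seq: str = ""
    qual: str = ""
    mate_start: int = -1
    mate_strand: str = "+"
    mate_mapped: bool = False
    insert: int = 0       # unsigned fragment length for inward pairs, else 0
    proper: bool = False
    pair_combos: list[tuple[Placement, Placement]] = field(default_factory=list)

    def set_primary(self, p: Placement) -> None:
        self.mapped = True
        self.start, self.strand, self.cigar = p.start, p.strand, p.cigar
        self.score, self.nm = p.score, p.nm

    def aligned_seq(self) -> str:
        """Read sequence in reference orientation (as the CIGAR consumes it)."""
        return self.seq if self.strand == "+" else revcomp(self.seq)

    def aligned_qual(self) -> str:
        return self.qual if self.strand == "+" else self.qual[::-1]

    def query_span(self) -> tuple[int, int]:
        """Aligned query interval [s,e) implied by the CIGAR (soft clips excluded)."""
        ops = parse_cigar(self.cigar)
        s = ops[0][1] if ops and ops[0][0] == "S" else 0
        consumed = sum(n for op, n in ops if op in "MIS")
        e = consumed - (ops[-1][1] if ops and ops[-1][0] == "S" else 0)
        return s, e

    def ref_end(self) -> int:
        return self.start + sum(n for op, n in parse_cigar(self.cigar) if op in "MD")


@dataclass
class PairStats:
    """Robust insert-size summary estimated from proper pairs (median and
    MAD-scaled SD); 'insert' is the outer fragment length of inward pairs."""
    insert_mean: float
    insert_sd: float
    orientation: str = "inward"
    n: int = 0
    degenerate: bool = False


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            ops.append((ch, num))
            num = 0
    return ops


def cigar_query_len(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in "MIS")


class ReferenceIndex:
    """Exact k-mer index over a (circular) reference sequence."""

    def __init__(self, name: str, seq: str, k: int = 17, circular: bool = True,
                 max_span: int = 2000):
        if not (4 <= k <= 31):
            raise ValueError("seed length k must be in [4, 31]")
        if len(seq) < k:
            raise ValueError("reference shorter than seed length")
        self.name = name
        self.seq = seq
        self.k = k
        self.circular = circular
        self.L = len(seq)
        ext_len = min(self.L, max_span) if circular else 0
        self.ext = seq + seq[:ext_len]
        self.ext_len = ext_len
        self.ext_arr = seq_to_array(self.ext)
        self._table: dict[str, list[int]] = {}
        limit = self.L if circular else self.L - k + 1
        table = self._table
        ext = self.ext
        for i in range(limit):
            kmer = ext[i:i + k]
            if kmer in table:
                table[kmer].append(i)
            else:
                table[kmer] = [i]

    def positions(self, kmer: str) -> list[int]:
        """Forward-strand start positions of a k-mer (canonical, < genome
        length); reverse-strand occurrences are found by querying the
        reverse complement."""
        return self._table.get(kmer, [])


def index_reference(name: str, seq: str, k: int = 17, circular: bool = True) -> ReferenceIndex:
    return ReferenceIndex(name, seq, k=k, circular=circular)


# ---------------------------------------------------------------------------
# Single-read placement
# ---------------------------------------------------------------------------

def _affine_rescore(ext_ops: list[tuple[str, int]], scoring: Scoring) -> tuple[int, str, int]:
    """Affine-gap score, merged M-cigar and mismatch count from an extended
    ('='/'X'/'I'/'D') edit path."""
    score = 0
    nm = 0
    merged: list[tuple[str, int]] = []
    for op, n in ext_ops:
        if op == "=":
            score += n * scoring.match
            op = "M"
        elif op == "X":
            score += n * scoring.mismatch
            nm += n
            op = "M"
        elif op in "ID":
            score += scoring.gap_open + (n - 1) * scoring.gap_extend
            nm += n
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    cigar = "".join(f"{n}{op}" for op, n in merged)
    return score, cigar, nm


def _edlib_ops(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            ops.append((ch, num))
            num = 0
    return ops


def _evaluate_candidate(index: ReferenceIndex, q_arr: np.ndarray, q: str,
                        start: int, scoring: Scoring) -> Placement | None:
    n = len(q)
    L = index.L
    start %= L
    if start + n > len(index.ext):
        return None  # hangs past a linear end / beyond the circular buffer
    ref_arr = index.ext_arr[start:start + n]
    nm = int(np.count_nonzero(ref_arr != q_arr))
    if nm <= 2:
        score = (n - nm) * scoring.match + nm * scoring.mismatch
        return Placement(start, "+", f"{n}M", score, nm)
    # gapped extension in a padded window
    pad = scoring.band
    ws = max(0, start - pad)
    we = min(len(index.ext), start + n + pad)
    window = index.ext[ws:we]
    res = edlib.align(q, window, mode="HW", task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        return None
    ops = _edlib_ops(res["cigar"])
    if sum(1 for op, _ in ops if op in "ID") > 1:
        # edlib minimizes unit-cost edits and may split one gap into
        # several; realign under the affine model so that every read
        # crossing the same indel reports the same gap placement
        realigned = _affine_realign(q, window, scoring)
        if realigned is not None:
            offset, score, cigar, nm = realigned
            return Placement((ws + offset) % L, "+", cigar, score, nm)
    score, cigar, nm = _affine_rescore(ops, scoring)
    return Placement((ws + res["locations"][0][0]) % L, "+", cigar,
                     score, res["editDistance"])


_PAIRWISE_ALIGNER = None


def _affine_realign(q: str, window: str, scoring: Scoring
                    ) -> tuple[int, int, str, int] | None:
    """Affine-gap semi-global alignment (free window ends) of a read inside
    its candidate window; returns (window offset, score, cigar, edits)."""
    global _PAIRWISE_ALIGNER
    from Bio import Align

    if _PAIRWISE_ALIGNER is None or \
            _PAIRWISE_ALIGNER.match_score != scoring.match:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = scoring.match
        a.mismatch_score = scoring.mismatch
        a.open_gap_score = scoring.gap_open
        a.extend_gap_score = scoring.gap_extend
        # reference-window overhangs are free ('deletion' = target consumed
        # with no query letter, i.e. the window extends past the read)
        if hasattr(a, "open_end_deletion_score"):
            a.open_end_deletion_score = 0.0
            a.extend_end_deletion_score = 0.0
        else:
            a.target_end_open_gap_score = 0.0
            a.target_end_extend_gap_score = 0.0
        _PAIRWISE_ALIGNER = a
    try:
        aln = _PAIRWISE_ALIGNER.align(window, q)[0]
    except (ValueError, OverflowError, MemoryError):
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    offset = int(t_blocks[0][0])
    ops: list[tuple[str, int]] = []
    nm = 0
    score = 0
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            dt, dq = ts - prev_t, qs - prev_q
            if dq > 0:
                ops.append(("I", int(dq)))
                nm += int(dq)
                score += scoring.gap_open + (int(dq) - 1) * scoring.gap_extend
            if dt > 0:
                ops.append(("D", int(dt)))
                nm += int(dt)
                score += scoring.gap_open + (int(dt) - 1) * scoring.gap_extend
        mm = sum(x != y for x, y in zip(window[ts:te], q[qs:qe]))
        nm += mm
        score += (te - ts - mm) * scoring.match + mm * scoring.mismatch
        if ops and ops[-1][0] == "M":
            ops[-1] = ("M", ops[-1][1] + int(te - ts))
        else:
            ops.append(("M", int(te - ts)))
        prev_t, prev_q = te, qe
    # unaligned query overhangs would mean the read hangs off the window
    if q_blocks[0][0] != 0 or q_blocks[-1][1] != len(q):
        return None
    cigar = "".join(f"{n}{op}" for op, n in ops)
    return offset, score, cigar, nm


def _clip_placements(index: ReferenceIndex, q_arr: np.ndarray, q: str,
                     start: int, scoring: Scoring) -> list[Placement]:
    """Prefix- or suffix-anchored soft-clipped placements at one locus."""
    n = len(q)
    L = index.L
    start %= L
    if start + n > len(index.ext):
        return []
    ref_arr = index.ext_arr[start:start + n]
    neq = ref_arr != q_arr
    out: list[Placement] = []
    # longest prefix with <= 2 mismatches
    cum = np.cumsum(neq)
    ok = np.nonzero(cum <= 2)[0]
    plen = int(ok[-1]) + 1 if len(ok) else 0
    if scoring.min_clip_anchor <= plen < n - 4:
        mm = int(cum[plen - 1])
        score = (plen - mm) * scoring.match + mm * scoring.mismatch
        out.append(Placement(start, "+", f"{plen}M{n - plen}S", score, mm))
    # longest suffix with <= 2 mismatches
    cum_r = np.cumsum(neq[::-1])
    ok = np.nonzero(cum_r <= 2)[0]
    slen = int(ok[-1]) + 1 if len(ok) else 0
    if scoring.min_clip_anchor <= slen < n - 4:
        mm = int(cum_r[slen - 1])
        score = (slen - mm) * scoring.match + mm * scoring.mismatch
        out.append(Placement((start + n - slen) % L, "+", f"{n - slen}S{slen}M", score, mm))
    return out


def _badness(p: Placement) -> int:
    """Mismatches plus twice the number of gap runs: one long indel is a
    plausible variant, a mismatch-riddled tail is a junction read that
    should clip instead."""
    ops = parse_cigar(p.cigar)
    gap_runs = sum(1 for op, _ in ops if op in "ID")
    gap_len = sum(n for op, n in ops if op in "ID")
    mismatches = max(0, p.nm - gap_len)
    return mismatches + 2 * gap_runs


def _map_single(index: ReferenceIndex, seq: str, scoring: Scoring,
                allow_clip: bool = True) -> list[Placement]:
    """All equally-best placements of one read (both strands)."""
    k = index.k
    n = len(seq)
    if n < k:
        return []
    best: list[Placement] = []
    candidates: dict[tuple[str, int], int] = {}
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        offsets = [0, (n - k) // 2, n - k]
        hits = 0
        for off in offsets:
            for p in index.positions(q[off:off + k]):
                cand = (p - off) % index.L
                candidates[(strand, cand)] = candidates.get((strand, cand), 0) + 1
                hits += 1
        if hits == 0:  # denser sampling for error-rich reads
            for off in range(k, n - k, k):
                for p in index.positions(q[off:off + k]):
                    cand = (p - off) % index.L
                    candidates[(strand, cand)] = candidates.get((strand, cand), 0) + 1
    if not candidates:
        return []
    ordered = sorted(candidates.items(), key=lambda kv: -kv[1])[:scoring.max_candidates]
    # merge near-duplicate diagonals (small indels shift the implied start)
    placements: dict[tuple[int, str, str], Placement] = {}
    q_cache: dict[str, tuple[str, np.ndarray]] = {}
    for (strand, cand), _votes in ordered:
        if strand not in q_cache:
            qs = seq if strand == "+" else revcomp(seq)
            q_cache[strand] = (qs, seq_to_array(qs))
        qs, q_arr = q_cache[strand]
        pl = _evaluate_candidate(index, q_arr, qs, cand, scoring)
        if pl is not None:
            key = (pl.start, strand, pl.cigar)
            pl = Placement(pl.start, strand, pl.cigar, pl.score, pl.nm)
            if key not in placements or placements[key].score < pl.score:
                placements[key] = pl
    min_score = int(scoring.min_score_frac * n)
    max_bad = max(scoring.max_nm_floor, int(scoring.max_nm_frac * n))
    full = [p for p in placements.values()
            if p.score >= min_score and _badness(p) <= max_bad]
    if full:
        top = max(p.score for p in full)
        best = [p for p in full if p.score == top]
    elif allow_clip:
        clips: dict[tuple[int, str, str], Placement] = {}
        for (strand, cand), _votes in ordered[:10]:
            qs, q_arr = q_cache[strand]
            for pl in _clip_placements(index, q_arr, qs, cand, scoring):
                key = (pl.start, strand, pl.cigar)
                clips[key] = Placement(pl.start, strand, pl.cigar, pl.score, pl.nm)
        if clips:
            top = max(p.score for p in clips.values())
            best = [p for p in clips.values() if p.score == top]
    return sorted(best, key=lambda p: (p.start, p.strand))


# ---------------------------------------------------------------------------
# Pair resolution
# ---------------------------------------------------------------------------

def _circular_insert(index: ReferenceIndex, p_fwd: Placement, p_rev: Placement,
                     len_fwd: int, len_rev: int) -> int | None:
    """Outer fragment length for an inward pair (fwd mate, rev mate), or
    None when the geometry is not inward on the circle."""
    L = index.L
    rev_end = p_rev.start + len_rev
    d = (rev_end - p_fwd.start) % L
    if 0 < d <= L // 2 or not index.circular and 0 < d:
        return d
    return None


def map_read_pairs(readset: ReadSet, index: ReferenceIndex,
                   scoring: Scoring | None = None,
                   expected_insert: tuple[float, float] | None = None
                   ) -> list[AlignmentRecord]:
    """Map a read set; returns one record per input read, in input order.

    ``expected_insert`` (mean, sd) guides pair resolution and mate rescue;
    when omitted it is taken from the simulation config if present.
    """
    scoring = scoring or Scoring()
    if expected_insert is None and readset.config is not None and readset.paired:
        expected_insert = (readset.config.insert_mean, readset.config.insert_sd)

    records: list[AlignmentRecord] = []
    if readset.paired:
        for m1, m2 in readset.pairs():
            r1, r2 = _map_pair(m1, m2, index, scoring, expected_insert)
            records += [r1, r2]
    else:
        for read in readset.reads:
            records.append(_record_from_placements(
                read, _map_single(index, read.seq, scoring), index, scoring))
    return records


def _record_from_placements(read: SimRead, placements: list[Placement],
                            index: ReferenceIndex, scoring: Scoring) -> AlignmentRecord:
    rec = AlignmentRecord(read.read_id, read.mate, index.name,
                          mapped=bool(placements), seq=read.seq, qual=read.qual)
    if placements:
        rec.placements = placements
        rec.multimap_count = len(placements)
        rec.set_primary(placements[0])
        rec.mapq = scoring.mapq_cap if len(placements) == 1 else 0
    return rec


def _map_pair(m1: SimRead, m2: SimRead, index: ReferenceIndex, scoring: Scoring,
              expected_insert: tuple[float, float] | None
              ) -> tuple[AlignmentRecord, AlignmentRecord]:
    p1 = _map_single(index, m1.seq, scoring)
    p2 = _map_single(index, m2.seq, scoring)

    # mate rescue: one side confidently placed, other side missing
    if expected_insert is not None:
        mu, sd = expected_insert
        if p1 and not p2:
            p2 = _rescue(index, m2.seq, p1[0], mu, sd, scoring)
        elif p2 and not p1:
            p1 = _rescue(index, m1.seq, p2[0], mu, sd, scoring)

    r1 = _record_from_placements(m1, p1, index, scoring)
    r2 = _record_from_placements(m2, p2, index, scoring)

    # joint resolution: prefer inward combos with plausible insert
    if p1 and p2:
        cap = (expected_insert[0] + 10 * max(expected_insert[1], 1)
               if expected_insert else index.L // 2)
        combos: list[tuple[Placement, Placement, int]] = []
        for a in p1:
            for b in p2:
                if a.strand == b.strand:
                    continue
                fwd, rev = (a, b) if a.strand == "+" else (b, a)
                lf = cigar_query_len(fwd.cigar)
                lr = cigar_query_len(rev.cigar)
                ins = _circular_insert(index, fwd, rev, lf, lr)
                if ins is not None and ins <= cap:
                    combos.append((a, b, ins))
        if combos:
            mu = expected_insert[0] if expected_insert else 0.0
            best_sum = max(a.score + b.score for a, b, _ in combos)
            combos = [(a, b, i) for a, b, i in combos if a.score + b.score == best_sum]
            combos.sort(key=lambda c: (abs(c[2] - mu), c[0].start))
            a, b, ins = combos[0]
            r1.set_primary(a)
            r2.set_primary(b)
            r1.proper = r2.proper = True
            r1.insert = r2.insert = ins
            r1.pair_combos = r2.pair_combos = [(x, y) for x, y, _ in combos]
            r1.multimap_count = r2.multimap_count = len(combos)
            if len(combos) == 1:
                r1.mapq = r2.mapq = scoring.mapq_cap
    for rec, other in ((r1, r2), (r2, r1)):
        rec.mate_mapped = other.mapped
        rec.mate_start = other.start
        rec.mate_strand = other.strand
    return r1, r2


def _rescue(index: ReferenceIndex, seq: str, anchor: Placement,
            mu: float, sd: float, scoring: Scoring) -> list[Placement]:
    """Targeted gapped search for a mate near its anchored partner."""
    n = len(seq)
    L = index.L
    span = int(mu + 4 * sd) + n
    if anchor.strand == "+":
        ws = anchor.start
    else:
        ws = anchor.start + cigar_query_len(anchor.cigar) - span
    ws %= L
    window = (index.seq + index.seq)[ws:ws + span] if index.circular \
        else index.seq[max(0, ws):ws + span]
    best: list[Placement] = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        res = edlib.align(q, window, mode="HW", task="path")
        if res["editDistance"] < 0 or res["editDistance"] > max(3, int(0.1 * n)):
            continue
        score, cigar, _ = _affine_rescore(_edlib_ops(res["cigar"]), scoring)
        start = (ws + res["locations"][0][0]) % L
        best.append(Placement(start, strand, cigar, score, res["editDistance"]))
    if not best:
        return []
    top = max(p.score for p in best)
    return [p for p in best if p.score == top and p.score >= scoring.min_score_frac * n]


# ---------------------------------------------------------------------------
# Multi-mapper assignment and insert statistics
# ---------------------------------------------------------------------------

def assign_multimappers(records: list[AlignmentRecord], seed: int) -> list[AlignmentRecord]:
    """Give every multi-mapping read exactly one primary placement, chosen
    uniformly among the equally-best ones; reproducible for a fixed seed.

    Mates are assigned jointly when compatible pair placements exist, so a
    pair never straddles two different repeat copies by bookkeeping
    accident.
    """
    rng = np.random.default_rng(derive_seed(seed, "assign_multimappers"))
    i = 0
    while i < len(records):
        rec = records[i]
        mate = records[i + 1] if (rec.mate == 1 and i + 1 < len(records)
                                  and records[i + 1].mate == 2
                                  and records[i + 1].read_id == rec.read_id) else None
        if mate is not None and rec.pair_combos:
            if len(rec.pair_combos) > 1:
                a, b = rec.pair_combos[int(rng.integers(len(rec.pair_combos)))]
                rec.set_primary(a)
                mate.set_primary(b)
                rec.mate_start, mate.mate_start = mate.start, rec.start
                rec.mate_strand, mate.mate_strand = mate.strand, rec.strand
            i += 2
            continue
        for r in ((rec,) if mate is None else (rec, mate)):
            if r.mapped and len(r.placements) > 1:
                r.set_primary(r.placements[int(rng.integers(len(r.placements)))])
        if mate is not None:
            rec.mate_start, mate.mate_start = mate.start, rec.start
            rec.mate_strand, mate.mate_strand = mate.strand, rec.strand
            i += 2
        else:
            i += 1
    return records


def estimate_insert_stats(records: list[AlignmentRecord]) -> PairStats:
    """Robust insert mean/SD (median, MAD-scaled) over proper pairs.

    Robustness matters: pairs spanning an undetected deletion carry grossly
    inflated inserts and must not drag the mean."""
    inserts = np.array([r.insert for r in records
                        if r.mate == 1 and r.proper and r.insert > 0], dtype=float)
    if len(inserts) == 0:
        raise ValueError("no proper pairs; cannot estimate insert distribution")
    if len(inserts) < 100:
        warnings.warn(f"only {len(inserts)} proper pairs; insert stats unstable")
    med = float(np.median(inserts))
    mad = float(np.median(np.abs(inserts - med)))
    sd = 1.4826 * mad
    return PairStats(insert_mean=med, insert_sd=sd, n=len(inserts),
                     degenerate=(sd == 0.0))


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------

def write_sam(records: list[AlignmentRecord], index: ReferenceIndex, path) -> None:
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": index.name, "LN": index.L}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment()
            a.query_name = rec.read_id
            a.query_sequence = rec.aligned_seq() if rec.mapped else rec.seq
            qual = rec.aligned_qual() if rec.mapped else rec.qual
            a.query_qualities = pysam.qualitystring_to_array(qual) if qual else None
            flag = 0
            if rec.mate:
                flag |= 0x1 | (0x40 if rec.mate == 1 else 0x80)
                if rec.proper:
                    flag |= 0x2
                if not rec.mate_mapped:
                    flag |= 0x8
                if rec.mate_mapped and rec.mate_strand == "-":
                    flag |= 0x20
            if not rec.mapped:
                flag |= 0x4
            if rec.mapped and rec.strand == "-":
                flag |= 0x10
            a.flag = flag
            if rec.mapped:
                a.reference_id = 0
                a.reference_start = rec.start
                a.mapping_quality = rec.mapq
                a.cigarstring = rec.cigar
                a.set_tag("NM", max(rec.nm, 0))
                a.set_tag("AS", rec.score)
                a.set_tag("NH", rec.multimap_count)
            if rec.mate and rec.mate_mapped:
                a.next_reference_id = 0
                a.next_reference_start = rec.mate_start
                a.template_length = rec.insert if rec.strand == "+" else -rec.insert
            out.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as f:
        ref_name = f.references[0] if f.references else "ref"
        for a in f:
            seq = a.query_sequence or ""
            qual = (pysam.qualities_to_qualitystring(a.query_qualities)
                    if a.query_qualities is not None else "")
            if a.is_reverse:  # SAM stores reference orientation; undo it
                seq, qual = revcomp(seq), qual[::-1]
            rec = AlignmentRecord(
                read_id=a.query_name,
                mate=(1 if a.is_read1 else 2) if a.is_paired else None,
                ref_name=ref_name, mapped=not a.is_unmapped,
                seq=seq, qual=qual)
            if rec.mapped:
                rec.start = a.reference_start
                rec.strand = "-" if a.is_reverse else "+"
                rec.cigar = a.cigarstring or "*"
                rec.mapq = a.mapping_quality
                rec.nm = a.get_tag("NM") if a.has_tag("NM") else -1
                rec.score = a.get_tag("AS") if a.has_tag("AS") else 0
                rec.multimap_count = a.get_tag("NH") if a.has_tag("NH") else 1
                rec.placements = [Placement(rec.start, rec.strand, rec.cigar,
                                            rec.score, rec.nm)]
            rec.proper = a.is_paired and a.is_proper_pair
            if a.is_paired and not a.mate_is_unmapped:
                rec.mate_mapped = True
                rec.mate_start = a.next_reference_start
                rec.mate_strand = "-" if a.mate_is_reverse else "+"
                rec.insert = abs(a.template_length)
            records.append(rec)
    return records
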
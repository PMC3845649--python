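"""Pileup-based small-variant calling and reciprocal cross-strain checking.

The calling model is deliberately simple and auditable: haploid majority
calls from pileup columns, filtered on a quality proxy (mean Phred of the
column) and on read-depth bounds.  Depth bounds matter on repeat-rich
genomes — columns far above the genome-wide depth are collapsed repeats and
must not yield variant calls.  A candidate found in one strain is then
re-evaluated in every other strain from that strain's own pileup
(supports / refutes / insufficient), so that a difference is only reported
when one strain demonstrably carries each allele — this suppresses the
false differences that depth or quality asymmetries between libraries
would otherwise create.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import edlib
import numpy as np
import pandas as pd

from ._util import seq_to_array
from .align import AlignmentRecord, parse_cigar


@dataclass
class CallFilters:
    q_min: float = 10.0
    d_min: int = 10
    d_max: int = 220
    c_min: int = 10     # consensus depth bounds
    c_max: int = 100
    # haploid majority: with per-base error below 1% a true allele sits near
    # fraction 1.0; 0.7 leaves headroom for junction-read dilution at indels
    # while still demanding a decisive majority
    f_maj: float = 0.7

    def __post_init__(self):
        if not (self.d_min < self.d_max and self.c_min < self.c_max):
            raise ValueError("depth bounds must satisfy min < max")
        if not (0.5 < self.f_maj <= 1.0):
            raise ValueError("majority fraction must lie in (0.5, 1]")

    @classmethod
    def preset_published(cls) -> "CallFilters":
        """Absolute bounds used for deep real libraries: quality >= 10,
        call depth in [10, 220], consensus depth in [10, 100]."""
        return cls(q_min=10, d_min=10, d_max=220, c_min=10, c_max=100)

    @classmethod
    def scaled(cls, mean_depth: float, q_min: float = 10.0,
               f_maj: float = 0.7) -> "CallFilters":
        """Depth bounds scaled to the library: d_min = max(10, 0.1*mean),
        d_max = 2*mean; absolute published bounds reflect a specific
        coverage and do not transfer across simulated depths."""
        d_min = max(10, int(round(0.1 * mean_depth)))
        d_max = max(d_min + 1, int(round(2 * mean_depth)))
        return cls(q_min=q_min, d_min=d_min, d_max=d_max,
                   c_min=d_min, c_max=d_max, f_maj=f_maj)


@dataclass
class VariantCall:
    strain: str
    position: int          # 1-based (VCF convention)
    ref: str
    alt: str
    quality: float
    depth: int
    allele_fraction: float
    kind: str = "snp"      # "snp" | "small_indel"


@dataclass
class ConfirmedDifference:
    cls: str                      # snp | small_indel | cnv | is_insertion | sv
    start: int                    # 0-based reference coordinate
    end: int
    statuses: dict[str, str]      # strain -> supports | refutes | insufficient
    detail: dict = field(default_factory=dict)

    @property
    def supporting(self) -> set[str]:
        return {s for s, v in self.statuses.items() if v == "supports"}

    @property
    def refuting(self) -> set[str]:
        return {s for s, v in self.statuses.items() if v == "refutes"}


class Pileup:
    """Per-position tallies against one reference sequence.

    ``depth`` counts aligned (M) bases; substitution evidence lives in a
    sparse ``alt_counts`` map and indel observations are anchored to the
    preceding reference base, as in VCF.
    """

    def __init__(self, ref_name: str, ref_seq: str, circular: bool = True):
        self.ref_name = ref_name
        self.ref_seq = ref_seq
        self.circular = circular
        L = len(ref_seq)
        self.L = L
        self.depth = np.zeros(L, dtype=np.int32)
        self.qsum = np.zeros(L, dtype=np.float64)
        self.alt_counts: dict[int, Counter] = {}
        self.indels: dict[int, Counter] = {}
        # reads anchored well past a position (margin bp each side); the
        # honest denominator for indel evidence, since a read ending inside
        # an indel can neither show nor refute it
        self.span = np.zeros(L, dtype=np.int32)
        self.span_margin = 20
        self._ref_ext = seq_to_array(ref_seq + ref_seq[:4096]) if circular \
            else seq_to_array(ref_seq)

    # -- construction -------------------------------------------------------

    def _add_range(self, arr: np.ndarray, s: int, e: int, val) -> None:
        L = self.L
        n = min(e - s, L)
        if n <= 0:
            return
        s %= L
        e = s + n
        if e <= L:
            arr[s:e] += val
        else:
            arr[s:] += val if np.isscalar(val) else val[:L - s]
            arr[:e - L] += val if np.isscalar(val) else val[L - s:]

    def add_record(self, rec: AlignmentRecord) -> None:
        if not rec.mapped:
            return
        if rec.ref_name != self.ref_name:
            raise ValueError(f"alignment is against {rec.ref_name!r}, pileup "
                             f"against {self.ref_name!r}")
        pos = rec.start
        qi = 0
        seq = rec.aligned_seq()
        qual = rec.aligned_qual()
        quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.float64) - 33 \
            if qual else None
        q_arr = seq_to_array(seq)
        ref_len = sum(n for op, n in parse_cigar(rec.cigar) if op in "MD")
        if ref_len > 2 * self.span_margin:
            self._add_range(self.span, pos + self.span_margin,
                            pos + ref_len - self.span_margin, 1)
        for op, n in parse_cigar(rec.cigar):
            if op == "M":
                self._add_range(self.depth, pos, pos + n, 1)
                if quals is not None:
                    self._add_range(self.qsum, pos, pos + n, quals[qi:qi + n])
                if rec.nm != 0 and pos % self.L + n <= len(self._ref_ext):
                    seg = self._ref_ext[pos % self.L: pos % self.L + n]
                    diffs = np.nonzero(seg != q_arr[qi:qi + n])[0]
                    for off in diffs:
                        p = (pos + int(off)) % self.L
                        self.alt_counts.setdefault(p, Counter())[chr(q_arr[qi + off])] += 1
                pos += n
                qi += n
            elif op == "I":
                anchor, payload = self._left_align(pos % self.L, "I", seq[qi:qi + n])
                self.indels.setdefault(anchor, Counter())[("I", payload)] += 1
                qi += n
            elif op == "D":
                anchor, payload = self._left_align(pos % self.L, "D", n)
                self.indels.setdefault(anchor, Counter())[("D", payload)] += 1
                pos += n
            elif op == "S":
                qi += n

    def _left_align(self, pos: int, op: str, payload) -> tuple[int, object]:
        """Shift an indel to its leftmost equivalent position (VCF
        normalization) so identical events from different reads share one
        anchor; returns (anchor position of the preceding base, payload)."""
        ref = self.ref_seq
        if op == "D":
            k = payload
            while pos > 0 and pos + k <= self.L and ref[pos - 1] == ref[pos + k - 1]:
                pos -= 1
            return (pos - 1) % self.L, k
        s = payload
        while pos > 0 and s and ref[pos - 1] == s[-1]:
            s = ref[pos - 1] + s[:-1]
            pos -= 1
        return (pos - 1) % self.L, s

    # -- access --------------------------------------------------------------

    def column(self, pos: int) -> "PileupColumn":
        pos %= self.L
        d = int(self.depth[pos])
        alts = self.alt_counts.get(pos, Counter())
        ref_base = self.ref_seq[pos]
        counts = {b: 0 for b in "ACGT"}
        for b, c in alts.items():
            if b in counts:
                counts[b] += c
        counts[ref_base] = max(0, d - sum(counts.values()))
        meanq = float(self.qsum[pos] / d) if d else 0.0
        return PileupColumn(pos, ref_base, d, counts,
                            dict(self.indels.get(pos, {})), meanq)

    def mean_depth(self) -> float:
        return float(self.depth.mean())


@dataclass
class PileupColumn:
    position: int          # 0-based
    ref_base: str
    depth: int
    counts: dict[str, int]
    indel_obs: dict
    mean_quality: float


def pileup(records: list[AlignmentRecord], ref_name: str, ref_seq: str,
           circular: bool = True) -> Pileup:
    """Build a pileup from primary alignments (multi-mappers must already be
    assigned)."""
    p = Pileup(ref_name, ref_seq, circular=circular)
    for rec in records:
        p.add_record(rec)
    return p


def call_variants(pile: Pileup, filters: CallFilters,
                  strain: str = "strain") -> list[VariantCall]:
    """Haploid majority calls: a site is called iff the alternate fraction
    reaches f_maj, the column quality proxy reaches q_min and the depth lies
    inside [d_min, d_max] (the upper bound suppresses collapsed repeats)."""
    calls: list[VariantCall] = []
    ref = pile.ref_seq
    for pos in sorted(pile.alt_counts):
        col = pile.column(pos)
        d = col.depth
        if not (filters.d_min <= d <= filters.d_max):
            continue
        alt, count = max(((b, c) for b, c in col.counts.items() if b != col.ref_base),
                         key=lambda bc: bc[1])
        frac = count / d if d else 0.0
        if frac >= filters.f_maj and col.mean_quality >= filters.q_min:
            calls.append(VariantCall(strain, pos + 1, col.ref_base, alt,
                                     round(col.mean_quality, 2), d, round(frac, 4), "snp"))
    for anchor in sorted(pile.indels):
        d = int(pile.depth[anchor])
        if not (filters.d_min <= d <= filters.d_max) or d == 0:
            continue
        (op, payload), count = max(pile.indels[anchor].items(), key=lambda kv: kv[1])
        denom = int(pile.span[anchor]) or d
        frac = min(1.0, count / denom)
        meanq = float(pile.qsum[anchor] / d)
        if frac >= filters.f_maj and meanq >= filters.q_min:
            if op == "D":
                refstr = ref[anchor:anchor + 1 + payload]
                altstr = ref[anchor]
            else:
                refstr = ref[anchor]
                altstr = ref[anchor] + payload
            calls.append(VariantCall(strain, anchor + 1, refstr, altstr,
                                     round(meanq, 2), d, round(frac, 4), "small_indel"))
    return calls


def consensus_genome(pile: Pileup, filters: CallFilters) -> str:
    """Reference-coordinate consensus over {A,C,G,T,N}: positions with depth
    inside [c_min, c_max] and a majority base at >= f_maj get that base,
    everything else N.  Output length equals the reference length."""
    L = pile.L
    ref_arr = seq_to_array(pile.ref_seq).copy()
    ok = (pile.depth >= filters.c_min) & (pile.depth <= filters.c_max)
    out = np.where(ok, ref_arr, ord("N")).astype(np.uint8)
    for pos, alts in pile.alt_counts.items():
        if not ok[pos]:
            continue
        col = pile.column(pos)
        base, count = max(col.counts.items(), key=lambda bc: bc[1])
        out[pos] = ord(base) if count / col.depth >= filters.f_maj else ord("N")
    return out.tobytes().decode()


# ---------------------------------------------------------------------------
# Assembly-vs-assembly comparison
# ---------------------------------------------------------------------------

@dataclass
class MismatchRecord:
    kind: str       # "sub" | "ins" | "del"  (with respect to sequence a)
    pos_a: int
    pos_b: int
    seq_a: str
    seq_b: str


def diff_assemblies(a: str, b: str, max_divergence: float = 0.25) -> list[MismatchRecord]:
    """Report every substitution and small indel between two sequences that
    share a coordinate frame; positions where either sequence is N are
    excluded.  Unequal-length inputs are pairwise-aligned first (global,
    unit costs); grossly divergent inputs raise ValueError."""
    records: list[MismatchRecord] = []
    if len(a) == len(b):
        arr_a, arr_b = seq_to_array(a), seq_to_array(b)
        for pos in np.nonzero(arr_a != arr_b)[0]:
            pos = int(pos)
            if a[pos] == "N" or b[pos] == "N":
                continue
            records.append(MismatchRecord("sub", pos, pos, a[pos], b[pos]))
        return records
    res = edlib.align(b, a, mode="NW", task="path")
    if res["editDistance"] < 0 or res["editDistance"] > max_divergence * max(len(a), len(b)):
        raise ValueError("sequences too divergent to share a coordinate frame")
    ia = ib = 0
    num = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
            continue
        n, num = num, 0
        if ch == "=":
            ia += n
            ib += n
        elif ch == "X":
            for j in range(n):
                if a[ia + j] != "N" and b[ib + j] != "N":
                    records.append(MismatchRecord("sub", ia + j, ib + j,
                                                  a[ia + j], b[ib + j]))
            ia += n
            ib += n
        elif ch == "D":   # consumes target (a) only: deletion in b
            records.append(MismatchRecord("del", ia, ib, a[ia:ia + n], ""))
            ia += n
        elif ch == "I":   # consumes query (b) only: insertion in b
            records.append(MismatchRecord("ins", ia, ib, "", b[ib:ib + n]))
            ib += n
    return _refine_record_clusters(records, a, b)


def _refine_record_clusters(records: list[MismatchRecord], a: str, b: str,
                            gap: int = 10) -> list[MismatchRecord]:
    """Re-derive tightly clustered records under an affine model.

    The unit-cost path may split one short indel into co-optimal fragments;
    records within ``gap`` bp of each other are realigned locally (gap-open
    penalty dominant) so that each underlying edit yields one record."""
    from .align import Scoring, _affine_realign

    if not records:
        return records
    out: list[MismatchRecord] = []
    cluster: list[MismatchRecord] = [records[0]]
    scoring = Scoring()

    def flush():
        if len(cluster) == 1:
            out.extend(cluster)
            return
        lo_a = max(0, cluster[0].pos_a - 15)
        hi_a = min(len(a), max(r.pos_a + len(r.seq_a) for r in cluster) + 15)
        lo_b = max(0, cluster[0].pos_b - 15)
        hi_b = min(len(b), max(r.pos_b + len(r.seq_b) for r in cluster) + 15)
        res = _affine_realign(b[lo_b:hi_b], a[lo_a - 5 if lo_a >= 5 else 0:hi_a + 5],
                              scoring)
        if res is None:
            out.extend(cluster)
            return
        offset, _score, cigar, _nm = res
        base_a = (lo_a - 5 if lo_a >= 5 else 0) + offset
        ia, ib = base_a, lo_b
        from .align import parse_cigar

        # only re-emit inside the cluster's own span: the padded window may
        # graze a neighboring record that is emitted on its own
        clamp_lo = cluster[0].pos_a - 2
        clamp_hi = max(r.pos_a + len(r.seq_a) for r in cluster) + 2
        for op, n in parse_cigar(cigar):
            if op == "M":
                for j in range(n):
                    if clamp_lo <= ia + j < clamp_hi and a[ia + j] != b[ib + j] \
                            and a[ia + j] != "N" and b[ib + j] != "N":
                        out.append(MismatchRecord("sub", ia + j, ib + j,
                                                  a[ia + j], b[ib + j]))
                ia += n
                ib += n
            elif op == "D":   # consumes a only
                if clamp_lo <= ia < clamp_hi:
                    out.append(MismatchRecord("del", ia, ib, a[ia:ia + n], ""))
                ia += n
            elif op == "I":   # consumes b only
                if clamp_lo <= ia < clamp_hi:
                    out.append(MismatchRecord("ins", ia, ib, "", b[ib:ib + n]))
                ib += n

    for rec in records[1:]:
        if rec.pos_a - (cluster[-1].pos_a + len(cluster[-1].seq_a)) <= gap:
            cluster.append(rec)
        else:
            flush()
            cluster = [rec]
    flush()
    return out


# ---------------------------------------------------------------------------
# Reciprocal cross-strain confirmation
# ---------------------------------------------------------------------------

def _site_status(pile: Pileup, call: VariantCall, filters: CallFilters) -> str:
    pos = call.position - 1
    d = int(pile.depth[pos])
    if d < filters.d_min:
        return "insufficient"
    if call.kind == "snp":
        col = pile.column(pos)
        frac = col.counts.get(call.alt, 0) / d
    else:
        if len(call.ref) > len(call.alt):
            key = ("D", len(call.ref) - len(call.alt))
        else:
            key = ("I", call.alt[len(call.ref):])
        denom = int(pile.span[pos]) or d
        frac = min(1.0, pile.indels.get(pos, Counter()).get(key, 0) / denom)
    if frac >= filters.f_maj:
        return "supports"
    if frac <= 1 - filters.f_maj:
        return "refutes"
    return "insufficient"  # mixed evidence: treated as unusable, not refuting


def cross_check(calls_by_strain: dict[str, list[VariantCall]],
                pileups_by_strain: dict[str, Pileup],
                filters: CallFilters
                ) -> tuple[list[ConfirmedDifference], list[dict]]:
    """Re-evaluate every candidate in every strain from that strain's own
    pileup.  A difference is confirmed iff at least one strain supports it,
    at least one refutes it, and no compared strain is depth-insufficient at
    the site; everything else lands in the audit list with a reason."""
    candidates: dict[tuple, VariantCall] = {}
    for calls in calls_by_strain.values():
        for c in calls:
            candidates.setdefault((c.position, c.ref, c.alt, c.kind), c)

    confirmed: list[ConfirmedDifference] = []
    audit: list[dict] = []
    for key in sorted(candidates):
        call = candidates[key]
        statuses = {s: _site_status(p, call, filters)
                    for s, p in pileups_by_strain.items()}
        has_support = any(v == "supports" for v in statuses.values())
        has_refute = any(v == "refutes" for v in statuses.values())
        insufficient = [s for s, v in statuses.items() if v == "insufficient"]
        span = len(call.ref) if call.kind == "small_indel" else 1
        if has_support and has_refute and not insufficient:
            confirmed.append(ConfirmedDifference(
                call.kind, call.position - 1, call.position - 1 + span, statuses,
                detail={"ref": call.ref, "alt": call.alt}))
        else:
            reason = ("insufficient coverage in " + ",".join(insufficient)
                      if insufficient else
                      "no refuting strain" if not has_refute else "no supporting strain")
            audit.append({"position": call.position, "ref": call.ref,
                          "alt": call.alt, "kind": call.kind, "reason": reason,
                          "statuses": statuses})
    return confirmed, audit


# ---------------------------------------------------------------------------
# Printed allele-table worked example
# ---------------------------------------------------------------------------

def load_allele_table(path=None) -> pd.DataFrame:
    """Load a printed per-strain allele table (TSV: coordinate column plus
    one column per strain; '-' marks an allele absent in that strain).
    With no path, the bundled table of the eight wMelPop-vs-wMelCS/DGRP
    variants is returned."""
    if path is None:
        ref = resources.files("strainforge").joinpath("data/table2_alleles.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", dtype={"coordinate": int})
    return pd.read_csv(path, sep="\t", dtype={"coordinate": int})


def allele_table_differences(table: pd.DataFrame, strain_a: str, strain_b: str
                             ) -> list[ConfirmedDifference]:
    """Confirmed differences between two strains of an allele table: rows
    where both strains have an observed state and the states differ.  An
    absent allele ('-') is an observed state (a deletion), not missing
    data."""
    for s in (strain_a, strain_b):
        if s not in table.columns:
            raise KeyError(f"strain {s!r} not in table")
    out: list[ConfirmedDifference] = []
    for _, row in table.iterrows():
        a, b = str(row[strain_a]).strip(), str(row[strain_b]).strip()
        if a in ("nan", "") or b in ("nan", ""):
            continue
        if a != b:
            indel = "-" in (a, b) or len(a) != len(b)
            cls = "small_indel" if indel else "snp"
            pos = int(row["coordinate"]) - 1
            out.append(ConfirmedDifference(
                cls, pos, pos + max(len(a), len(b)),
                {strain_a: "supports", strain_b: "refutes"},
                detail={strain_a: a, strain_b: b}))
    return out
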
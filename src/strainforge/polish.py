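"""Homopolymer-error polishing of pyrosequencing-derived draft assemblies.

Flow-based (454-style) sequencing systematically miscounts homopolymer run
lengths, and those errors survive into draft assemblies.  Given alignments
of both the original pyro reads and an accurate short-read library against
the same draft, a run-length correction is emitted at a homopolymer run iff
BOTH conditions hold:

1. the short reads are consistent with a different run length and
   inconsistent with the assembly (majority above a support threshold for
   a length other than the assembly's), and
2. the pyro reads covering the site disagree among themselves about the
   run length (at least two distinct lengths, each seen in at least two
   reads) — the signature of a platform artifact rather than a true
   variant.

A site where short reads support a change but the pyro reads agree
unanimously on the assembly length is left alone: that is a candidate true
variant between the sequenced DNA and the assembly, not a sequencing error.
The corrected length is the short-read majority length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from ._util import homopolymer_runs
from .align import AlignmentRecord, parse_cigar


@dataclass
class PolishParams:
    support_threshold: float = 0.8   # short-read majority fraction
    min_short_depth: int = 10        # spanning short reads required at a run
    min_pyro_depth: int = 4
    min_run_len: int = 3             # homopolymer definition
    pyro_distinct_lengths: int = 2   # "disagreement" definition:
    pyro_min_per_length: int = 2     # >= 2 lengths, each in >= 2 reads

    def __post_init__(self):
        if not (0.5 < self.support_threshold <= 1.0):
            raise ValueError("support threshold must lie in (0.5, 1]")


@dataclass
class HomopolymerCorrection:
    position: int            # assembly coordinate of the run start
    base: str
    run_len_assembly: int
    run_len_corrected: int
    short_support: float     # majority fraction among spanning short reads
    pyro_disagreement: bool
    short_depth: int = 0
    pyro_lengths: dict = None


def _run_observations(records: list[AlignmentRecord],
                      runs: list[tuple[int, int, str]]) -> list[Counter]:
    """Observed run length per read for each homopolymer run.

    A read contributes iff it aligns (M) to the flanking bases on both
    sides of the run; the observation is the longest run of the run base in
    the read segment between those anchors."""
    obs = [Counter() for _ in runs]
    run_starts = [r[0] for r in runs]
    import bisect

    for rec in records:
        if not rec.mapped:
            continue
        # ref->read coordinate pairs for M ops
        segments: list[tuple[int, int, int]] = []  # (ref_start, ref_end, read_start)
        rp, qp = rec.start, 0
        for op, n in parse_cigar(rec.cigar):
            if op == "M":
                segments.append((rp, rp + n, qp))
                rp += n
                qp += n
            elif op == "I":
                qp += n
            elif op == "D":
                rp += n
            elif op == "S":
                qp += n
        if not segments:
            continue
        span_lo, span_hi = segments[0][0], rp

        def read_pos(ref_pos: int) -> int | None:
            for rs, re_, qs in segments:
                if rs <= ref_pos < re_:
                    return qs + (ref_pos - rs)
            return None

        lo = bisect.bisect_left(run_starts, span_lo)
        for ri in range(lo, len(runs)):
            s, e, base = runs[ri]
            if s - 1 < span_lo:
                continue
            if e >= span_hi:
                break
            a = read_pos(s - 1)
            b = read_pos(e)
            if a is None or b is None or b <= a:
                continue
            segment = rec.aligned_seq()[a + 1:b]
            best = cur = 0
            for ch in segment:
                cur = cur + 1 if ch == base else 0
                best = max(best, cur)
            obs[ri][best] += 1
    return obs


def detect_homopolymer_errors(assembly: str,
                              pyro_records: list[AlignmentRecord],
                              short_records: list[AlignmentRecord],
                              params: PolishParams | None = None,
                              log: list | None = None
                              ) -> list[HomopolymerCorrection]:
    """Apply the two-condition hybrid-evidence rule at every homopolymer run
    of the assembly; sites below the evidence depth are skipped (and logged
    when a log list is supplied), never corrected."""
    params = params or PolishParams()
    runs = list(homopolymer_runs(assembly, params.min_run_len))
    short_obs = _run_observations(short_records, runs)
    pyro_obs = _run_observations(pyro_records, runs)

    corrections: list[HomopolymerCorrection] = []
    for (s, e, base), sc, pc in zip(runs, short_obs, pyro_obs):
        L_asm = e - s
        depth_s = sum(sc.values())
        if depth_s < params.min_short_depth or sum(pc.values()) < params.min_pyro_depth:
            if log is not None and (sc or pc):
                log.append({"position": s, "reason": "insufficient depth",
                            "short_depth": depth_s, "pyro_depth": sum(pc.values())})
            continue
        maj_len, maj_count = sc.most_common(1)[0]
        frac = maj_count / depth_s
        cond1 = maj_len != L_asm and frac >= params.support_threshold
        strong = {ln for ln, c in pc.items() if c >= params.pyro_min_per_length}
        cond2 = len(strong) >= params.pyro_distinct_lengths
        if cond1 and cond2:
            corrections.append(HomopolymerCorrection(
                position=s, base=base, run_len_assembly=L_asm,
                run_len_corrected=maj_len, short_support=round(frac, 4),
                pyro_disagreement=True, short_depth=depth_s,
                pyro_lengths=dict(pc)))
        elif cond1 and log is not None:
            log.append({"position": s, "reason": "pyro reads agree with assembly; "
                        "candidate true variant, not corrected",
                        "short_majority": maj_len})
    return corrections


def apply_corrections(assembly: str,
                      corrections: list[HomopolymerCorrection]
                      ) -> tuple[str, list[dict]]:
    """Rewrite the assembly with the corrected run lengths; later
    coordinates shift by the accumulated length delta.  Overlapping
    corrections are an error."""
    corrections = sorted(corrections, key=lambda c: c.position)
    for a, b in zip(corrections, corrections[1:]):
        if a.position + a.run_len_assembly > b.position:
            raise ValueError("overlapping corrections")
    parts: list[str] = []
    log: list[dict] = []
    cursor = 0
    shift = 0
    for c in corrections:
        parts.append(assembly[cursor:c.position])
        parts.append(c.base * c.run_len_corrected)
        log.append({"position": c.position, "new_position": c.position + shift,
                    "base": c.base, "from": c.run_len_assembly,
                    "to": c.run_len_corrected,
                    "short_support": c.short_support})
        shift += c.run_len_corrected - c.run_len_assembly
        cursor = c.position + c.run_len_assembly
    parts.append(assembly[cursor:])
    out = "".join(parts)
    assert len(out) == len(assembly) + sum(
        c.run_len_corrected - c.run_len_assembly for c in corrections)
    return out, log


def write_correction_log(log: list[dict], path) -> None:
    with open(path, "w") as f:
        f.write("position\tbase\tfrom\tto\tshort_support\n")
        for entry in log:
            f.write(f"{entry['position']}\t{entry['base']}\t{entry['from']}"
                    f"\t{entry['to']}\t{entry['short_support']}\n")
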
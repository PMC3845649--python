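"""Copy-number detection from windowed total coverage.

Mean per-site total coverage (multi-mapping reads included, after random
assignment to one repeat copy) is computed for non-overlapping windows
(default 50 nt) along the genome; contiguous runs of windows whose ratio to
the genome-wide median departs from 1 beyond a noise band are merged into
segments with an integer copy estimate.  Boundaries are then refined to
base resolution using the per-position depth step and, where available,
soft-clipped reads whose clip edges pile up at the true junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignmentRecord, parse_cigar
from .variants import Pileup


@dataclass
class CoverageProfile:
    window: int
    values: np.ndarray          # mean per-site coverage per window
    median: float               # genome-wide median window coverage
    genome_length: int

    def ratios(self) -> np.ndarray:
        if self.median <= 0:
            raise ValueError("degenerate profile: zero median coverage")
        return self.values / self.median


@dataclass
class CNSegment:
    start: int                  # 0-based half-open, reference coordinates
    end: int
    ratio: float                # depth-weighted mean coverage ratio
    copy_estimate: int          # round(ratio * background copy number)
    n_windows: int
    refined: bool = False
    breakpoint_confidence: str = "window"   # window | depth_step | clipped
    detail: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationParams:
    noise_lo: float = 0.7       # ratios inside [lo, hi] are background
    noise_hi: float = 1.35
    n_min: int = 10             # minimum run length, in windows
    merge_gap: int = 2          # bridge runs separated by <= this many windows
    background_copies: int = 1


def window_coverage(pile: Pileup, window: int = 50) -> CoverageProfile:
    """Mean per-site coverage for non-overlapping windows; a short final
    window is averaged over its actual length."""
    if window < 1:
        raise ValueError("window must be >= 1")
    depth = pile.depth.astype(float)
    L = len(depth)
    n_full = L // window
    values = depth[:n_full * window].reshape(n_full, window).mean(axis=1)
    if L % window:
        values = np.append(values, depth[n_full * window:].mean())
    return CoverageProfile(window, values, float(np.median(values)), L)


def segment_copy_number(profile: CoverageProfile,
                        params: SegmentationParams | None = None) -> list[CNSegment]:
    """Merge contiguous off-background windows into integer-copy segments;
    background (copy estimate == background) is not reported."""
    params = params or SegmentationParams()
    ratios = profile.ratios()
    off = (ratios < params.noise_lo) | (ratios > params.noise_hi)
    segments: list[CNSegment] = []
    runs = _runs(off)
    # bridge small gaps between runs deviating in the same direction
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= params.merge_gap and \
                _same_direction(ratios, merged[-1], (s, e), params):
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    w = profile.window
    for s, e in merged:
        if e - s < params.n_min:
            continue
        seg_ratios = ratios[s:e]
        weights = np.full(e - s, w, dtype=float)
        if e == len(ratios) and profile.genome_length % w:
            weights[-1] = profile.genome_length % w
        mean_ratio = float(np.average(seg_ratios, weights=weights))
        copy = int(round(mean_ratio * params.background_copies))
        if copy == params.background_copies and abs(mean_ratio - 1) < 0.5:
            continue
        start = s * w
        end = min(profile.genome_length, e * w)
        segments.append(CNSegment(start, end, round(mean_ratio, 3), copy, e - s))
    return segments


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return out
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i != prev + 1:
            out.append((start, prev + 1))
            start = i
        prev = i
    out.append((start, prev + 1))
    return out


def _same_direction(ratios, run_a, run_b, params) -> bool:
    mean_a = float(ratios[run_a[0]:run_a[1]].mean())
    mean_b = float(ratios[run_b[0]:run_b[1]].mean())
    return (mean_a > params.noise_hi) == (mean_b > params.noise_hi)


def refine_boundaries(segment: CNSegment, pile: Pileup,
                      records: list[AlignmentRecord] | None = None,
                      search_pad: int | None = None,
                      window: int = 50) -> CNSegment:
    """Move segment breakpoints to base resolution.

    Soft-clipped reads whose clip edge falls near a window-resolution
    boundary pinpoint the junction; without clipped support the boundary
    falls back to the maximal per-position depth step.  Refinement never
    moves a boundary further than one window beyond its supporting
    evidence."""
    pad = search_pad if search_pad is not None else 2 * window
    depth = pile.depth.astype(float)
    L = len(depth)

    clip_edges: dict[int, int] = {}
    if records:
        for rec in records:
            if not rec.mapped or "S" not in rec.cigar:
                continue
            ops = parse_cigar(rec.cigar)
            if ops[0][0] == "S":
                clip_edges[rec.start % L] = clip_edges.get(rec.start % L, 0) + 1
            if ops[-1][0] == "S":
                e = rec.ref_end() % L
                clip_edges[e] = clip_edges.get(e, 0) + 1

    def refine_one(b: int, is_start: bool) -> tuple[int, str]:
        lo, hi = max(0, b - pad), min(L, b + pad)
        # clipped-read evidence first
        local = {p: c for p, c in clip_edges.items() if lo <= p < hi and c >= 2}
        if local:
            best = max(local, key=lambda p: (local[p], -abs(p - b)))
            return best, "clipped"
        # depth-step: position of maximal |step| of the cumulative difference
        seg = depth[lo:hi]
        if len(seg) < 2:
            return b, "window"
        steps = np.abs(np.diff(seg))
        return lo + int(np.argmax(steps)) + 1, "depth_step"

    new_start, conf_s = refine_one(segment.start, True)
    new_end, conf_e = refine_one(segment.end, False)
    if new_end <= new_start:  # refinement collapsed: keep window resolution
        return segment
    conf = "clipped" if (conf_s == "clipped" and conf_e == "clipped") else \
        ("depth_step" if "depth_step" in (conf_s, conf_e) or "clipped" in (conf_s, conf_e)
         else "window")
    return CNSegment(new_start, new_end, segment.ratio, segment.copy_estimate,
                     segment.n_windows, refined=True, breakpoint_confidence=conf,
                     detail=dict(segment.detail))


def write_bedgraph(profile: CoverageProfile, ref_name: str, path) -> None:
    with open(path, "w") as f:
        f.write(f'track type=bedGraph name="{ref_name} coverage"\n')
        w = profile.window
        for i, v in enumerate(profile.values):
            end = min(profile.genome_length, (i + 1) * w)
            f.write(f"{ref_name}\t{i * w}\t{end}\t{v:.3f}\n")


def write_segments_bed(segments: list[CNSegment], ref_name: str, path) -> None:
    with open(path, "w") as f:
        f.write("# chrom\tstart\tend\tname\tratio\tcopy_estimate\tconfidence\n")
        for s in segments:
            f.write(f"{ref_name}\t{s.start}\t{s.end}\tcnv\t{s.ratio}"
                    f"\t{s.copy_estimate}\t{s.breakpoint_confidence}\n")
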
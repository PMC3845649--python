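"""Ancestor genome construction and strain derivation.

Models a repeat-rich circular bacterial chromosome (AT-biased, multi-copy IS
elements with terminal inverted repeats, direct- and inverted-repeat pairs)
and applies the mutation event classes observed between near-identical
endosymbiont strains: point mutations, small indels, IS-element insertions,
repeat-bounded segmental deletions, tandem amplifications and
repeat-bounded inversions.  Every derivation carries an exact truth record
and an ancestor-to-derived coordinate liftover so downstream detectors can
be scored against the plant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .._util import derive_seed, gc_content, random_dna, revcomp


class LayoutInfeasibleError(ValueError):
    """Requested features cannot be packed into the genome."""


@dataclass(frozen=True)
class ISElement:
    """One genomic copy of an insertion-sequence element."""

    start: int
    end: int
    family: str
    strand: str = "+"
    tir_len: int = 30

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatPair:
    """Two near-identical copies, same orientation (direct) or reverse
    complement (inverted)."""

    first: tuple[int, int]
    second: tuple[int, int]
    inverted: bool = False


@dataclass
class GenomeModel:
    """Annotated circular reference sequence with its repeat/IS catalog."""

    name: str
    sequence: str
    is_elements: list[ISElement] = field(default_factory=list)
    direct_repeat_pairs: list[RepeatPair] = field(default_factory=list)
    inverted_repeat_pairs: list[RepeatPair] = field(default_factory=list)
    gc_target: float = 0.36
    is_family_seqs: dict[str, str] = field(default_factory=dict)
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)

    def validate(self, repeat_identity: float = 0.95) -> None:
        L = len(self.sequence)
        feats = [(e.start, e.end) for e in self.is_elements]
        for pair in self.direct_repeat_pairs + self.inverted_repeat_pairs:
            feats += [pair.first, pair.second]
        for s, e in feats:
            if not (0 <= s < e <= L):
                raise ValueError(f"feature ({s},{e}) outside [0,{L})")
        for el in self.is_elements:
            seq = self.sequence[el.start:el.end]
            t = el.tir_len
            if seq[:t] != revcomp(seq[-t:]):
                raise ValueError(f"IS element at {el.start} lacks terminal inverted repeats")
        for pair in self.direct_repeat_pairs:
            a = self.sequence[pair.first[0]:pair.first[1]]
            b = self.sequence[pair.second[0]:pair.second[1]]
            if _identity(a, b) < repeat_identity:
                raise ValueError("direct repeat pair below identity threshold")
        for pair in self.inverted_repeat_pairs:
            a = self.sequence[pair.first[0]:pair.first[1]]
            b = revcomp(self.sequence[pair.second[0]:pair.second[1]])
            if _identity(a, b) < repeat_identity:
                raise ValueError("inverted repeat pair below identity threshold")
        if abs(self.gc - self.gc_target) > 0.02:
            raise ValueError(f"realized GC {self.gc:.3f} departs from target {self.gc_target}")


def _identity(a: str, b: str) -> float:
    if len(a) != len(b) or not a:
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class AncestorConfig:
    """Declarative layout for :func:`build_ancestor`.

    ``placements`` entries are (kind, spec) tuples; supported kinds:

    - ``("is", {"family": "IS5", "length": 900, "tir_len": 30, "copies": 3})``
      random non-overlapping copies of one element family;
    - ``("direct_pair", {"length": 1000, "gap": 57000})`` same-orientation
      repeat pair separated by ``gap`` bp;
    - ``("inverted_pair", {"length": 1000, "gap": 20000})`` reverse-complement
      pair.

    Explicit ``start`` keys pin a feature; otherwise placement is random.
    """

    length: int
    gc: float = 0.36
    placements: list[tuple[str, dict]] = field(default_factory=list)
    repeat_identity: float = 1.0
    name: str = "ancestor"
    margin: int = 200  # minimum spacing between features


def build_ancestor(config: AncestorConfig, seed: int) -> GenomeModel:
    """Construct a random annotated circular genome; deterministic per seed.

    Raises :class:`LayoutInfeasibleError` when the requested features cannot
    fit, rather than silently truncating any of them.
    """
    rng = np.random.default_rng(derive_seed(seed, f"ancestor:{config.name}"))
    L = config.length
    seq = list(random_dna(rng, L, config.gc))

    occupied: list[tuple[int, int]] = []
    model = GenomeModel(name=config.name, sequence="", gc_target=config.gc)

    def reserve(length: int, start: int | None = None) -> int:
        if length + 2 * config.margin > L:
            raise LayoutInfeasibleError(f"feature of {length} bp cannot fit genome of {L} bp")
        if start is not None:
            iv = (start, start + length)
            if start < 0 or start + length > L or _overlaps(iv, occupied, config.margin):
                raise LayoutInfeasibleError(f"pinned feature at {start} (+{length} bp) collides")
            occupied.append(iv)
            return start
        for _ in range(2000):
            s = int(rng.integers(0, L - length))
            iv = (s, s + length)
            if not _overlaps(iv, occupied, config.margin):
                occupied.append(iv)
                return s
        raise LayoutInfeasibleError("layout infeasible: could not place feature after 2000 tries")

    def write(s: int, fragment: str) -> None:
        seq[s:s + len(fragment)] = fragment

    for kind, spec in config.placements:
        if kind == "is":
            fam = spec.get("family", "IS5")
            elen = int(spec.get("length", 900))
            tir = int(spec.get("tir_len", 30))
            if elen <= 2 * tir:
                raise LayoutInfeasibleError("IS element shorter than its two TIRs")
            if fam not in model.is_family_seqs:
                tir_seq = random_dna(rng, tir, config.gc)
                interior = random_dna(rng, elen - 2 * tir, config.gc)
                model.is_family_seqs[fam] = tir_seq + interior + revcomp(tir_seq)
            element = model.is_family_seqs[fam]
            starts = spec.get("starts")
            copies = int(spec.get("copies", 1)) if starts is None else len(starts)
            for i in range(copies):
                s = reserve(elen, None if starts is None else int(starts[i]))
                strand = "+" if rng.random() < 0.5 else "-"
                write(s, element if strand == "+" else revcomp(element))
                model.is_elements.append(ISElement(s, s + elen, fam, strand, tir))
        elif kind in ("direct_pair", "inverted_pair"):
            rlen = int(spec.get("length", 1000))
            gap = int(spec.get("gap", 10000))
            total = 2 * rlen + gap
            s = reserve(total, spec.get("start"))
            unit = random_dna(rng, rlen, config.gc)
            second = _degrade(unit, config.repeat_identity, rng)
            if kind == "direct_pair":
                write(s, unit)
                write(s + rlen + gap, second)
                model.direct_repeat_pairs.append(
                    RepeatPair((s, s + rlen), (s + rlen + gap, s + total)))
            else:
                write(s, unit)
                write(s + rlen + gap, revcomp(second))
                model.inverted_repeat_pairs.append(
                    RepeatPair((s, s + rlen), (s + rlen + gap, s + total), inverted=True))
        else:
            raise ValueError(f"unknown placement kind {kind!r}")

    model.sequence = "".join(seq)
    model.validate(repeat_identity=min(0.95, config.repeat_identity))
    return model


def _overlaps(iv: tuple[int, int], occupied: list[tuple[int, int]], margin: int) -> bool:
    s, e = iv
    return any(s < oe + margin and os_ < e + margin for os_, oe in occupied)


def _degrade(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Introduce substitutions so the copy has roughly the requested identity."""
    if identity >= 1.0:
        return seq
    n_mut = int(round(len(seq) * (1 - identity)))
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        out[pos] = "ACGT"[(("ACGT".index(out[pos])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


# ---------------------------------------------------------------------------
# Mutation events and strain derivation
# ---------------------------------------------------------------------------

EVENT_KINDS = ("snp", "small_indel", "is_insertion", "segmental_deletion",
               "tandem_amplification", "inversion")


@dataclass(frozen=True)
class MutationEvent:
    """One planted difference, in ancestor coordinates.

    kind-specific fields:

    - ``snp``: ``position``, ``alt`` (single base);
    - ``small_indel``: ``position`` plus either ``deletion_length`` or
      ``insertion_seq`` (the indel occupies/inserts at ``position``);
    - ``is_insertion``: ``position`` (target site), ``family``, ``strand``,
      ``tsd_len`` target-site duplication;
    - ``segmental_deletion``: ``interval`` spanning from the end of the first
      direct-repeat copy to the end of the second (single-recombination
      semantics: one hybrid repeat copy survives);
    - ``tandem_amplification``: ``interval`` and multiplicity ``m`` >= 2;
    - ``inversion``: ``interval`` between an inverted-repeat pair.
    """

    kind: str
    position: int = -1
    alt: str = ""
    deletion_length: int = 0
    insertion_seq: str = ""
    family: str = ""
    strand: str = "+"
    tsd_len: int = 4
    interval: tuple[int, int] = (0, 0)
    m: int = 0

    def span(self) -> tuple[int, int]:
        """Ancestor interval this event occupies (for overlap checks)."""
        if self.kind == "snp":
            return (self.position, self.position + 1)
        if self.kind == "small_indel":
            # pure insertions occupy no ancestor bases (inserted before position)
            return (self.position, self.position + self.deletion_length)
        if self.kind == "is_insertion":
            return (self.position, self.position + max(1, self.tsd_len))
        return self.interval

    def length_delta(self, genome: "GenomeModel") -> int:
        if self.kind == "snp":
            return 0
        if self.kind == "small_indel":
            return len(self.insertion_seq) - self.deletion_length
        if self.kind == "is_insertion":
            return len(genome.is_family_seqs[self.family]) + self.tsd_len
        if self.kind == "segmental_deletion":
            return self.interval[0] - self.interval[1]
        if self.kind == "tandem_amplification":
            return (self.m - 1) * (self.interval[1] - self.interval[0])
        if self.kind == "inversion":
            return 0
        raise ValueError(self.kind)


class Liftover:
    """Monotone ancestor-to-derived coordinate map built from colinear blocks.

    Each block is (anc_start, anc_end, der_start, strand); deleted ancestor
    positions map to None.
    """

    def __init__(self, blocks: list[tuple[int, int, int, int]]):
        self.blocks = sorted(blocks)

    def lift(self, pos: int) -> int | None:
        for a0, a1, d0, strand in self.blocks:
            if a0 <= pos < a1:
                return d0 + (pos - a0) if strand > 0 else d0 + (a1 - 1 - pos)
        return None


@dataclass
class StrainTruth:
    """A derived strain plus the exact record of how it was made."""

    name: str
    ancestor: GenomeModel
    sequence: str
    events: list[MutationEvent]
    liftover: Liftover

    def to_model(self) -> GenomeModel:
        """View the derived strain as a (feature-less) GenomeModel, suitable
        for use as a mapping reference."""
        return GenomeModel(name=self.name, sequence=self.sequence,
                           gc_target=self.ancestor.gc_target,
                           is_family_seqs=dict(self.ancestor.is_family_seqs))


def apply_events(genome: GenomeModel, events: list[MutationEvent],
                 name: str = "derived") -> StrainTruth:
    """Apply non-overlapping mutation events to an ancestor genome.

    Deletions must be bounded by a cataloged direct-repeat pair and
    inversions by an inverted-repeat pair; violations raise ValueError.
    """
    anc = genome.sequence
    L = len(anc)
    evs = sorted(events, key=lambda e: e.span()[0])
    for e in evs:
        s, t = e.span()
        if not (0 <= s <= t <= L):
            raise ValueError(f"event {e.kind} span ({s},{t}) outside genome")
    for a, b in zip(evs, evs[1:]):
        if a.span()[1] > b.span()[0]:
            raise ValueError(f"overlapping events at {a.span()} / {b.span()}")

    for e in evs:
        if e.kind == "segmental_deletion" and not _deletion_repeat_bounded(genome, e):
            raise ValueError("segmental_deletion interval is not bounded by a direct repeat pair")
        if e.kind == "inversion" and not _inversion_repeat_bounded(genome, e):
            raise ValueError("inversion interval is not bounded by an inverted repeat pair")
        if e.kind == "tandem_amplification" and e.m < 2:
            raise ValueError("tandem_amplification requires multiplicity m >= 2")
        if e.kind == "snp" and anc[e.position] == e.alt:
            raise ValueError(f"snp alt equals ancestor base at {e.position}")

    parts: list[str] = []
    blocks: list[tuple[int, int, int, int]] = []
    cursor = 0   # ancestor coordinate
    out_len = 0  # derived coordinate

    def emit(anc_s: int, anc_e: int) -> None:
        nonlocal out_len
        if anc_e > anc_s:
            parts.append(anc[anc_s:anc_e])
            blocks.append((anc_s, anc_e, out_len, +1))
            out_len += anc_e - anc_s

    for e in evs:
        s, t = e.span()
        emit(cursor, s)
        if e.kind == "snp":
            parts.append(e.alt)
            out_len += 1
        elif e.kind == "small_indel":
            if e.deletion_length:
                pass  # bases dropped
            parts.append(e.insertion_seq)
            out_len += len(e.insertion_seq)
        elif e.kind == "is_insertion":
            element = genome.is_family_seqs[e.family]
            if e.strand == "-":
                element = revcomp(element)
            tsd = anc[e.position:e.position + e.tsd_len]
            frag = tsd + element + tsd
            parts.append(frag)
            out_len += len(frag)
        elif e.kind == "segmental_deletion":
            pass  # interval dropped; surviving repeat copy was emitted before s
        elif e.kind == "tandem_amplification":
            unit = anc[s:t]
            for copy_i in range(e.m):
                parts.append(unit)
                blocks.append((s, t, out_len, +1) if copy_i == 0 else (s, t, out_len, +1))
                out_len += t - s
            # only the first copy should serve as THE lifted image; drop extras
            blocks = blocks[:-(e.m - 1)]
        elif e.kind == "inversion":
            parts.append(revcomp(anc[s:t]))
            blocks.append((s, t, out_len, -1))
            out_len += t - s
        else:
            raise ValueError(e.kind)
        cursor = t
    emit(cursor, L)

    derived = "".join(parts)
    expected = L + sum(e.length_delta(genome) for e in evs)
    assert len(derived) == expected, "length accounting failed"
    return StrainTruth(name=name, ancestor=genome, sequence=derived,
                       events=list(evs), liftover=Liftover(blocks))


def _deletion_repeat_bounded(genome: GenomeModel, e: MutationEvent) -> bool:
    s, t = e.interval
    for pair in genome.direct_repeat_pairs:
        if s == pair.first[1] and t == pair.second[1]:
            return True
        if s == pair.first[0] and t == pair.second[0]:
            return True
    return False


def _inversion_repeat_bounded(genome: GenomeModel, e: MutationEvent) -> bool:
    s, t = e.interval
    for pair in genome.inverted_repeat_pairs:
        if s == pair.first[1] and t == pair.second[0]:
            return True
    return False


def snp_event(genome: GenomeModel, position: int, rng: np.random.Generator | None = None,
              alt: str | None = None) -> MutationEvent:
    """Convenience constructor choosing a non-reference alt base."""
    ref = genome.sequence[position]
    if alt is None:
        choices = [b for b in "ACGT" if b != ref]
        alt = choices[0] if rng is None else choices[int(rng.integers(3))]
    return MutationEvent(kind="snp", position=position, alt=alt)
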
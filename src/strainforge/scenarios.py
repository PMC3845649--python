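"""Canned synthetic strain-contrast scenarios.

Each builder emulates one of the strain comparisons the pipeline is meant
to resolve, at desk scale but with the event geometry preserved:

- ``cs_vs_pop``: two strains identical except for a tandem triplication of
  a 19-kb region — the single difference between the benign donor strain
  and its pathogenic derivative;
- ``pop_vs_cla``: a derived strain carrying five differences — loss of the
  entire ~57-kb amplified array by a single recombination between the
  same-orientation repeats that flank it, a new IS-element insertion, two
  point mutations and a 10-bp deletion;
- ``cla_vs_pgyp``: two independent sequencing runs (different technologies)
  of the *same* genome — the pipeline must report zero differences;
- ``phylo_clades``: two clades of consensus-genome relatives with the
  pathogenic strain arising inside the donor clade, for tree inference.

Genome sizes are reduced relative to a real ~1.3-Mb chromosome so that a
full simulate-map-call-detect cycle stays interactive; event sizes that
carry meaning (the 19-kb unit, the 57-kb loss, the 10-bp deletion) are kept
at face value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import derive_seed
from .simulate.genome import (AncestorConfig, GenomeModel, MutationEvent,
                              RepeatPair, StrainTruth, apply_events,
                              build_ancestor, snp_event)
from .simulate.reads import (ReadSet, ReadSimConfig, simulate_pyro_reads,
                             simulate_short_reads)


@dataclass
class StrainInput:
    name: str
    readsets: list[ReadSet]
    assembly: str | None = None


@dataclass
class Scenario:
    name: str
    reference: GenomeModel
    strains: list[StrainInput]
    truths: dict[str, StrainTruth] = field(default_factory=dict)
    compare: list[tuple[str, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


# Paired-library profile used throughout: 100-bp mates, 700 +/- 70 bp
# fragments.  The fragment length deliberately exceeds the flanking-repeat
# length used in the deletion scenarios (400 bp), so that read pairs can
# straddle a repeat-mediated junction with both mates in unique sequence —
# the geometry discordant-pair detection relies on.
def short_config(depth: float = 35.0, insert_mean: float = 700.0,
                 insert_sd: float = 70.0, eps_sub: float = 0.002) -> ReadSimConfig:
    return ReadSimConfig(technology="short", read_length=100, paired=True,
                         insert_mean=insert_mean, insert_sd=insert_sd,
                         eps_sub=eps_sub, depth=depth)


def pyro_config(depth: float = 35.0, eps_hp: float = 0.02,
                eps_sub: float = 0.001) -> ReadSimConfig:
    return ReadSimConfig(technology="pyro", paired=False, depth=depth,
                         eps_hp=eps_hp, eps_sub=eps_sub)


def _short_lib(truth_seq: str, strain: str, seed: int, depth: float,
               **kw) -> ReadSet:
    cfg = short_config(depth=depth, **kw)
    return simulate_short_reads(truth_seq, cfg, derive_seed(seed, f"lib:{strain}"),
                                name=strain)


def cs_vs_pop(seed: int, genome_len: int = 100_000, unit_len: int = 19_000,
              multiplicity: int = 3, depth: float = 35.0) -> Scenario:
    """Sole planted event: tandem amplification of a 19-kb region."""
    unit_start = 40_000
    anc = build_ancestor(AncestorConfig(
        length=genome_len, gc=0.36, name="wCS_like",
        placements=[
            ("is", {"family": "IS5", "length": 900, "tir_len": 30,
                    "starts": [5_000, 20_000, 70_000]}),
        ]), seed)
    cs = apply_events(anc, [], name="CS")
    pop = apply_events(anc, [MutationEvent(
        kind="tandem_amplification",
        interval=(unit_start, unit_start + unit_len), m=multiplicity)], name="Pop")
    strains = [
        StrainInput("CS", [_short_lib(cs.sequence, "CS", seed, depth)]),
        StrainInput("Pop", [_short_lib(pop.sequence, "Pop", seed, depth)]),
    ]
    return Scenario("cs_vs_pop", anc, strains, {"CS": cs, "Pop": pop},
                    compare=[("CS", "Pop")],
                    meta={"unit": (unit_start, unit_start + unit_len),
                          "multiplicity": multiplicity})


def _pop_like_reference(seed: int, genome_len: int, unit_len: int,
                        repeat_len: int, multiplicity: int
                        ) -> tuple[GenomeModel, StrainTruth, GenomeModel]:
    """Ancestor with one repeat-bracketed unit, amplified to the full array.

    Returns (single-copy ancestor, amplification truth, derived model with a
    repeat catalog in derived coordinates)."""
    pair_start = 30_000
    anc = build_ancestor(AncestorConfig(
        length=genome_len, gc=0.36, name="wCS_like",
        placements=[
            ("direct_pair", {"length": repeat_len, "gap": unit_len - repeat_len,
                             "start": pair_start}),
            ("is", {"family": "IS5", "length": 900, "tir_len": 30,
                    "starts": [5_000, 15_000, 60_000 + unit_len]}),
        ]), seed)
    r1 = anc.direct_repeat_pairs[0].first            # (30000, 30400)
    r2 = anc.direct_repeat_pairs[0].second
    amp_iv = (r1[1], r2[1])                           # unit + trailing repeat
    pop = apply_events(anc, [MutationEvent(
        kind="tandem_amplification", interval=amp_iv, m=multiplicity)], name="Pop")
    shift = (multiplicity - 1) * (amp_iv[1] - amp_iv[0])
    model = pop.to_model()
    model.direct_repeat_pairs = [RepeatPair(r1, (r2[0] + shift, r2[1] + shift))]
    model.is_elements = []
    for el in anc.is_elements:
        lifted = pop.liftover.lift(el.start)
        if lifted is not None:
            from .simulate.genome import ISElement

            model.is_elements.append(ISElement(lifted, lifted + el.length,
                                               el.family, el.strand, el.tir_len))
    return anc, pop, model


def pop_vs_cla(seed: int, genome_len: int = 120_000, unit_len: int = 19_000,
               repeat_len: int = 400, multiplicity: int = 3,
               depth: float = 35.0, full_event_set: bool = True) -> Scenario:
    """The five-difference contrast: deletion of the whole amplified array
    (single recombination between flanking direct repeats, removing
    multiplicity x unit_len = 57 kb), one new IS insertion, two point
    mutations and a 10-bp deletion.  With ``full_event_set=False`` only the
    array deletion is planted."""
    anc, pop, pop_model = _pop_like_reference(seed, genome_len, unit_len,
                                              repeat_len, multiplicity)
    pair = pop_model.direct_repeat_pairs[0]
    del_iv = (pair.first[1], pair.second[1])   # 57 kb
    rng = np.random.default_rng(derive_seed(seed, "pop_vs_cla:events"))
    events = [MutationEvent(kind="segmental_deletion", interval=del_iv)]
    if full_event_set:
        L = len(pop_model.sequence)
        safe_lo = del_iv[1] + 3_000
        events += [
            MutationEvent(kind="is_insertion", position=int(L - 18_000),
                          family="IS5", strand="+"),
            snp_event(pop_model, int(safe_lo + 4_000), rng),
            snp_event(pop_model, int(L - 9_000), rng),
            MutationEvent(kind="small_indel", position=int(safe_lo + 9_000),
                          deletion_length=10),
        ]
    cla = apply_events(pop_model, events, name="CLA")
    strains = [
        StrainInput("Pop", [_short_lib(pop.sequence, "Pop", seed, depth)]),
        StrainInput("CLA", [_short_lib(cla.sequence, "CLA", seed, depth)]),
    ]
    return Scenario("pop_vs_cla", pop_model, strains,
                    {"Pop": pop, "CLA": cla}, compare=[("Pop", "CLA")],
                    meta={"deletion_interval": del_iv,
                          "deleted_length": del_iv[1] - del_iv[0],
                          "events": events, "ancestor": anc})


def cla_vs_pgyp(seed: int, genome_len: int = 50_000, depth: float = 35.0,
                mixed_technology: bool = True) -> Scenario:
    """Identical genomes, independently sequenced (one pyro library, one
    short paired library when mixed): the correct report is empty."""
    anc = build_ancestor(AncestorConfig(
        length=genome_len, gc=0.36, name="wPop_like",
        placements=[("is", {"family": "IS5", "length": 900, "tir_len": 30,
                            "starts": [genome_len // 6, genome_len * 3 // 5]})]),
        seed)
    if mixed_technology:
        cla_reads = simulate_pyro_reads(anc.sequence, pyro_config(depth=depth),
                                        derive_seed(seed, "lib:CLA"), name="CLA")
    else:
        cla_reads = _short_lib(anc.sequence, "CLA", seed, depth)
    pgyp_reads = _short_lib(anc.sequence, "PGYP", seed + 1, depth)
    strains = [StrainInput("CLA", [cla_reads]), StrainInput("PGYP", [pgyp_reads])]
    truth = apply_events(anc, [], name="shared")
    return Scenario("cla_vs_pgyp", anc, strains,
                    {"CLA": truth, "PGYP": truth}, compare=[("CLA", "PGYP")])


def phylo_clades(seed: int, genome_len: int = 40_000, depth: float = 30.0
                 ) -> Scenario:
    """Two clades diverged from one reference genome, with the pathogenic
    strain derived inside the donor clade (sister to its lab-stock
    relative).  Mutations are planted along a known tree; the expected
    clades are recorded in meta."""
    anc = build_ancestor(AncestorConfig(length=genome_len, gc=0.36,
                                        name="wMel_ref"), seed)
    rng = np.random.default_rng(derive_seed(seed, "phylo:muts"))
    positions = rng.choice(genome_len - 200, size=400, replace=False) + 100
    positions = iter(sorted(int(p) for p in positions))

    def snps(n: int) -> list[MutationEvent]:
        return [snp_event(anc, next(positions), rng) for _ in range(n)]

    mel_shared = snps(25)
    cs_shared = snps(25)
    dgrp_shared = snps(10)
    canton_pop_shared = snps(10)
    taxa_events = {
        "Mel1": mel_shared + snps(6),
        "Mel2": mel_shared + snps(6),
        "Mel3": mel_shared + snps(6),
        "DGRP335": cs_shared + dgrp_shared + snps(4),
        "DGRP338": cs_shared + dgrp_shared + snps(4),
        "CantonS": cs_shared + canton_pop_shared + snps(3),
        "Pop": cs_shared + canton_pop_shared + snps(3),
    }
    strains: list[StrainInput] = []
    truths: dict[str, StrainTruth] = {}
    for taxon, events in taxa_events.items():
        truth = apply_events(anc, events, name=taxon)
        truths[taxon] = truth
        strains.append(StrainInput(
            taxon, [_short_lib(truth.sequence, taxon, seed, depth)]))
    return Scenario("phylo_clades", anc, strains, truths,
                    meta={"expected_clades": [
                        {"CantonS", "Pop"},
                        {"DGRP335", "DGRP338", "CantonS", "Pop"},
                        {"Mel1", "Mel2", "Mel3"}]})


BUILTIN = {"cs_vs_pop": cs_vs_pop, "pop_vs_cla": pop_vs_cla,
           "cla_vs_pgyp": cla_vs_pgyp, "phylo_clades": phylo_clades}
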
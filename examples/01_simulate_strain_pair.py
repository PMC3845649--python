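"""Build an annotated ancestor genome, derive a strain carrying known
mutations, and write the ground truth as VCF + BED.

The ancestor is a circular, AT-biased (36% GC) chromosome with two copies
of an IS element (terminal inverted repeats included).  The derived strain
carries one point mutation and one 10-bp deletion; the liftover lets us
verify every untouched base survived unchanged.
"""

from strainforge.simulate import (AncestorConfig, MutationEvent, apply_events,
                                  build_ancestor, write_truth)

ancestor = build_ancestor(AncestorConfig(
    length=30_000, gc=0.36,
    placements=[("is", {"family": "IS5", "length": 900, "tir_len": 30,
                        "copies": 2})]), seed=42)
print(f"ancestor: {len(ancestor.sequence):,} bp, GC {ancestor.gc:.1%}, "
      f"{len(ancestor.is_elements)} IS copies")

alt = "A" if ancestor.sequence[12_000] != "A" else "G"
derived = apply_events(ancestor, [
    MutationEvent(kind="snp", position=12_000, alt=alt),
    MutationEvent(kind="small_indel", position=18_000, deletion_length=10),
], name="derived")
print(f"derived:  {len(derived.sequence):,} bp "
      f"({len(derived.sequence) - len(ancestor.sequence):+d} bp from "
      f"{len(derived.events)} events)")

checked = sum(1 for pos in range(0, 30_000, 7)
              if pos not in range(18_000, 18_010) and pos != 12_000
              and derived.sequence[derived.liftover.lift(pos)]
              == ancestor.sequence[pos])
print(f"liftover spot-check: {checked} unmutated positions identical")

write_truth(derived, "derived.truth.vcf", "derived.truth.bed")
print("truth written: derived.truth.vcf (2 small variants, 1-based), "
      "derived.truth.bed (structural events, 0-based half-open)")
# The VCF deletion record has an 11-bp REF and 1-bp ALT: the standard
# anchored encoding of a 10-bp deletion.
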
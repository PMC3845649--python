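"""Hybrid homopolymer polishing of a pyrosequencing-style draft.

Ten homopolymer runs of a 20-kb genome are corrupted by one base each
(the characteristic flow-sequencing failure mode), then corrected with
the two-condition rule: short reads must contradict the assembly AND the
pyro reads must disagree among themselves about the run length.  Sites
where the pyro reads are unanimous are left alone as candidate true
variants.
"""

import edlib

from strainforge.align import ReferenceIndex, map_read_pairs
from strainforge.polish import apply_corrections, detect_homopolymer_errors
from strainforge.simulate import (AncestorConfig, ReadSimConfig,
                                  build_ancestor, simulate_pyro_reads,
                                  simulate_short_reads)

truth = build_ancestor(AncestorConfig(length=20_000, gc=0.36), seed=9)


def plant_hp_errors(seq, n, seed):
    import numpy as np

    from strainforge._util import homopolymer_runs

    runs = list(homopolymer_runs(seq, 4))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(runs), size=n, replace=False))
    out, last, planted = [], 0, []
    for idx in chosen:
        s, e, base = runs[idx]
        delta = 1 if rng.random() < 0.5 else -1
        out += [seq[last:s], base * (e - s + delta)]
        planted.append((s, e - s, e - s + delta))
        last = e
    out.append(seq[last:])
    return "".join(out), planted


assembly, planted = plant_hp_errors(truth.sequence, 10, seed=2)
print(f"draft assembly: {len(planted)} planted homopolymer errors, edit "
      f"distance to truth = "
      f"{edlib.align(assembly, truth.sequence)['editDistance']}")

short = simulate_short_reads(truth.sequence, ReadSimConfig(
    depth=35, insert_mean=700, insert_sd=70, eps_sub=0.001), seed=3)
pyro = simulate_pyro_reads(truth.sequence, ReadSimConfig(
    technology="pyro", paired=False, depth=30, eps_hp=0.15), seed=4)

index = ReferenceIndex("asm", assembly)
corrections = detect_homopolymer_errors(
    assembly, map_read_pairs(pyro, index), map_read_pairs(short, index))
polished, log = apply_corrections(assembly, corrections)
print(f"{len(log)} corrections applied; edit distance to truth now "
      f"{edlib.align(polished, truth.sequence)['editDistance']}")
for entry in log[:5]:
    print(f"  run at {entry['position']}: {entry['base']} x{entry['from']} "
          f"-> x{entry['to']} (short-read support {entry['short_support']})")
# Edit distance drops to (near) zero: the short reads arbitrate run
# lengths, and the pyro-disagreement condition keeps true variants intact.
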
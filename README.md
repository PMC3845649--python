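# strainforge

Comparative genomics of near-identical bacterial strains: find, confirm
and count *every* detectable difference between closely related genomes
from sequencing reads.

The package targets the regime exemplified by the *Wolbachia* wMelCS /
wMelPop strain series, where two ~1.3-Mb endosymbiont genomes separated by
decades of evolution differ by a handful of events — a copy-number change
of one region, an IS-element hop, a couple of point mutations — and the
scientific claim ("these strains differ by exactly N events, and strain X
arose inside clade Y") rests on exhaustive detection with explicit
confirmation of every candidate.  It provides, as importable library
modules:

- **simulate** — annotated circular ancestor genomes (AT-biased, IS
  elements with terminal inverted repeats, direct/inverted repeat pairs),
  derived strains with exact truth records for six mutation classes, and
  two read-technology error models (accurate short pairs; homopolymer-
  error-prone pyrosequencing-style reads);
- **align** — a seed-and-extend mapper for small genomes with multi-mapper
  bookkeeping, joint mate resolution, soft clipping and SAM I/O;
- **polish** — hybrid homopolymer correction of draft assemblies (short
  reads must contradict the assembly *and* pyro reads must disagree among
  themselves);
- **variants** — pileup, filtered haploid calling, reference-coordinate
  consensus genomes, assembly-vs-assembly diffing, and reciprocal
  cross-strain confirmation (supports / refutes / insufficient per
  strain);
- **cnv** — 50-nt windowed total coverage, integer-copy segmentation,
  breakpoint refinement from clipped reads or depth steps;
- **svscan** — the three discordant-pair classes (too far / bad
  orientation / one end unmapped), endpoint-consistent clustering,
  split-read IS-insertion discovery via terminal-inverted-repeat matches,
  and evidence reconciliation;
- **phylo** — core-column extraction from consensus genomes (blocks ≥ 100
  bp), p / Jukes–Cantor distances, neighbor-joining trees, clade queries;
- **qpcr** — relative amplification E^(Cp_ref)/E^(Cp_test) and
  across-strain fold changes with censoring;
- **pipeline** — the orchestrated comparison producing one
  `DifferenceReport` per strain pair, with an audit trail of every
  unconfirmed candidate.

The statistic at the core of the difference report is deliberately plain:
a site-level difference is *confirmed* iff, re-evaluated in every strain
from that strain's own pileup, at least one strain supports the allele
(fraction ≥ f_maj), at least one refutes it, and none is coverage-
insufficient; structural differences require concordant evidence from two
independent channels (e.g. a zero-copy coverage segment plus a
discordant-pair cluster whose insert excess matches).  One region-level
event counts as one difference.

## Worked example

Two strains identical except for a tandem triplication of a 19-kb region
(`examples/03_triplication_cnv.py`):

```python
from strainforge.pipeline import compare_strains
from strainforge.scenarios import cs_vs_pop

scenario = cs_vs_pop(seed=7)          # 100-kb reference, 35x paired reads
reports, _ = compare_strains(scenario.strains, scenario.reference,
                             seed=7, pairs=scenario.compare)
print(reports[0].total, reports[0].by_class)
```

prints

```
CS vs Pop: 1 confirmed difference(s) {'cnv': 1}
  cnv at [39,997, 59,006): coverage ratio {'CS': 1.013, 'Pop': 2.868},
  copy states {'CS': 1, 'Pop': 3}, length 19.01 kb, 174 everted junction pairs
```

— exactly one difference between the strains: a segment whose coverage
ratio rounds to three copies in one strain and one in the other, 19 kb
long, corroborated by everted read pairs at the tandem junctions.  The
other examples walk through the five-difference cell-line-passage
contrast (including a ~57-kb repeat-mediated deletion measured two
independent ways), the zero-difference control between two sequencing
runs of the same genome, the printed eight-variant allele table, the
consensus-genome phylogeny that places the pathogenic strain inside the
donor clade, qPCR copy-number verification and homopolymer polishing:

```bash
python examples/04_five_differences.py
python examples/05_consensus_phylogeny.py
```

A thin CLI (`strainforge run|map|call|consensus|cnv|sv|isfind|polish|
phylo|qpcr`) wraps the same functions for shell use; see
`strainforge --help` and `examples/scenario_cs_vs_pop.yaml`.

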
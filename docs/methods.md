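# Methods

`strainforge` implements the full computational chain used to enumerate the
differences between near-identical bacterial strains — the regime where two
genomes of ~1 Mb differ by a handful of events and every candidate must be
confirmed or explicitly discarded.  This note records the models, the
parameters that matter, and the design decisions taken where more than one
reasonable choice existed.

## The synthetic study system

Real strain comparisons of this kind start from deposited read sets; the
package instead generates its own study system so every stage is testable
against planted truth.  The generator emulates a *Wolbachia*-like
chromosome and the event classes observed between the wMelCS / wMelPop /
wMelPop-CLA / wMelPop-PGYP strain series:

- **Ancestor genome** (`simulate.build_ancestor`): circular, AT-biased
  (default GC 0.36, realized composition within ±2 percentage points),
  carrying multi-copy IS elements with terminal inverted repeats (TIRs,
  default 30 bp on a 900-bp element), same-orientation ("direct") repeat
  pairs and reverse-complement ("inverted") repeat pairs.  Feature packing
  is randomized with a 200-bp spacing margin; an impossible request raises
  a layout error rather than silently truncating.
- **Mutation events** (`simulate.apply_events`): point mutations, small
  indels, IS insertions (with a 4-bp target-site duplication), segmental
  deletions, tandem amplifications and inversions.  Two events carry
  mechanistic constraints: a segmental deletion must be bounded by a
  cataloged direct-repeat pair and removes the interval plus one repeat
  copy (single-homologous-recombination semantics, one hybrid copy
  survives); an inversion must be bounded by an inverted-repeat pair.
  Every derivation returns a monotone ancestor→derived liftover and an
  exact event list, and length accounting is asserted internally.
- **Read simulation**: two technology profiles.  *Short* — inward-facing
  paired reads (default 100 bp, fragment 700 ± 70 bp, see below), i.i.d.
  substitutions at `eps_sub` (default 0.002) with Phred qualities encoding
  that rate, no homopolymer artifacts.  *Pyro* — longer single-end reads
  (Gaussian length, default 300 ± 50 bp) whose dominant error is
  homopolymer run-length miscounting: a run of length L ≥ 3 gains or loses
  one base with probability p(L) = min(p_max, eps_hp·(L−2)), the direction
  equiprobable.  No published quantitative error profile exists for the
  flow-sequencing platform this emulates; p(L) is a declared stand-in that
  is monotone in run length and fully configurable (defaults eps_hp 0.02,
  p_max 1.0).  Reads are drawn circular-aware (they may span the origin).

What the generator does **not** model: GC- or origin-proximity coverage
bias, quality miscalibration, chimeric fragments, contamination, or
plasmids.  Passing tests therefore demonstrate the *logic* of each
detector under clean sampling noise, not robustness to the full error
structure of real libraries — the depth-bound filters and reciprocal
confirmation exist precisely because real libraries are messier.

### Scenario geometry

The canned scenarios keep the event sizes that carry meaning at face value
(the 19-kb amplified unit, the 3× multiplicity, hence a ~57-kb loss, the
10-bp deletion) on reduced chromosomes of 100–160 kb so a full
simulate→compare cycle runs in seconds.  Two linked choices are geometric:
the repeats flanking the deletable array are 400 bp and the short-read
fragment length is 700 ± 70 bp.  Read pairs can then straddle a
repeat-mediated junction with both mates anchored in unique sequence,
which is the configuration discordant-pair detection requires; with
fragments shorter than the flanking repeat, junction-spanning pairs always
have one mate inside the repeat and the pair route is blind (coverage
still sees the event).  Scenario depth defaults to 35×.

## Alignment

A purpose-built seed-and-extend mapper (exact k-mer index, k = 17, both
strands, circularity handled by extending the reference and canonicalizing
coordinates mod L) with:

- scoring +1 match / −2 mismatch / −4 gap open / −1 gap extend;
- an ungapped fast path for the dominant substitution-only case; gapped
  extension in a ±16-bp padded window via unit-cost edit distance
  (`edlib`), rescored under the affine model; when the unit-cost path
  fragments one indel into co-optimal pieces the window is realigned under
  the affine model proper (Biopython `PairwiseAligner`), so every read
  crossing the same indel reports the same gap placement — tests verify
  score equality against an exhaustive affine DP oracle;
- acceptance thresholds: score ≥ 0.4·read length **and** "badness"
  (mismatches + 2·gap runs) ≤ max(4, 0.07·read length).  The badness cap
  is what separates a plausible variant (one long gap) from a junction
  read limping across a breakpoint on a mismatch-riddled tail; the latter
  falls back to prefix/suffix soft-clipping (minimum 20 bp anchored),
  which is exactly the evidence breakpoint refinement wants;
- all equally-best placements retained; mates resolved jointly toward an
  inward-facing plausible insert, with mate rescue by targeted search near
  a uniquely placed partner; multi-mappers later assigned uniformly at
  random among equally-best placements (pairs jointly, so a pair never
  straddles two repeat copies by bookkeeping accident).  Random assignment
  preserves *total* coverage over a repeat family, which is what makes a
  triplicated region show a 3× signal.
- mapping-quality proxy: capped score gap between best and second-best
  placement; only relative confidence is consumed downstream.

Insert statistics are median/MAD-based: pairs silently spanning an
undetected deletion carry grossly inflated inserts and must not drag the
location estimate the discordance test is built on.

## Variant calling and reciprocal confirmation

Pileup columns accumulate aligned bases (reference orientation), with
indels anchored to the preceding base and left-normalized (VCF
convention).  Indel evidence uses an honest denominator: the number of
reads anchored ≥ 20 bp past the site, because a read ending inside an
indel can neither show nor refute it.

Calls are haploid majority calls filtered on three axes: column quality
proxy (mean Phred) ≥ 10, majority fraction ≥ `f_maj`, and depth inside
[d_min, d_max].  The upper depth bound suppresses collapsed repeats.  Two
filter presets exist: the absolute bounds appropriate to deep real
libraries (quality 10, call depth 10–220, consensus depth 10–100,
exposed as `CallFilters.preset_published()`) and, as the default, bounds
scaled to the library (d_min = max(10, 0.1·mean depth), d_max = 2·mean),
since absolute bounds encode a specific coverage.  `f_maj` defaults to
0.7: with per-base error below 1% a true haploid allele sits near
fraction 1.0, and the headroom absorbs junction-read dilution at indels
while still demanding a decisive majority.

A consensus genome assigns the majority base where depth lies inside the
consensus bounds and the majority reaches `f_maj`, else N; output length
equals reference length, so consensus genomes from one reference are
already positionally aligned.

**Cross-checking** is the package's central safeguard: every candidate
from any strain is re-evaluated in *every* strain from that strain's own
pileup as supports (allele fraction ≥ f_maj), refutes (≤ 1−f_maj) or
insufficient (depth < d_min, or mixed evidence).  A difference is
confirmed iff at least one strain supports, at least one refutes, and no
compared strain is insufficient at the site.  This removes the detection
asymmetries that depth or quality differences between libraries would
otherwise convert into false strain differences — it is the property that
makes two independent sequencing runs of the same genome report zero
differences.

Assembly-vs-assembly comparison (`diff_assemblies`) reports every
substitution and small indel between sequences sharing a coordinate
frame, N-columns excluded; clustered records are locally re-derived under
the affine model so one planted edit yields one record.  In the pipeline
it runs as an auxiliary route whose disagreements with the read route are
surfaced in the audit list, never auto-resolved.

## Copy number

Mean per-site total coverage (multi-mappers included after random
assignment) over non-overlapping 50-nt windows; a short final window
averages over its actual length.  Windows whose ratio to the genome-wide
median leaves the background band [0.7, 1.35] are merged into segments
when ≥ 10 consecutive windows agree (gaps ≤ 2 windows bridged); the
integer copy estimate is the rounded depth-weighted mean ratio.  The band
and run length separate integer copy states cleanly at depth ≥ 30; both
are configurable.  Boundaries are then refined to base resolution from
soft-clip pile-ups when ≥ 2 clip edges coincide, else from the maximal
per-position depth step, searching ± 2 windows around the
window-resolution boundary — a declared substitute for a finer-grained
published procedure whose details are not available, sharing its stated
goal.  Refinement confidence is reported (clipped / depth_step / window).

## Structural variation and IS insertions

Non-proper pairs are classified, in declared order, as one_end_unmapped,
bad_orientation (same-strand, or outward/everted) or too_far (inferred
fragment > μ + 4σ under the robust insert stats; the z = 4 threshold
makes the Gaussian tail contribution < 10⁻⁴ per pair).  Pairs with an
ambiguous (multi-placement) or clipped mate are excluded from pair
classes: clipped mates carry junction signal, not geometry.  Clusters
must agree at *both* breakpoint ends (within μ + 3σ) and reach 3
supporting pairs; overlap alone is not enough, since two unrelated
wide-spanning noise pairs can overlap hugely while describing nothing in
common.  Clusters are typed (too_far → deletion; same-strand →
inversion; everted → tandem-duplication junction; one_end_unmapped →
novel insertion) and annotated with any direct/inverted repeat pair
flanking them in the reference catalog.  Orientation evidence anchored
inside a cataloged IS element is discarded — element copies make those
placements untrustworthy.

IS insertions are found independently of pair geometry: reads containing
a TIR match (≥ 15 bp at ≥ 90% identity) plus ≥ 20 bp of non-element
flank are split, the flank is mapped, and unique flank placements
cluster (30-bp window, ≥ 2 junction reads) into sites labeled ancestral
(at a cataloged element edge) or new.  Per-strain presence/absence —
present, absent-with-coverage, or insufficient — is what turns a site
into a strain difference.

`reconcile` automates the final manual-inspection step as concordance
rules per strain pair: a deletion is confirmed by a zero-copy coverage
segment *plus* an agreeing too_far cluster (and reports both length
estimates: refined zero-coverage span and median insert excess); an
amplification needs only the segment (everted junction pairs corroborate
but are optional); an IS difference needs a strain-differential site with
adequate coverage in the absent strain.  Coverage shifts confined to
repeat-family copies are attributed to the family's insertion difference
rather than reported as independent CNVs, and small-variant calls inside
a confirmed structural footprint (IS target-site duplication, SV
breakpoint ± 50 bp) are recognized as that event's own junction signal.
Everything that fails a rule lands in the audit list with a reason.

## Homopolymer polishing

A correction is emitted at a homopolymer run (≥ 3 identical bases — the
flow-sequencing error mode is negligible below that) iff (1) the
short-read majority (> 0.8 among ≥ 10 spanning reads) indicates a run
length different from the assembly and (2) the pyro reads disagree among
themselves (≥ 2 distinct lengths, each in ≥ 2 of ≥ 4 reads) — the
signature of a platform artifact.  Short reads contradicting a unanimous
pyro pile-up mark a candidate true variant and are logged, not
corrected.  The published description of this rule states no evidence
depths; the thresholds here are declared assumptions, conservative and
configurable.  Corrected length is the short-read majority; application
shifts downstream coordinates and is idempotent under re-polishing.

## Phylogeny

Because all consensus genomes are called against one reference, core
extraction reduces to keeping maximal all-callable (non-N) column runs of
≥ 100 bp — no rearrangement inference is needed for consensus rows.
Distances are p-distances with the Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3), flagged beyond its domain (p ≥ 0.75).  Trees are
inferred by neighbor joining (via scikit-bio) with tiny negative NJ
branches clamped to zero; on near-identical genomes the acceptance-level
quantity is the topology, where NJ and likelihood methods agree, so NJ is
used as a documented substitution for a maximum-likelihood step, not an
emulation of one.  `is_clade` tests whether any edge bipartition of the
unrooted tree isolates exactly a given taxon set.  No bootstrap, rate
heterogeneity or recombination detection is attempted.

## qPCR

Relative amplification is E^(Cp_ref)/E^(Cp_test) with efficiency
E ∈ (1, 2] supplied by configuration (default 2.0; how E is estimated is
outside scope).  Replicates are averaged on the Cp scale — the
near-Gaussian quantity — before exponentiation.  Zero template copies
propagate as censored ("no amplification") rather than a number.  Only
within-gene, across-strain folds are emitted; cross-gene ratios depend on
primer efficiencies and are deliberately not computable from the API.
The Cp simulator (Cp = Cp₁ − log copies / log E + noise) exists to close
the loop in tests: planted copy ratios {0, 1, 2, 3} are recovered at
noise SD ≤ 0.2.

## Difference accounting

A report counts one copy-number change of one region as ONE difference
regardless of how many genes it spans; one IS insertion is one; one SV is
one; each confirmed SNP or small indel is one.  The total always equals
the sum over classes, every confirmed difference carries its evidence,
and reports are byte-reproducible given inputs and seeds (every
stochastic stage takes an explicit seed; there is no global RNG state;
stage seeds are derived from the master seed by hashing stage labels).

## Known limitations

- The mapper targets genomes ≤ ~5 Mb at ≤ ~5% divergence; no spliced
  alignment, no base-quality-aware scoring.
- SVs nested inside long repeats the read length cannot bridge are out of
  reach, as for any short-read pipeline.
- Coverage-based copy estimates assume no systematic coverage bias; on
  real libraries GC correction would be required before trusting ratios
  near the band edges.
- Deletion length from coverage span can include up to one flanking-repeat
  length of ambiguity, since reads from the surviving hybrid repeat copy
  distribute over both reference copies.
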
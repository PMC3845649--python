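"""End-to-end strain comparison.

``compare_strains`` runs the full evidence chain for every strain against a
shared reference — map, assign multi-mappers, pile up, call and filter
variants, window coverage into copy-number segments, classify and cluster
discordant pairs, locate IS junctions — then, per strain pair, confirms
small variants reciprocally (each strain re-evaluated from its own pileup)
and reconciles the structural evidence into a difference report whose
accounting matches how strain comparisons are reported in practice: one
copy-number change of one region is ONE difference, however many genes it
spans; one IS insertion is one; one SV is one; each confirmed SNP or small
indel is one.

Three comparison routes are supported where inputs permit: reads against
the common reference (always), assembly against assembly (when both
strains carry an assembly of comparable length), and reads against the
partner assembly implicitly via the cross-check.  Route disagreements are
surfaced in the audit list, never silently resolved.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from ._util import derive_seed
from .align import (PairStats, ReferenceIndex, Scoring, assign_multimappers,
                    estimate_insert_stats, map_read_pairs)
from .cnv import (CNSegment, CoverageProfile, SegmentationParams,
                  refine_boundaries, segment_copy_number, window_coverage)
from .scenarios import BUILTIN, Scenario, StrainInput
from .simulate.genome import GenomeModel
from .simulate.truthio import write_fasta, write_truth
from .svscan import (ISInsertion, SVCandidate, SVParams, classify_pairs,
                     cluster_candidates, find_is_insertions, is_presence_matrix,
                     reconcile)
from .variants import (CallFilters, ConfirmedDifference, Pileup, VariantCall,
                       call_variants, consensus_genome, cross_check,
                       diff_assemblies, pileup)


@dataclass
class PipelineConfig:
    k: int = 17
    scoring: Scoring = field(default_factory=Scoring)
    window: int = 50
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)
    sv_params: SVParams = field(default_factory=SVParams)
    filters: CallFilters | None = None      # None: scale depth bounds per strain
    circular: bool = True
    refine_cnv: bool = True
    assembly_route_max_delta: int = 2000    # length gap beyond which the
    # assembly-vs-assembly route is skipped (whole-arm SVs are the coverage
    # route's job)


@dataclass
class StrainAnalysis:
    name: str
    records: list
    pile: Pileup
    filters: CallFilters
    calls: list[VariantCall]
    consensus: str
    profile: CoverageProfile
    segments: list[CNSegment]
    stats: PairStats | None
    sv_candidates: list[SVCandidate]
    is_sites: list[ISInsertion]
    mean_depth: float


@dataclass
class DifferenceReport:
    strain_a: str
    strain_b: str
    differences: list[ConfirmedDifference]
    audit: list[dict]
    provenance: dict = field(default_factory=dict)

    @property
    def by_class(self) -> dict[str, int]:
        return dict(Counter(d.cls for d in self.differences))

    @property
    def total(self) -> int:
        return len(self.differences)

    def to_dict(self) -> dict:
        return {
            "strain_pair": [self.strain_a, self.strain_b],
            "total": self.total,
            "by_class": self.by_class,
            "differences": [
                {"class": d.cls, "start": d.start, "end": d.end,
                 "statuses": d.statuses, "detail": _jsonable(d.detail)}
                for d in self.differences],
            "unconfirmed": _jsonable(self.audit),
            "provenance": self.provenance,
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def analyze_strain(strain: StrainInput, index: ReferenceIndex,
                   reference: GenomeModel, config: PipelineConfig,
                   seed: int) -> StrainAnalysis:
    """Run the per-strain evidence chain against the shared reference."""
    records = []
    paired_blocks = []
    for rs in strain.readsets:
        block = map_read_pairs(rs, index, config.scoring)
        records += block
        if rs.paired:
            paired_blocks.append(block)
    assign_multimappers(records, derive_seed(seed, f"assign:{strain.name}"))

    pile = pileup(records, index.name, index.seq, circular=config.circular)
    mean_depth = pile.mean_depth()
    filters = config.filters or CallFilters.scaled(mean_depth)
    calls = call_variants(pile, filters, strain.name)
    consensus = consensus_genome(pile, filters)
    profile = window_coverage(pile, config.window)

    segments = segment_copy_number(profile, config.seg_params)
    if config.refine_cnv:
        segments = [refine_boundaries(s, pile, records, window=config.window)
                    for s in segments]

    stats = None
    discordant = []
    for block in paired_blocks:
        try:
            block_stats = estimate_insert_stats(block)
        except ValueError:
            continue
        stats = stats or block_stats
        discordant += classify_pairs(block, block_stats, config.sv_params.z,
                                     genome_length=index.L,
                                     circular=config.circular)
    sv_candidates = cluster_candidates(discordant, records, config.sv_params,
                                       stats, reference) if discordant else []

    is_sites: list[ISInsertion] = []
    if reference.is_family_seqs:
        for rs in strain.readsets:
            is_sites += find_is_insertions(
                rs, reference.is_family_seqs, index, config.sv_params,
                reference=reference if reference.is_elements else None,
                scoring=config.scoring)
    return StrainAnalysis(strain.name, records, pile, filters, calls, consensus,
                          profile, segments, stats, sv_candidates, is_sites,
                          mean_depth)


def compare_strains(strains: list[StrainInput], reference: GenomeModel,
                    seed: int, config: PipelineConfig | None = None,
                    pairs: list[tuple[str, str]] | None = None,
                    analyses: dict[str, StrainAnalysis] | None = None
                    ) -> tuple[list[DifferenceReport], dict[str, StrainAnalysis]]:
    """Compare every requested strain pair; returns the reports plus the
    per-strain analyses (reusable for consensus/phylogeny)."""
    if len(strains) < 2:
        raise ValueError("need at least two strains to compare")
    config = config or PipelineConfig()
    index = ReferenceIndex(reference.name, reference.sequence, k=config.k,
                           circular=config.circular)
    analyses = analyses or {}
    for strain in strains:
        if strain.name not in analyses:
            analyses[strain.name] = analyze_strain(strain, index, reference,
                                                   config, seed)
    names = [s.name for s in strains]
    pairs = pairs or [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]

    by_name = {s.name: s for s in strains}
    reports: list[DifferenceReport] = []
    for a, b in pairs:
        ana, anb = analyses[a], analyses[b]
        pair_filters = config.filters or CallFilters.scaled(
            min(ana.mean_depth, anb.mean_depth))
        confirmed, audit = cross_check(
            {a: ana.calls, b: anb.calls}, {a: ana.pile, b: anb.pile}, pair_filters)
        matrix = is_presence_matrix({a: ana.is_sites, b: anb.is_sites},
                                    {a: ana.pile, b: anb.pile},
                                    d_min=pair_filters.d_min)
        struct, struct_audit = reconcile(
            {a: ana.segments, b: anb.segments},
            {a: ana.profile, b: anb.profile},
            {a: ana.sv_candidates, b: anb.sv_candidates},
            matrix, a, b, config.sv_params, reference=reference)
        audit = audit + struct_audit
        # a small-variant call sitting in the footprint of a confirmed
        # structural difference (IS target-site duplication, SV breakpoint)
        # is that event's own junction signal, not a second difference
        footprints = []
        for d in struct:
            if d.cls == "is_insertion":
                footprints.append((d.start - 10, d.end + 10))
            else:  # breakpoint neighborhoods only; the interior is fair game
                footprints.append((d.start - 50, d.start + 50))
                footprints.append((d.end - 50, d.end + 50))
        kept = []
        for d in confirmed:
            hit = next((fp for fp in footprints
                        if d.start < fp[1] and d.end > fp[0]), None)
            if hit is None:
                kept.append(d)
            else:
                audit.append({"position": d.start + 1, "kind": d.cls,
                              "reason": "within the footprint of a confirmed "
                                        "structural difference"})
        confirmed = kept

        sa, sb = by_name[a], by_name[b]
        if sa.assembly and sb.assembly and \
                abs(len(sa.assembly) - len(sb.assembly)) <= config.assembly_route_max_delta:
            audit += _assembly_route_audit(sa.assembly, sb.assembly,
                                           confirmed, a, b)
        report = DifferenceReport(
            a, b, differences=confirmed + struct, audit=audit,
            provenance={"seed": seed, "config": _config_hash(config),
                        "mean_depth": {a: round(ana.mean_depth, 2),
                                       b: round(anb.mean_depth, 2)}})
        reports.append(report)
    return reports, analyses


def _assembly_route_audit(asm_a: str, asm_b: str,
                          confirmed: list[ConfirmedDifference],
                          a: str, b: str) -> list[dict]:
    """Assembly-vs-assembly route: surface disagreements with the read
    route rather than resolving them."""
    out: list[dict] = []
    try:
        mismatches = diff_assemblies(asm_a, asm_b)
    except ValueError as exc:
        return [{"route": "assembly", "reason": str(exc)}]
    read_route_pos = {d.start for d in confirmed}
    for m in mismatches:
        if m.pos_a not in read_route_pos and (m.pos_a - 1) not in read_route_pos:
            out.append({"route": "assembly", "kind": m.kind, "position": m.pos_a,
                        "reason": f"assembly route sees {m.kind} not confirmed "
                                  f"by the read route ({a} vs {b})"})
    return out


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({k: repr(v) for k, v in vars(config).items()},
                      sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

class ConfigError(ValueError):
    """Scenario configuration problem, with the offending keys listed."""

    def __init__(self, message: str, keys: list[str]):
        super().__init__(f"{message}: {keys}")
        self.keys = keys


_ALLOWED_KEYS = {"scenario", "seed", "outdir", "options"}


def run_scenario(config: dict | str | Path, outdir: str | Path | None = None
                 ) -> tuple[Scenario, list[DifferenceReport]]:
    """Run a named scenario end to end (simulate, compare, report).

    ``config`` is a mapping or a YAML file with keys ``scenario`` (one of
    the builtin names), ``seed`` (int), optional ``options`` (keyword
    overrides for the scenario builder, e.g. depth) and optional
    ``outdir``."""
    if not isinstance(config, dict):
        import yaml

        with open(config) as f:
            config = yaml.safe_load(f)
    unknown = sorted(set(config) - _ALLOWED_KEYS)
    if unknown:
        raise ConfigError("unknown configuration keys", unknown)
    missing = sorted({"scenario", "seed"} - set(config))
    if missing:
        raise ConfigError("missing configuration keys", missing)
    name = config["scenario"]
    if name not in BUILTIN:
        raise ConfigError("unknown scenario (available: "
                          + ", ".join(sorted(BUILTIN)) + ")", [name])
    options = config.get("options") or {}
    if not isinstance(options, dict):
        raise ConfigError("options must be a mapping", ["options"])
    scenario = BUILTIN[name](int(config["seed"]), **options)
    reports, analyses = compare_strains(scenario.strains, scenario.reference,
                                        int(config["seed"]),
                                        pairs=scenario.compare or None)
    outdir = outdir or config.get("outdir")
    if outdir:
        _write_artifacts(Path(outdir), scenario, reports, analyses)
    return scenario, reports


def _write_artifacts(outdir: Path, scenario: Scenario,
                     reports: list[DifferenceReport],
                     analyses: dict[str, StrainAnalysis]) -> None:
    from .cnv import write_bedgraph, write_segments_bed

    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(scenario.reference.name, scenario.reference.sequence,
                outdir / "reference.fa")
    for name, truth in scenario.truths.items():
        if truth.events:
            write_truth(truth, outdir / f"{name}.truth.vcf",
                        outdir / f"{name}.truth.bed")
    for name, ana in analyses.items():
        write_bedgraph(ana.profile, scenario.reference.name,
                       outdir / f"{name}.coverage.bedgraph")
        write_segments_bed(ana.segments, scenario.reference.name,
                           outdir / f"{name}.cnv.bed")
        write_fasta(name, ana.consensus, outdir / f"{name}.consensus.fa")
    payload = [r.to_dict() for r in reports]
    (outdir / "report.json").write_text(json.dumps(payload, indent=2) + "\n")
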
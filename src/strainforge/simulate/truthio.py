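"""Ground-truth serialization.

Small variants (SNPs, small indels) are written as VCF v4.2 records in
1-based coordinates with the usual anchored REF/ALT convention; structural
events (IS insertions, segmental deletions, tandem amplifications,
inversions) as BED6+ rows in 0-based half-open coordinates with kind,
multiplicity and payload columns.  Both dialects are stated in the file
headers.  Reading the pair of files back reproduces the event list exactly.
"""

from __future__ import annotations

from ..simulate.genome import GenomeModel, MutationEvent, StrainTruth


def write_truth(truth: StrainTruth, vcf_path, bed_path) -> None:
    anc = truth.ancestor.sequence
    small = [e for e in truth.events if e.kind in ("snp", "small_indel")]
    structural = [e for e in truth.events if e.kind not in ("snp", "small_indel")]

    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write("##source=strainforge-truth\n")
        vcf.write("##coordinates=1-based (VCF convention)\n")
        vcf.write(f"##contig=<ID={truth.ancestor.name},length={len(anc)}>\n")
        vcf.write('##INFO=<ID=KIND,Number=1,Type=String,Description="Planted event kind">\n')
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for e in sorted(small, key=lambda e: e.position):
            chrom = truth.ancestor.name
            if e.kind == "snp":
                vcf.write(f"{chrom}\t{e.position + 1}\t.\t{anc[e.position]}\t{e.alt}"
                          f"\t.\tPASS\tKIND=snp\n")
            else:
                # anchor on the base before the edited span
                p = e.position - 1
                ref = anc[p:e.position + e.deletion_length]
                alt = anc[p] + e.insertion_seq
                vcf.write(f"{chrom}\t{p + 1}\t.\t{ref}\t{alt}\t.\tPASS\tKIND=small_indel\n")

    with open(bed_path, "w") as bed:
        bed.write("# strainforge structural truth; 0-based half-open coordinates\n")
        bed.write("# chrom\tstart\tend\tkind\tscore\tstrand\tmultiplicity\tpayload\n")
        for e in sorted(structural, key=lambda e: e.span()[0]):
            s, t = e.span()
            payload = e.family if e.kind == "is_insertion" else "."
            extra = f"tsd={e.tsd_len}" if e.kind == "is_insertion" else "."
            bed.write(f"{truth.ancestor.name}\t{s}\t{t}\t{e.kind}\t0\t{e.strand}"
                      f"\t{e.m if e.m else 1}\t{payload}\t{extra}\n")


def read_truth(vcf_path, bed_path, ancestor: GenomeModel) -> list[MutationEvent]:
    """Parse truth files written by :func:`write_truth` back into events."""
    events: list[MutationEvent] = []
    anc = ancestor.sequence
    with open(vcf_path) as vcf:
        for line in vcf:
            if line.startswith("#"):
                continue
            _, pos, _, ref, alt, *_rest = line.rstrip("\n").split("\t")
            pos = int(pos) - 1
            if len(ref) == 1 and len(alt) == 1:
                events.append(MutationEvent(kind="snp", position=pos, alt=alt))
            else:
                events.append(MutationEvent(
                    kind="small_indel", position=pos + 1,
                    deletion_length=len(ref) - 1, insertion_seq=alt[1:]))
    with open(bed_path) as bed:
        for line in bed:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            _, s, t, kind, _, strand, mult, payload = fields[:8]
            s, t, mult = int(s), int(t), int(mult)
            if kind == "is_insertion":
                tsd = int(fields[8].split("=")[1]) if len(fields) > 8 and "=" in fields[8] else 4
                events.append(MutationEvent(kind=kind, position=s, family=payload,
                                            strand=strand, tsd_len=tsd))
            elif kind == "tandem_amplification":
                events.append(MutationEvent(kind=kind, interval=(s, t), m=mult))
            else:
                events.append(MutationEvent(kind=kind, interval=(s, t)))
    _ = anc
    return sorted(events, key=lambda e: e.span()[0])


def write_fasta(name: str, seq: str, path, width: int = 80) -> None:
    with open(path, "w") as f:
        f.write(f">{name}\n")
        for i in range(0, len(seq), width):
            f.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
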
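"""Technology-specific read simulation.

Two profiles are modeled:

- ``short``: accurate paired short reads (Illumina-like).  Inward-facing
  mates drawn from a Gaussian fragment-length distribution, i.i.d.
  substitution errors at ``eps_sub``, Phred qualities consistent with that
  rate, no homopolymer artifacts.
- ``pyro``: longer single-end pyrosequencing-like reads whose dominant
  error mode is homopolymer run-length miscounting: a maximal run of length
  L >= 3 is lengthened or shortened by one base with probability
  p(L) = min(p_max, eps_hp * (L - 2)), the +/-1 direction equiprobable.
  The probability is non-decreasing in L, matching the qualitative failure
  mode of flow-based sequencing.

Templates are drawn circular-aware: a read may span the origin of the
(circular) chromosome.  All simulation is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._util import (derive_seed, homopolymer_runs, phred_char,
                     phred_from_error_rate, revcomp)


@dataclass
class ReadSimConfig:
    technology: str = "short"          # "short" | "pyro"
    read_length: int = 100             # fixed length for short reads
    pyro_length_mean: float = 300.0    # pyro read-length distribution
    pyro_length_sd: float = 50.0
    pyro_length_min: int = 50
    paired: bool = True
    insert_mean: float = 400.0         # fragment length, outer coords (bp)
    insert_sd: float = 40.0
    eps_sub: float = 0.002             # per-base substitution rate
    eps_hp: float = 0.02               # homopolymer per-run rate scale
    hp_pmax: float = 1.0               # cap on per-run error probability
    depth: float = 30.0                # target mean coverage (x)
    circular: bool = True

    def validate(self) -> None:
        if not (0 <= self.eps_sub <= 1 and 0 <= self.eps_hp <= 1):
            raise ValueError("error rates must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.technology == "short" and self.paired:
            if self.insert_mean <= 2 * self.read_length:
                raise ValueError("insert_mean must exceed twice the read length")

    def model_description(self) -> str:
        if self.technology == "pyro":
            return (f"pyro error model: per-run p(L)=min({self.hp_pmax},"
                    f"{self.eps_hp}*(L-2)) for runs L>=3, +/-1 bp equiprobable; "
                    f"eps_sub={self.eps_sub}")
        return f"short-read model: i.i.d. substitutions at eps_sub={self.eps_sub}"


@dataclass
class SimRead:
    read_id: str
    seq: str
    qual: str
    mate: int | None = None      # 1 or 2 for paired reads
    true_start: int = -1         # template start on the (circular) source
    true_strand: str = "+"


@dataclass
class ReadSet:
    name: str
    technology: str
    paired: bool
    reads: list[SimRead] = field(default_factory=list)
    config: ReadSimConfig | None = None

    def __len__(self) -> int:
        return len(self.reads)

    def pairs(self):
        """Yield (mate1, mate2) tuples for a paired set."""
        if not self.paired:
            raise ValueError("read set is unpaired")
        for i in range(0, len(self.reads), 2):
            yield self.reads[i], self.reads[i + 1]

    def total_bases(self) -> int:
        return sum(len(r.seq) for r in self.reads)


def _template(seq: str, start: int, length: int, circular: bool) -> str:
    L = len(seq)
    if start + length <= L:
        return seq[start:start + length]
    if not circular:
        raise ValueError("template extends past a linear sequence end")
    return (seq + seq[:length])[start:start + length]


def _substitute(read: np.ndarray, eps: float, rng: np.random.Generator) -> np.ndarray:
    if eps <= 0:
        return read
    hits = np.nonzero(rng.random(len(read)) < eps)[0]
    if len(hits):
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        code = np.searchsorted(np.sort(lut), read[hits])  # A<C<G<T ascii order
        read = read.copy()
        read[hits] = lut[(code + rng.integers(1, 4, size=len(hits))) % 4]
    return read


def simulate_short_reads(seq: str, config: ReadSimConfig, seed: int,
                         name: str = "reads") -> ReadSet:
    """Simulate an inward-oriented paired short-read library."""
    if config.technology != "short" or not config.paired:
        raise ValueError("config must have technology='short', paired=True")
    if not seq:
        raise ValueError("empty template sequence")
    config.validate()
    rng = np.random.default_rng(derive_seed(seed, f"short:{name}"))
    L = len(seq)
    rl = config.read_length
    n_pairs = max(1, int(round(config.depth * L / (2 * rl))))

    starts = rng.integers(0, L if config.circular else max(1, L - int(config.insert_mean)),
                          size=n_pairs)
    frags = np.clip(np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)),
                    2 * rl, None).astype(int)
    q = phred_from_error_rate(config.eps_sub)
    qual = phred_char(q) * rl

    reads: list[SimRead] = []
    for i in range(n_pairs):
        frag = _template(seq, int(starts[i]), int(frags[i]), config.circular)
        m1 = np.frombuffer(frag[:rl].encode(), dtype=np.uint8)
        m2 = np.frombuffer(revcomp(frag[-rl:]).encode(), dtype=np.uint8)
        m1 = _substitute(m1, config.eps_sub, rng)
        m2 = _substitute(m2, config.eps_sub, rng)
        rid = f"{name}_{i}"
        reads.append(SimRead(rid, m1.tobytes().decode(), qual, 1, int(starts[i]), "+"))
        reads.append(SimRead(rid, m2.tobytes().decode(), qual, 2,
                             (int(starts[i]) + int(frags[i]) - rl) % L, "-"))
    return ReadSet(name=name, technology="short", paired=True, reads=reads, config=config)


def _hp_distort(template: str, eps_hp: float, pmax: float,
                rng: np.random.Generator) -> str:
    """Apply run-length +/-1 errors to homopolymer runs of length >= 3."""
    if eps_hp <= 0:
        return template
    out: list[str] = []
    last = 0
    for s, e, base in homopolymer_runs(template, 3):
        run_len = e - s
        p = min(pmax, eps_hp * (run_len - 2))
        out.append(template[last:s])
        if rng.random() < p:
            new_len = run_len + (1 if rng.random() < 0.5 else -1)
            out.append(base * new_len)
        else:
            out.append(base * run_len)
        last = e
    out.append(template[last:])
    return "".join(out)


def simulate_pyro_reads(seq: str, config: ReadSimConfig, seed: int,
                        name: str = "pyro") -> ReadSet:
    """Simulate single-end pyrosequencing-like reads with homopolymer errors."""
    if config.technology != "pyro":
        raise ValueError("config must have technology='pyro'")
    if not seq:
        raise ValueError("empty template sequence")
    config.validate()
    rng = np.random.default_rng(derive_seed(seed, f"pyro:{name}"))
    L = len(seq)
    mean_len = config.pyro_length_mean
    n_reads = max(1, int(round(config.depth * L / mean_len)))
    starts = rng.integers(0, L if config.circular else max(1, L - int(mean_len)), size=n_reads)
    lengths = np.clip(np.rint(rng.normal(mean_len, config.pyro_length_sd, size=n_reads)),
                      config.pyro_length_min, None).astype(int)
    q = phred_from_error_rate(max(config.eps_sub, 1e-4))

    reads: list[SimRead] = []
    for i in range(n_reads):
        template = _template(seq, int(starts[i]), int(lengths[i]), config.circular)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            template = revcomp(template)
        r = _hp_distort(template, config.eps_hp, config.hp_pmax, rng)
        arr = _substitute(np.frombuffer(r.encode(), dtype=np.uint8), config.eps_sub, rng)
        r = arr.tobytes().decode()
        reads.append(SimRead(f"{name}_{i}", r, phred_char(q) * len(r), None,
                             int(starts[i]), strand))
    return ReadSet(name=name, technology="pyro", paired=False, reads=reads, config=config)


# ---------------------------------------------------------------------------
# FASTQ I/O (Sanger Phred+33)
# ---------------------------------------------------------------------------

def write_fastq(readset: ReadSet, path, path2=None) -> None:
    """Write a read set; paired sets go to two files when path2 is given,
    otherwise interleaved."""
    def record(r: SimRead) -> str:
        suffix = f"/{r.mate}" if r.mate else ""
        return f"@{r.read_id}{suffix}\n{r.seq}\n+\n{r.qual}\n"

    if readset.paired and path2 is not None:
        with open(path, "w") as f1, open(path2, "w") as f2:
            for m1, m2 in readset.pairs():
                f1.write(record(m1))
                f2.write(record(m2))
    else:
        with open(path, "w") as f:
            for r in readset.reads:
                f.write(record(r))


def read_fastq(path, path2=None, name: str = "reads",
               technology: str = "short") -> ReadSet:
    reads: list[SimRead] = []

    def parse(p, mate):
        out = []
        with open(p) as f:
            while True:
                header = f.readline().strip()
                if not header:
                    break
                seq = f.readline().strip()
                f.readline()
                qual = f.readline().strip()
                rid = header[1:].split("/")[0].split()[0]
                out.append(SimRead(rid, seq, qual, mate))
        return out

    if path2 is not None:
        for m1, m2 in zip(parse(path, 1), parse(path2, 2)):
            reads += [m1, m2]
        paired = True
    else:
        reads = parse(path, None)
        paired = False
    return ReadSet(name=name, technology=technology, paired=paired, reads=reads)
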
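"""Small shared helpers: sequence ops, Phred handling, seed derivation."""

from __future__ import annotations

import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def phred_char(q: int) -> str:
    """Sanger Phred+33 encoding of a single quality value."""
    return chr(33 + max(0, min(93, int(q))))


def phred_from_error_rate(eps: float, cap: int = 40) -> int:
    if eps <= 0:
        return cap
    return min(cap, int(round(-10.0 * np.log10(eps))))


def derive_seed(seed: int, label: str) -> int:
    """Stable child seed for a named stage.

    Keeps every stochastic stage independently seeded from one master seed
    without any global RNG state; result is < 2**31.
    """
    mix = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    return int(mix.generate_state(1)[0] & 0x7FFFFFFF)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    codes = rng.choice(4, size=length, p=p)
    return "".join(BASES[c] for c in codes) if length < 4096 else _codes_to_str(codes)


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode()


def seq_to_array(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array for fast comparisons."""
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def homopolymer_runs(seq: str, min_len: int = 3):
    """Yield (start, end, base) for maximal single-base runs of length >= min_len."""
    i, n = 0, len(seq)
    while i < n:
        j = i + 1
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            yield i, j, seq[i]
        i = j
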
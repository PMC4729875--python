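"""Small sequence and numeric helpers shared across modules."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5,
               alphabet: str = "ACGT") -> str:
    """Random DNA with the given GC content (only meaningful for ACGT)."""
    if alphabet == "ACGT":
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        idx = rng.choice(4, size=length, p=p)
    else:
        idx = rng.integers(len(alphabet), size=length)
        return "".join(alphabet[i] for i in idx)
    return "".join("ACGT"[i] for i in idx)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()
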
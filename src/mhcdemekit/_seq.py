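"""Small sequence utilities shared across modules.

Nucleotide sequences are plain upper-case strings at module boundaries;
hot loops use uint8 arrays (A,C,G,T,N -> 0..4) via :func:`encode` /
:func:`decode`.
"""
from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
_CODE = {c: i for i, c in enumerate("ACGTN")}
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# two-base IUPAC ambiguity codes
IUPAC2 = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
IUPAC2_REV = {v: tuple(sorted(k)) for k, v in IUPAC2.items()}
IUPAC_MULTI = set("BDHVN")  # >= 3-base ambiguity codes

STOP_CODONS = {"TAA", "TAG", "TGA"}


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string as a uint8 array."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(a.shape, 4, dtype=np.uint8)
    for c, i in _CODE.items():
        out[a == ord(c)] = i
    return out


def decode(arr: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[np.asarray(arr, dtype=np.uint8)].tobytes().decode()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str, frame: int = 0) -> str:
    """Translate from ``frame``, truncating a trailing partial codon."""
    core = seq[frame:]
    core = core[: len(core) - len(core) % 3]
    return str(Seq(core).translate())


def has_internal_stop(seq: str, frame: int = 0) -> bool:
    prot = translate(seq, frame)
    return "*" in prot[:-1] or (prot.endswith("*") and len(prot) * 3 + frame < len(seq))


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def random_coding_seq(length: int, rng: np.random.Generator, frame: int = 0) -> str:
    """Random sequence free of stop codons in the given reading frame."""
    while True:
        s = random_seq(length, rng)
        if not has_internal_stop(s, frame):
            return s


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences of unequal length")
    return int(np.count_nonzero(encode(a) != encode(b)))


def diff_sites(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y]


def homopolymer_runs(seq: str, min_len: int = 3) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of length >= ``min_len`` as (start, length, base)."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i, seq[i]))
        i = j
    return runs


def phred_to_ascii(quals) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def ascii_to_phred(s: str) -> list[int]:
    return [ord(c) - 33 for c in s]
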
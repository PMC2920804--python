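"""Small nucleotide-sequence helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")

#: IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "S": "CG", "W": "AT", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, text: str) -> bool:
    """True iff ``text`` matches ``pattern`` base-for-base, where the
    pattern may contain IUPAC degeneracy codes. Lengths must agree."""
    if len(pattern) != len(text):
        return False
    return all(t in IUPAC[p] for p, t in zip(pattern, text))


def mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply independent per-base substitutions at ``error_rate``.

    Each hit base is replaced by one of the three other bases, uniformly.
    """
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size == 0:
        return seq
    for i in hits:
        old = chr(arr[i])
        choices = [b for b in BASES if b != old]
        arr[i] = ord(choices[rng.integers(3)])
    return arr.tobytes().decode()


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))
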
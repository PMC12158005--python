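"""Nucleotide alphabet helpers shared across the pipeline.

All sequences are handled internally as uppercase DNA over {A,C,G,T,N};
RNA input (U) is normalized to T at ingest.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# base -> small integer code; anything unexpected (incl. N) maps to 4 and
# never matches A/C/G/T in vectorized comparisons.
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_LUT[ord(_b)] = _i

VALID_BASES = frozenset("ACGTN")

#: Watson-Crick partner by code (A<->T, C<->G); N has none.
WC_PARTNER = {0: 3, 1: 2, 2: 1, 3: 0}
#: G:U wobble pairs by code, on DNA letters (G:T and T:G).
GU_PAIRS = {(2, 3), (3, 2)}


def normalize(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, convert U to T and validate the alphabet."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in {context}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pairs_watson_crick(a: str, b: str) -> bool:
    return (a, b) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def pairs_wobble(a: str, b: str) -> bool:
    return (a, b) in {("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    """True for Watson-Crick or G:U wobble pairing (DNA letters, T for U)."""
    return pairs_watson_crick(a, b) or pairs_wobble(a, b)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA with the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
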
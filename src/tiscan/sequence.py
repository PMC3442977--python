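"""DNA alphabet utilities shared by all modules.

Sequences are handled as plain upper-case strings over {A, C, G, T} and,
for numeric work, as ``uint8`` arrays with A=0, C=1, G=2, T=3.  Ambiguity
characters encode to 4 so that callers can mask them out.  An ordered base
r-tuple maps to an integer index in base 4 with the tuple's first (lowest)
position most significant, e.g. for r=2 the tuple "CT" has index 1*4+3=7.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterator

import numpy as np

from .errors import InputError

BASES = "ACGT"
AMBIGUOUS_CODE = 4

_ENCODE = np.full(256, AMBIGUOUS_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode(seq: str, strict: bool = False) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3, other=4)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if strict and (arr == AMBIGUOUS_CODE).any():
        bad = sorted({c for c in seq if c.upper() not in BASES})
        raise InputError(f"non-ACGT characters in sequence: {bad}")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def tuple_index(bases: str) -> int:
    """Index of an ordered base tuple, first position most significant."""
    idx = 0
    for b in bases:
        code = BASES.find(b.upper())
        if code < 0:
            raise InputError(f"invalid base {b!r} in tuple {bases!r}")
        idx = idx * 4 + code
    return idx


def index_to_tuple(idx: int, r: int) -> str:
    out = []
    for _ in range(r):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def position_subsets(L: int, r: int) -> Iterator[tuple[int, ...]]:
    """All C(L, r) strictly increasing r-subsets of 1-based positions."""
    if not 1 <= r <= L:
        raise InputError(f"subset order r={r} outside [1, L={L}]")
    return combinations(range(1, L + 1), r)


def n_subsets(L: int, r: int) -> int:
    return comb(L, r)
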
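"""Genome-background probabilities of ordered base r-tuples.

An L-base window slides along the reference sequences and, within each
window, every one of the C(L, r) position subsets contributes one ordered
base r-tuple to the count.  Counts are pooled over subsets — the background
probability q depends only on the bases of the tuple, not on the spacing
between the positions — giving a table of 4**r probabilities.  The window
length L matters because it bounds the span of the tuples that are pooled.

The resulting table is reusable: once counted for a species it serves every
scan of that species at the same (L, r).  For large references ``stride``
and ``sampling_fraction`` subsample window start positions (seeded, hence
reproducible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .sequence import (
    AMBIGUOUS_CODE,
    encode,
    index_to_tuple,
    n_subsets,
    position_subsets,
    reverse_complement,
    tuple_index,
)


@dataclass
class BackgroundModel:
    """Pooled background probabilities over the 4**r ordered base r-tuples."""

    r: int
    L: int
    q: np.ndarray = field(repr=False)
    total_count: int
    source_label: str = ""
    skipped_windows: int = 0

    def prob(self, bases: str) -> float:
        return float(self.q[tuple_index(bases)])

    def log2q(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.q)

    def to_dict(self) -> dict:
        return {
            "schema": "tiscan-model-1",
            "kind": "background",
            "r": self.r,
            "L": self.L,
            "total_count": int(self.total_count),
            "skipped_windows": int(self.skipped_windows),
            "source_label": self.source_label,
            "q": {
                index_to_tuple(i, self.r): float(p) for i, p in enumerate(self.q)
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BackgroundModel":
        r = int(d["r"])
        q = np.zeros(4**r)
        for bases, p in d["q"].items():
            q[tuple_index(bases)] = p
        return cls(
            r=r,
            L=int(d["L"]),
            q=q,
            total_count=int(d["total_count"]),
            source_label=d.get("source_label", ""),
            skipped_windows=int(d.get("skipped_windows", 0)),
        )


def uniform_background(L: int, r: int) -> BackgroundModel:
    """The maximally uninformative background: q(t) = 4**-r for every tuple."""
    return BackgroundModel(
        r=r,
        L=L,
        q=np.full(4**r, 4.0**-r),
        total_count=0,
        source_label="uniform",
    )


def count_background(
    references: Sequence[str] | Mapping[str, str],
    L: int,
    r: int,
    stride: int = 1,
    sampling_fraction: float = 1.0,
    seed: int | None = None,
    include_reverse_complement: bool = False,
    source_label: str = "",
) -> BackgroundModel:
    """Count r-tuples in sliding L-base windows over reference sequences.

    Windows start every ``stride`` bases and must lie fully inside a
    reference.  Windows containing a non-ACGT character are skipped and
    tallied in ``skipped_windows``.  With ``sampling_fraction`` < 1 the
    surviving windows are subsampled with a ``seed``-initialised RNG.
    Overlapping windows deliberately recount shared tuples: every window
    contributes all of its C(L, r) subsets.
    """
    if isinstance(references, Mapping):
        references = list(references.values())
    if not references:
        raise InputError("no reference sequences given")
    if not 1 <= r <= L:
        raise InputError(f"subset order r={r} outside [1, L={L}]")
    if stride < 1:
        raise InputError("stride must be >= 1")
    if not 0 < sampling_fraction <= 1:
        raise InputError("sampling_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    weights = 4 ** np.arange(r - 1, -1, -1, dtype=np.int64)
    offsets = [np.array([p - 1 for p in s]) for s in position_subsets(L, r)]
    counts = np.zeros(4**r, dtype=np.int64)
    n_windows = 0
    skipped = 0

    seqs = list(references)
    if include_reverse_complement:
        seqs += [reverse_complement(s) for s in references]
    for ref in seqs:
        if len(ref) < L:
            raise InputError(f"reference of length {len(ref)} shorter than window L={L}")
        enc = encode(ref).astype(np.int64)
        invalid = (enc == AMBIGUOUS_CODE).astype(np.int64)
        # bad[s] = number of ambiguous bases in window starting at s
        csum = np.concatenate([[0], np.cumsum(invalid)])
        starts = np.arange(0, len(ref) - L + 1, stride)
        bad = csum[starts + L] - csum[starts] > 0
        skipped += int(bad.sum())
        starts = starts[~bad]
        if sampling_fraction < 1:
            starts = starts[rng.random(len(starts)) < sampling_fraction]
        if len(starts) == 0:
            continue
        n_windows += len(starts)
        for offs in offsets:
            idx = np.zeros(len(starts), dtype=np.int64)
            for k, o in enumerate(offs):
                idx += enc[starts + o] * weights[k]
            counts += np.bincount(idx, minlength=4**r)
    total = int(counts.sum())
    if total == 0:
        raise InputError("no scoreable windows in the references")
    assert total == n_windows * n_subsets(L, r)
    return BackgroundModel(
        r=r,
        L=L,
        q=counts / total,
        total_count=total,
        source_label=source_label,
        skipped_windows=skipped,
    )


def background_information(bg: BackgroundModel, sequence: str) -> float:
    """Pre-binding information IS1 of a length-L window, in bits.

    IS1 = -(L / (C(L, r) * r)) * sum over subsets of log2 q(tuple).
    Returns +inf if any tuple has zero background probability.  Under a
    uniform background this equals 2L bits for every window.
    """
    if len(sequence) != bg.L:
        raise InputError(f"sequence length {len(sequence)} != window length {bg.L}")
    total = 0.0
    for subset in position_subsets(bg.L, bg.r):
        bases = "".join(sequence[p - 1] for p in subset)
        q = bg.prob(bases)
        if q <= 0:
            return math.inf
        total += math.log2(q)
    C = n_subsets(bg.L, bg.r)
    return -(bg.L / (C * bg.r)) * total
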
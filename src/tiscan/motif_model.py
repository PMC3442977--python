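"""Position-interdependent motif probability models.

A motif is learned from an alignment of known binding sites of one factor
(all sites the same length L after gap resolution).  Rather than assuming
the L columns independent, the model estimates, for every subset of r
distinct columns, the joint probability of the ordered base r-tuple read at
those columns.  The order-r information estimate of a candidate sequence is
the average sub-sequence information over all C(L, r) column subsets,
rescaled to the full length L:

    I_r(seq) = -(L / (r * C(L, r))) * sum over subsets of log2 p~(tuple)

With r=1 this reduces to the classic per-column (PWM) information under the
independence assumption; with r >= 2 the estimate responds to correlations
between columns.  For positively correlated motifs I_r decreases strictly
with r, for negatively correlated ones it increases, and for independent
columns all I_r coincide — which is the basis of the correlation
diagnostic below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .errors import InputError
from .sequence import BASES, encode, index_to_tuple, n_subsets, position_subsets, tuple_index

#: Subset orders above this require an explicit override; the cost of the
#: model grows as C(L, r) * 4**r and orders beyond 4 are rarely informative.
DEFAULT_MAX_R = 4

GapPolicy = Literal["drop-gapped-columns", "reject-if-gapped"]
GAP_CHARS = "-."

Tendency = Literal["positive", "negative", "independent", "mixed"]


@dataclass(frozen=True)
class MotifAlignment:
    """Equal-length, gap-free aligned binding sites of one factor.

    Positions are 1-based throughout the model domain.
    """

    factor_name: str
    sites: tuple[str, ...]
    site_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.sites:
            raise InputError("alignment has no sites")
        L = len(self.sites[0])
        if L < 2:
            raise InputError(f"motif length {L} < 2")
        for s in self.sites:
            if len(s) != L:
                raise InputError("aligned sites differ in length")
            if any(c not in BASES for c in s):
                raise InputError(f"non-ACGT character in site {s!r}")
        if not self.site_ids:
            object.__setattr__(
                self, "site_ids", tuple(f"site{i + 1}" for i in range(len(self.sites)))
            )
        elif len(self.site_ids) != len(self.sites):
            raise InputError("site_ids length does not match number of sites")

    @property
    def L(self) -> int:
        return len(self.sites[0])

    @property
    def N(self) -> int:
        return len(self.sites)

    def column(self, position: int) -> str:
        """The alignment column at a 1-based position."""
        if not 1 <= position <= self.L:
            raise InputError(f"position {position} outside [1, {self.L}]")
        return "".join(s[position - 1] for s in self.sites)

    def encoded(self) -> np.ndarray:
        """(N, L) uint8 matrix of base codes."""
        return np.vstack([encode(s) for s in self.sites])


def resolve_gaps(
    raw_alignment: Sequence[str],
    policy: GapPolicy = "drop-gapped-columns",
    factor_name: str = "motif",
    site_ids: Sequence[str] | None = None,
) -> MotifAlignment:
    """Turn a raw (possibly gapped) alignment into a gap-free MotifAlignment.

    ``drop-gapped-columns`` removes every column containing at least one gap
    character ('-' or '.'); ``reject-if-gapped`` raises on any gap.
    """
    if policy not in ("drop-gapped-columns", "reject-if-gapped"):
        raise InputError(f"unknown gap policy {policy!r}")
    rows = [r.upper() for r in raw_alignment]
    if not rows:
        raise InputError("empty alignment")
    L0 = len(rows[0])
    for r in rows:
        if len(r) != L0:
            raise InputError("raw alignment rows differ in length")
        for c in r:
            if c not in BASES and c not in GAP_CHARS:
                raise InputError(f"invalid character {c!r} in alignment row")
    gapped = [j for j in range(L0) if any(r[j] in GAP_CHARS for r in rows)]
    if gapped and policy == "reject-if-gapped":
        raise InputError(f"alignment contains gaps in columns {[j + 1 for j in gapped]}")
    keep = [j for j in range(L0) if j not in set(gapped)]
    if len(keep) < 2:
        raise InputError("fewer than 2 gap-free columns remain")
    sites = tuple("".join(r[j] for j in keep) for r in rows)
    return MotifAlignment(factor_name, sites, tuple(site_ids) if site_ids else ())


@dataclass
class MotifProbabilityModel:
    """p~ tables over (column subset, ordered base r-tuple).

    ``tables`` maps each strictly increasing r-tuple of 1-based positions to
    a length-4**r probability vector indexed by :func:`tuple_index`.  With
    pseudocount c the estimate for tuple t is (count(t) + c) / (N + c*4**r);
    c = 0 gives the plain empirical frequency, in which case tuples never
    seen in training have probability exactly 0 and score as unscorable
    (infinite-information sentinel) downstream.
    """

    factor_name: str
    L: int
    r: int
    N: int
    pseudocount: float
    tables: dict[tuple[int, ...], np.ndarray] = field(repr=False)

    def prob(self, subset: Iterable[int], bases: str) -> float:
        key = tuple(subset)
        if key not in self.tables:
            raise InputError(f"no table for position subset {key}")
        return float(self.tables[key][tuple_index(bases)])

    def subset_log2_prob(self, subset: Iterable[int], sequence: str) -> float:
        """log2 p~ of the tuple read from ``sequence`` at one subset (-inf if 0)."""
        key = tuple(subset)
        bases = "".join(sequence[p - 1] for p in key)
        p = self.prob(key, bases)
        return math.log2(p) if p > 0 else -math.inf

    def to_dict(self) -> dict:
        return {
            "schema": "tiscan-model-1",
            "kind": "motif",
            "factor": self.factor_name,
            "L": self.L,
            "r": self.r,
            "N": self.N,
            "pseudocount": self.pseudocount,
            "subsets": [
                {
                    "positions": list(key),
                    "probs": {
                        index_to_tuple(i, self.r): float(p)
                        for i, p in enumerate(table)
                    },
                }
                for key, table in sorted(self.tables.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MotifProbabilityModel":
        r = int(d["r"])
        tables = {}
        for entry in d["subsets"]:
            vec = np.zeros(4**r)
            for bases, p in entry["probs"].items():
                vec[tuple_index(bases)] = p
            tables[tuple(entry["positions"])] = vec
        return cls(
            factor_name=d["factor"],
            L=int(d["L"]),
            r=r,
            N=int(d["N"]),
            pseudocount=float(d["pseudocount"]),
            tables=tables,
        )


def _check_r(L: int, r: int, allow_high_r: bool) -> None:
    if r < 1:
        raise InputError(f"subset order r={r} must be >= 1")
    if r > L:
        raise InputError(f"subset order r={r} exceeds motif length L={L}")
    if r > DEFAULT_MAX_R and not allow_high_r:
        raise InputError(
            f"r={r} > {DEFAULT_MAX_R}; pass allow_high_r=True to override"
        )


def estimate_subset_probs(
    alignment: MotifAlignment,
    r: int,
    pseudocount: float = 0.0,
    allow_high_r: bool = False,
) -> MotifProbabilityModel:
    """Estimate the r-tuple probability tables from aligned known sites."""
    _check_r(alignment.L, r, allow_high_r)
    if pseudocount < 0:
        raise InputError("pseudocount must be nonnegative")
    enc = alignment.encoded().astype(np.int64)
    N = alignment.N
    denom = N + pseudocount * 4**r
    weights = 4 ** np.arange(r - 1, -1, -1, dtype=np.int64)
    tables: dict[tuple[int, ...], np.ndarray] = {}
    for subset in position_subsets(alignment.L, r):
        cols = enc[:, [p - 1 for p in subset]]
        idx = cols @ weights
        counts = np.bincount(idx, minlength=4**r).astype(float)
        tables[subset] = (counts + pseudocount) / denom
    return MotifProbabilityModel(
        factor_name=alignment.factor_name,
        L=alignment.L,
        r=r,
        N=N,
        pseudocount=pseudocount,
        tables=tables,
    )


def marginal_prob(model: MotifProbabilityModel, position: int, base: str) -> float:
    """Per-column base probability p_j(i).

    For an r=1 model this is a direct table lookup; for r >= 2 the first
    subset containing the position is marginalised over its other columns.
    The two routes agree exactly when pseudocount is 0.
    """
    if not 1 <= position <= model.L:
        raise InputError(f"position {position} outside [1, {model.L}]")
    code = BASES.find(base.upper())
    if code < 0:
        raise InputError(f"invalid base {base!r}")
    if model.r == 1:
        return float(model.tables[(position,)][code])
    for subset, table in sorted(model.tables.items()):
        if position in subset:
            axis = subset.index(position)
            cube = table.reshape((4,) * model.r)
            other = tuple(a for a in range(model.r) if a != axis)
            return float(cube.sum(axis=other)[code])
    raise InputError(f"no subset containing position {position}")  # pragma: no cover


def information_Ir(model: MotifProbabilityModel, sequence: str) -> float:
    """Order-r information estimate of a length-L sequence, in bits.

    Returns +inf when the sequence contains a base tuple that has zero
    probability under the model (unobserved in training, pseudocount 0).
    """
    if len(sequence) != model.L:
        raise InputError(
            f"sequence length {len(sequence)} != motif length {model.L}"
        )
    total = 0.0
    for subset in model.tables:
        lp = model.subset_log2_prob(subset, sequence)
        if lp == -math.inf:
            return math.inf
        total += lp
    C = n_subsets(model.L, model.r)
    return -(model.L / (model.r * C)) * total


def information_independent(model_r1: MotifProbabilityModel, sequence: str) -> float:
    """Information under the independence assumption (identical to I_1)."""
    if model_r1.r != 1:
        raise InputError("independent information requires an r=1 model")
    return information_Ir(model_r1, sequence)


def correlation_tendency(
    model_family: Sequence[MotifProbabilityModel],
    sequence: str,
    tol: float = 1e-6,
) -> Tendency:
    """Classify column correlation from the trend of I_r over r = 1..rmax.

    Strictly decreasing I_r means the bases the sequence reads are
    positively correlated (the independent estimate overstates the true
    information), strictly increasing means negatively correlated, all equal
    within ``tol`` bits means independent; anything else is ``mixed``.
    """
    if len(model_family) < 2:
        raise InputError("need models for at least r=1 and r=2")
    rs = [m.r for m in model_family]
    if rs != list(range(1, len(rs) + 1)):
        raise InputError(f"model family must cover r=1..rmax contiguously, got {rs}")
    values = [information_Ir(m, sequence) for m in model_family]
    if any(math.isinf(v) for v in values):
        raise InputError("infinite I_r; sequence contains an unobserved tuple")
    diffs = [b - a for a, b in zip(values, values[1:])]
    if all(d < -tol for d in diffs):
        return "positive"
    if all(d > tol for d in diffs):
        return "negative"
    if all(abs(d) <= tol for d in diffs):
        return "independent"
    return "mixed"
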
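"""Transferred-information scoring, thresholding and window scanning.

A factor binds a site only if enough information flows from the site to the
factor during binding.  The transferred information of an L-base window is

    TI_r = IS1 - IS2
         = (L / (r * C(L, r))) * sum over subsets of log2 [p~(tuple) / q(tuple)]

where IS1 is the window's information against the genome background and IS2
its information under the factor's motif model.  The acceptance threshold is
the minimum transferred information (MTI): the smallest TI_r over the known
training sites of the factor.  A window is called a hit when TI_r >= MTI
(inclusive).  Zero-probability tuples are mapped to sentinels rather than
exceptions: a zero motif probability rejects the window (TI = -inf), a zero
background probability with positive motif probability accepts it with a
warning (TI = +inf, the transferred information is unbounded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .background_model import BackgroundModel
from .errors import InputError, ModelMismatchError, UnscorableSiteError
from .motif_model import MotifAlignment, MotifProbabilityModel, estimate_subset_probs
from .sequence import AMBIGUOUS_CODE, encode, n_subsets, reverse_complement

Strands = Literal["both", "forward", "reverse"]
MergePolicy = Literal["greedy-local-max", "none"]


@dataclass(frozen=True)
class ScoredWindow:
    """One scored L-base window, 0-based half-open coordinates."""

    sequence_id: str
    start: int
    end: int
    strand: str
    is1: float
    is2: float
    ti: float
    is_hit: bool


@dataclass
class TrainedDetector:
    """Motif model + background model + MTI threshold for one factor."""

    motif: MotifProbabilityModel
    background: BackgroundModel
    mti: float
    training_site_ids: tuple[str, ...] = ()
    _tables: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.motif.r != self.background.r:
            raise ModelMismatchError(
                f"motif r={self.motif.r} != background r={self.background.r}"
            )
        if self.motif.L != self.background.L:
            raise ModelMismatchError(
                f"motif L={self.motif.L} != background L={self.background.L}"
            )

    @property
    def r(self) -> int:
        return self.motif.r

    @property
    def L(self) -> int:
        return self.motif.L

    @property
    def factor_name(self) -> str:
        return self.motif.factor_name

    def _scoring_tables(self):
        """Stacked log2 tables in subset iteration order, built lazily."""
        if not self._tables:
            subsets = sorted(self.motif.tables)
            offsets = np.array([[p - 1 for p in s] for s in subsets], dtype=np.int64)
            with np.errstate(divide="ignore"):
                logp = np.log2(np.vstack([self.motif.tables[s] for s in subsets]))
            self._tables = {
                "offsets": offsets,
                "logp": logp,
                "logq": self.background.log2q(),
                "weights": 4 ** np.arange(self.r - 1, -1, -1, dtype=np.int64),
                "factor": self.L / (self.r * n_subsets(self.L, self.r)),
            }
        return self._tables

    def score(self, window: str) -> tuple[float, float, float]:
        return ti_score(self, window)

    def to_dict(self) -> dict:
        return {
            "schema": "tiscan-model-1",
            "kind": "detector",
            "mti": self.mti,
            "training_site_ids": list(self.training_site_ids),
            "motif": self.motif.to_dict(),
            "background": self.background.to_dict(),
        }

    @classmethod
    def from_dict(cls, d) -> "TrainedDetector":
        return cls(
            motif=MotifProbabilityModel.from_dict(d["motif"]),
            background=BackgroundModel.from_dict(d["background"]),
            mti=float(d["mti"]),
            training_site_ids=tuple(d.get("training_site_ids", ())),
        )


def _window_sums(detector: TrainedDetector, enc: np.ndarray, starts: np.ndarray):
    """Sums of log2 p~ and log2 q over all subsets for each window start."""
    t = detector._scoring_tables()
    sp = np.zeros(len(starts))
    sq = np.zeros(len(starts))
    with np.errstate(invalid="ignore"):
        for si, offs in enumerate(t["offsets"]):
            idx = np.zeros(len(starts), dtype=np.int64)
            for k, o in enumerate(offs):
                idx += enc[starts + o] * t["weights"][k]
            sp += t["logp"][si, idx]
            sq += t["logq"][idx]
    return sp, sq, t["factor"]


def _sentinel_scores(sp: float, sq: float, factor: float) -> tuple[float, float, float]:
    is2 = math.inf if sp == -math.inf else -factor * sp
    is1 = math.inf if sq == -math.inf else -factor * sq
    if sp == -math.inf:
        ti = -math.inf  # unobserved motif tuple: reject
    elif sq == -math.inf:
        ti = math.inf  # undertrained background: accept with warning
    else:
        ti = factor * (sp - sq)
    return is1, is2, ti


def ti_score(detector: TrainedDetector, window: str) -> tuple[float, float, float]:
    """(IS1, IS2, TI) in bits for one L-base ACGT window."""
    if len(window) != detector.L:
        raise InputError(
            f"window length {len(window)} != detector L={detector.L}"
        )
    enc = encode(window, strict=True).astype(np.int64)
    sp, sq, factor = _window_sums(detector, enc, np.array([0]))
    is1, is2, ti = _sentinel_scores(float(sp[0]), float(sq[0]), factor)
    if ti == math.inf:
        warnings.warn(
            "window contains a tuple with zero background probability; "
            "TI is unbounded (+inf)",
            RuntimeWarning,
            stacklevel=2,
        )
    return is1, is2, ti


def compute_mti(
    motif: MotifProbabilityModel,
    background: BackgroundModel,
    training_sites: Sequence[str],
) -> float:
    """Minimum transferred information over the training sites (the threshold)."""
    if not training_sites:
        raise InputError("no training sites")
    detector = TrainedDetector(motif, background, mti=-math.inf)
    tis = []
    for site in training_sites:
        _, _, ti = ti_score(detector, site)
        if math.isinf(ti):
            raise UnscorableSiteError(
                f"training site {site!r} has infinite TI "
                "(zero motif or background tuple probability)"
            )
        tis.append(ti)
    return min(tis)


def split_training(
    alignment: MotifAlignment, fraction: float, seed: int | None = None
) -> tuple[MotifAlignment, tuple[str, ...]]:
    """Seeded random training subset of the known sites.

    Keeps floor(fraction * N) sites, at least 1; returns the training
    alignment and the held-out site ids.
    """
    if not 0 < fraction <= 1:
        raise InputError("training fraction must be in (0, 1]")
    if fraction == 1.0:
        return alignment, ()
    n_train = max(1, int(fraction * alignment.N))
    rng = np.random.default_rng(seed)
    order = rng.permutation(alignment.N)
    chosen = sorted(order[:n_train])
    held = sorted(order[n_train:])
    train = MotifAlignment(
        alignment.factor_name,
        tuple(alignment.sites[i] for i in chosen),
        tuple(alignment.site_ids[i] for i in chosen),
    )
    return train, tuple(alignment.site_ids[i] for i in held)


def train_detector(
    alignment: MotifAlignment,
    background: BackgroundModel,
    r: int,
    pseudocount: float = 0.0,
    training_fraction: float = 1.0,
    seed: int | None = None,
    allow_high_r: bool = False,
) -> tuple[TrainedDetector, tuple[str, ...]]:
    """Estimate the motif model on a training split and derive the MTI.

    Returns the detector and the held-out site ids (empty at fraction 1.0).
    By construction every training site satisfies TI >= MTI, so rescanning
    the training material yields no false negatives.
    """
    if alignment.L != background.L:
        raise ModelMismatchError(
            f"alignment L={alignment.L} != background L={background.L}"
        )
    train, held_out = split_training(alignment, training_fraction, seed)
    motif = estimate_subset_probs(train, r, pseudocount, allow_high_r)
    mti = compute_mti(motif, background, train.sites)
    detector = TrainedDetector(
        motif, background, mti=mti, training_site_ids=train.site_ids
    )
    return detector, held_out


def scan(
    detector: TrainedDetector,
    query: str,
    sequence_id: str = "query",
    strands: Strands = "both",
) -> list[ScoredWindow]:
    """Score every L-base window of ``query`` on the requested strands.

    Reverse-strand windows are scored on the reverse complement and reported
    in forward coordinates with strand '-'.  Windows containing non-ACGT
    characters are skipped.  Output is ordered by (start, strand).
    """
    L = detector.L
    n = len(query)
    if n < L:
        raise InputError(f"query length {n} < motif length {L}")
    if strands not in ("both", "forward", "reverse"):
        raise InputError(f"unknown strands option {strands!r}")
    out: list[ScoredWindow] = []

    def _one_strand(seq: str, strand: str) -> None:
        enc = encode(seq).astype(np.int64)
        invalid = (enc == AMBIGUOUS_CODE).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(invalid)])
        starts = np.arange(0, n - L + 1)
        starts = starts[csum[starts + L] - csum[starts] == 0]
        if len(starts) == 0:
            return
        sp, sq, factor = _window_sums(detector, enc, starts)
        for s, vp, vq in zip(starts, sp, sq):
            is1, is2, ti = _sentinel_scores(float(vp), float(vq), factor)
            if strand == "+":
                fwd_start = int(s)
            else:
                fwd_start = n - L - int(s)
            out.append(
                ScoredWindow(
                    sequence_id=sequence_id,
                    start=fwd_start,
                    end=fwd_start + L,
                    strand=strand,
                    is1=is1,
                    is2=is2,
                    ti=ti,
                    is_hit=bool(ti >= detector.mti),
                )
            )

    if strands in ("both", "forward"):
        _one_strand(query, "+")
    if strands in ("both", "reverse"):
        _one_strand(reverse_complement(query), "-")
    out.sort(key=lambda w: (w.sequence_id, w.start, w.strand))
    return out


def merge_hits(
    windows: Sequence[ScoredWindow], policy: MergePolicy = "greedy-local-max"
) -> list[ScoredWindow]:
    """Collapse overlapping hit windows into representative hits.

    ``greedy-local-max`` clusters transitively overlapping hit windows on
    the same (sequence, strand) and keeps the maximal-TI window of each
    cluster (ties broken leftmost); ``none`` passes hits through unchanged.
    """
    hits = [w for w in windows if w.is_hit]
    if policy == "none":
        return sorted(hits, key=lambda w: (w.sequence_id, w.start, w.strand))
    if policy != "greedy-local-max":
        raise InputError(f"unknown merge policy {policy!r}")
    merged: list[ScoredWindow] = []
    groups: dict[tuple[str, str], list[ScoredWindow]] = {}
    for w in hits:
        groups.setdefault((w.sequence_id, w.strand), []).append(w)
    for key in sorted(groups):
        ws = sorted(groups[key], key=lambda w: w.start)
        cluster: list[ScoredWindow] = []
        cluster_end = -1
        for w in ws:
            if cluster and w.start >= cluster_end:
                merged.append(_cluster_max(cluster))
                cluster = []
            cluster.append(w)
            cluster_end = max(cluster_end, w.end)
        if cluster:
            merged.append(_cluster_max(cluster))
    merged.sort(key=lambda w: (w.sequence_id, w.start, w.strand))
    return merged


def _cluster_max(cluster: list[ScoredWindow]) -> ScoredWindow:
    best = cluster[0]
    for w in cluster[1:]:
        if w.ti > best.ti:
            best = w
    return best
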
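"""Site-level performance metrics for motif predictions.

Predicted sites are matched one-to-one against known (ground-truth) sites
by interval overlap; from the matching the module reports the false
positive rate FP = (|P| - TP) / |P|, the false negative rate
FN = (|K| - TP) / |K|, the site-level Jaccard index
perf = |K ∩ P| / |K ∪ P| = TP / (|P| + |K| - TP), and the prediction ratio
PT/RT = |P| / |K|.

The overlap criterion is configurable: a predicted interval may match a
known site when their overlap is at least ``overlap_threshold`` times the
known site's length (default 0.5).  Matching is strand-agnostic by default
because genuine sites produce signal on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import InputError


@dataclass(frozen=True)
class SiteInterval:
    """A genomic interval, 0-based half-open, with factor label and strand."""

    sequence_id: str
    start: int
    end: int
    factor: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InputError(
                f"malformed interval [{self.start}, {self.end}) on {self.sequence_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "SiteInterval") -> int:
        if self.sequence_id != other.sequence_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class EvaluationReport:
    """Site-level FP/FN/perf/PT-RT summary of one prediction set."""

    n_predicted: int
    n_known: int
    tp: int
    fp_rate: float
    fn_rate: float
    perf: float
    pt_rt: float
    empty_prediction: bool = False
    matching_policy: dict = field(default_factory=dict)
    per_factor: dict[str, "EvaluationReport"] = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_known": self.n_known,
            "tp": self.tp,
            "fp": self.fp_rate,
            "fn": self.fn_rate,
            "perf": self.perf,
            "pt_rt": self.pt_rt,
            "empty_prediction": self.empty_prediction,
        }


def match_sites(
    predicted: Sequence[SiteInterval],
    known: Sequence[SiteInterval],
    overlap_threshold: float = 0.5,
    strand_aware: bool = False,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of predicted to known sites.

    Candidate pairs are those whose overlap is at least
    ``overlap_threshold`` times the known site's length; pairs are accepted
    in order of decreasing overlap (ties broken by position), each site
    participating in at most one match.  Returns (predicted_idx, known_idx)
    pairs.
    """
    if not 0 < overlap_threshold <= 1:
        raise InputError("overlap_threshold must be in (0, 1]")
    candidates: list[tuple[int, int, int]] = []
    for pi, p in enumerate(predicted):
        for ki, k in enumerate(known):
            if strand_aware and p.strand != k.strand:
                continue
            ov = p.overlap(k)
            if ov >= overlap_threshold * k.length:
                candidates.append((ov, pi, ki))
    candidates.sort(key=lambda c: (-c[0], predicted[c[1]].start, known[c[2]].start, c[1], c[2]))
    matched_p: set[int] = set()
    matched_k: set[int] = set()
    matching: list[tuple[int, int]] = []
    for _, pi, ki in candidates:
        if pi in matched_p or ki in matched_k:
            continue
        matched_p.add(pi)
        matched_k.add(ki)
        matching.append((pi, ki))
    matching.sort()
    return matching


def evaluate(
    matching: Sequence[tuple[int, int]],
    n_predicted: int,
    n_known: int,
    matching_policy: dict | None = None,
) -> EvaluationReport:
    """Turn a one-to-one matching into the FP/FN/perf/PT-RT report."""
    if n_known == 0:
        raise InputError("no known sites; rates are undefined")
    tp = len(matching)
    if tp > min(n_predicted, n_known):
        raise InputError("matching larger than either site set")
    empty = n_predicted == 0
    fp = 0.0 if empty else (n_predicted - tp) / n_predicted
    fn = (n_known - tp) / n_known
    perf = tp / (n_predicted + n_known - tp)
    return EvaluationReport(
        n_predicted=n_predicted,
        n_known=n_known,
        tp=tp,
        fp_rate=fp,
        fn_rate=fn,
        perf=perf,
        pt_rt=n_predicted / n_known,
        empty_prediction=empty,
        matching_policy=dict(matching_policy or {}),
    )


def evaluate_predictions(
    predicted: Sequence[SiteInterval],
    known: Sequence[SiteInterval],
    overlap_threshold: float = 0.5,
    strand_aware: bool = False,
) -> EvaluationReport:
    """Match and evaluate, overall and per factor.

    Per-factor reports partition both sets by their factor label; the
    overall report matches within factor (a prediction labelled with one
    factor never counts for another) and pools the counts.
    """
    policy = {
        "overlap_threshold": overlap_threshold,
        "strand_aware": strand_aware,
        "matching": "greedy one-to-one by descending overlap",
    }
    factors = sorted(
        {s.factor for s in predicted} | {s.factor for s in known}
    )
    per_factor: dict[str, EvaluationReport] = {}
    total_tp = 0
    for f in factors:
        p_f = [s for s in predicted if s.factor == f]
        k_f = [s for s in known if s.factor == f]
        if not k_f:
            continue  # predictions with no known counterpart count below
        m = match_sites(p_f, k_f, overlap_threshold, strand_aware)
        per_factor[f] = evaluate(m, len(p_f), len(k_f), policy)
        total_tp += len(m)
    if not per_factor:
        raise InputError("no known sites; rates are undefined")
    report = evaluate(
        [(i, i) for i in range(total_tp)], len(predicted), len(known), policy
    )
    report.per_factor = per_factor
    return report
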
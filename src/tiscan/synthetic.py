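"""Synthetic test material with recorded ground truth.

Generates the artificial evaluation sets the scanner is benchmarked on:
random background sequences matched to a target GC content, each harbouring
a uniform-random 0-3 occurrences of each motif, with sites sampled
independently per column from a position weight matrix (PWM) and embedded
at non-overlapping positions.  Because PWM-sampled pseudo-sites carry no
column-column correlation, they exercise exactly the regime where the
independent (r=1) detector accepts and higher-r detectors become selective.

Also provides deterministic fixtures: a constraint-driven alignment builder
for correlated-column worked examples, and three demo factor site sets
(gcn4-, gal4- and mcb-like yeast motifs) with the degenerate outlier sites
typical of curated collections.

PWMs are (4, L) arrays with rows A, C, G, T and columns summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .motif_model import MotifAlignment
from .sequence import BASES, reverse_complement

#: Conventional GC fraction for S. cerevisiae-like background sequences.
DEFAULT_GC = 0.38


@dataclass(frozen=True)
class TruthSite:
    """Ground-truth record of one embedded site (0-based, half-open)."""

    sequence_id: str
    start: int
    end: int
    factor: str
    strand: str
    site: str  # the site string as sampled (forward orientation)


@dataclass
class SyntheticSet:
    """A generated sequence set plus its ground truth."""

    sequences: dict[str, str]
    truth: list[TruthSite]
    gc_content: float
    seed: int | None
    motif_pwms: dict[str, np.ndarray] = field(default_factory=dict)

    def truth_for(self, factor: str) -> list[TruthSite]:
        return [t for t in self.truth if t.factor == factor]


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_background_sequence(
    length: int,
    gc_content: float,
    rng: int | np.random.Generator | None = None,
    allow_degenerate: bool = False,
) -> str:
    """i.i.d. random DNA with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length <= 0:
        raise InputError("length must be positive")
    lo, hi = (0.0, 1.0) if allow_degenerate else (np.nextafter(0, 1), np.nextafter(1, 0))
    if not lo <= gc_content <= hi:
        raise InputError(f"gc_content {gc_content} outside (0, 1)")
    rng = _as_rng(rng)
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    codes = rng.choice(4, size=length, p=p)
    return "".join(BASES[c] for c in codes)


def validate_pwm(pwm: np.ndarray) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4 or pwm.shape[1] < 1:
        raise InputError(f"PWM must be a 4xL matrix, got shape {pwm.shape}")
    if (pwm < 0).any() or not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise InputError("PWM columns must be nonnegative and sum to 1")
    return pwm


def sample_site_from_pwm(
    pwm: np.ndarray, rng: int | np.random.Generator | None = None
) -> str:
    """Sample one site, each position independently from its PWM column."""
    pwm = validate_pwm(pwm)
    rng = _as_rng(rng)
    L = pwm.shape[1]
    return "".join(
        BASES[rng.choice(4, p=pwm[:, j] / pwm[:, j].sum())] for j in range(L)
    )


def pwm_from_alignment(alignment: MotifAlignment, pseudocount: float = 0.0) -> np.ndarray:
    """Column base frequencies of an alignment as a (4, L) PWM."""
    enc = alignment.encoded()
    pwm = np.zeros((4, alignment.L))
    for j in range(alignment.L):
        counts = np.bincount(enc[:, j], minlength=4).astype(float)
        pwm[:, j] = (counts + pseudocount) / (alignment.N + 4 * pseudocount)
    return pwm


def build_test_set(
    n_sequences: int,
    sequence_length: int,
    factors: Mapping[str, np.ndarray],
    gc_content: float = DEFAULT_GC,
    seed: int | None = None,
    strands: str = "forward",
    max_sites_per_factor: int = 3,
    max_placement_tries: int = 200,
) -> SyntheticSet:
    """Generate random sequences with 0-3 embedded sites per factor each.

    For every (sequence, factor) pair the occurrence count is uniform on
    {0, .., max_sites_per_factor}; sites are sampled from the factor's PWM
    and placed uniformly among positions that do not overlap previously
    placed sites.  With ``strands="both"`` each site's strand is drawn
    uniformly and minus-strand sites are embedded as reverse complements;
    the default embeds on the forward strand only.
    """
    if n_sequences < 1:
        raise InputError("need at least one sequence")
    if strands not in ("forward", "both"):
        raise InputError(f"unknown strands option {strands!r}")
    pwms = {name: validate_pwm(p) for name, p in factors.items()}
    rng = _as_rng(seed)
    sequences: dict[str, str] = {}
    truth: list[TruthSite] = []
    for i in range(n_sequences):
        seq_id = f"synth{i + 1}"
        seq = list(
            generate_background_sequence(sequence_length, gc_content, rng)
        )
        occupied: list[tuple[int, int]] = []
        for name in pwms:  # insertion order: deterministic
            pwm = pwms[name]
            L = pwm.shape[1]
            if L > sequence_length:
                raise InputError(
                    f"motif {name} (L={L}) longer than sequence ({sequence_length})"
                )
            count = int(rng.integers(0, max_sites_per_factor + 1))
            for _ in range(count):
                site = sample_site_from_pwm(pwm, rng)
                strand = "+"
                if strands == "both" and rng.integers(0, 2) == 1:
                    strand = "-"
                placed = False
                for _try in range(max_placement_tries):
                    start = int(rng.integers(0, sequence_length - L + 1))
                    if all(
                        start + L <= s or start >= e for s, e in occupied
                    ):
                        placed = True
                        break
                if not placed:
                    raise InputError(
                        f"could not place a {name} site without overlap in "
                        f"{seq_id} after {max_placement_tries} tries"
                    )
                embedded = site if strand == "+" else reverse_complement(site)
                seq[start : start + L] = embedded
                occupied.append((start, start + L))
                truth.append(
                    TruthSite(seq_id, start, start + L, name, strand, site)
                )
        sequences[seq_id] = "".join(seq)
    truth.sort(key=lambda t: (t.sequence_id, t.start, t.factor))
    return SyntheticSet(
        sequences=sequences,
        truth=truth,
        gc_content=gc_content,
        seed=seed if isinstance(seed, int) else None,
        motif_pwms=dict(pwms),
    )


def make_correlated_fixture(
    columns: Mapping[int, str],
    factor_name: str = "fixture",
    length: int | None = None,
    fill_base: str = "A",
) -> MotifAlignment:
    """Deterministic alignment from per-column base constraints.

    ``columns`` maps a 1-based position to the column string (one base per
    site, top to bottom).  All given columns must have the same number of
    sites; unconstrained columns are filled with ``fill_base``.  Raises if
    the constraints are inconsistent (unequal column heights, positions out
    of range, non-ACGT bases).
    """
    if not columns:
        raise InputError("no column constraints given")
    heights = {len(c) for c in columns.values()}
    if len(heights) != 1:
        raise InputError(f"inconsistent column heights {sorted(heights)}")
    n_sites = heights.pop()
    if n_sites < 1:
        raise InputError("columns are empty")
    L = length if length is not None else max(columns)
    if L < max(columns) or min(columns) < 1:
        raise InputError("column positions outside [1, L]")
    if fill_base not in BASES:
        raise InputError(f"fill base {fill_base!r} not in {BASES}")
    for pos, col in columns.items():
        if any(b not in BASES for b in col):
            raise InputError(f"non-ACGT base in column {pos}: {col!r}")
    sites = tuple(
        "".join(
            columns[j][i] if j in columns else fill_base for j in range(1, L + 1)
        )
        for i in range(n_sites)
    )
    return MotifAlignment(factor_name, sites)


def figure2_alignment() -> MotifAlignment:
    """Eight rox1-like sites with the classic correlated-column structure.

    Column 1 is half C, half T; column 11 is three-quarters T; every
    C-at-1 site carries T-at-11 (so the pair probability of (C, T) at
    positions (1, 11) is 0.5, well above the 0.375 product of marginals,
    i.e. positively correlated), while exactly two T-at-1 sites carry
    T-at-11 (pair probability 0.25 below the 0.375 product: negatively
    correlated).  Columns 4 and 6 are identical, a fully positively
    correlated pair.
    """
    return make_correlated_fixture(
        {
            1: "CCCCTTTT",
            2: "TTCTTCTT",
            3: "AAAGAAAA",
            4: "AATAATAT",
            5: "TTTTTTTC",
            6: "AATAATAT",
            7: "GGGGGGGG",
            8: "TTTTTTTT",
            9: "TTTTTTTT",
            10: "GGAGGGGG",
            11: "TTTTTTAC",
            12: "ACAAAGAA",
        },
        factor_name="rox1",
    )


def alignment_from_counts(
    site_counts: Mapping[str, int], factor_name: str = "fixture"
) -> MotifAlignment:
    """Alignment holding each site string a given number of times.

    Convenient for constructing alignments with exact joint-count structure
    (e.g. anti-correlated columns where a tuple is rarer than the product of
    its marginals would predict).
    """
    sites: list[str] = []
    for s in site_counts:
        if site_counts[s] < 0:
            raise InputError("negative site count")
        sites.extend([s] * site_counts[s])
    return MotifAlignment(factor_name, tuple(sites))


# --- demo factor site sets ---------------------------------------------------
#
# Hand-curated yeast-like site collections. Each includes a small number of
# degenerate sites, as curated TFBS collections do; the weakest site sets a
# permissive MTI, mirroring how experimentally mapped sites behave.

_DEMO_SITES: dict[str, tuple[str, ...]] = {
    # TGACTCA-core bZIP-type motif, padded context, L=10
    "gcn4": (
        "ATGACTCATC", "ATGACTCATC", "ATGACTCATC", "ATGACTCATC",
        "ATGACTCATC", "ATGACTCATC", "ATGACTCATC", "ATGACTCATC",
        "ATGACTCATT", "ATGACTCATA", "ATGAGTCATC", "ATGACTCTTC",
        "TTGACTCATC", "AAGACTCATC", "ATGATTCATC", "ATGACTAATC",
        "ATGACCCATC", "GTGACTCATC", "ATAACTCATG", "TAGAATCTAG",
    ),
    # CGG-N11-CCG zinc-cluster motif with a near-random spacer, L=17
    "gal4": (
        "CGGAGGACTGTTATCCG",
        "CGGTCTATCCGTTTCCG",
        "CGGACAACTGTCATCCG",
        "CGGCGGATTAGAAGCCG",
        "CGGAATTCCGTAGTCCG",
        "CGGTGACAGTCTTACCG",
        "CGGCCTATACAGATCCG",
        "CGGATGTCTGAATACCG",
        "CAGACTACTCGTATCCG",
    ),
    # ACGCGT MluI-box cell-cycle motif, padded, L=8
    "mcb": (
        "AACGCGTA", "AACGCGTA", "AACGCGTA", "AACGCGTA",
        "AACGCGTA", "AACGCGTA", "AACGCGTA", "AACGCGTT",
        "TACGCGTA", "AACGCGAA", "ATCGCGTA", "CACGCGTA",
        "AACGCGTG", "GACGCGTA", "AACACGTA", "TTCGCGAT",
    ),
}


def demo_factor_alignments() -> dict[str, MotifAlignment]:
    """Three built-in factor site sets for simulation and demonstration."""
    return {
        name: MotifAlignment(name, sites) for name, sites in _DEMO_SITES.items()
    }
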
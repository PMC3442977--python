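"""Readers and writers for the package's interchange formats.

FASTA for sequences and aligned sites, BED6 for hits and ground truth, TSV
for spectra and evaluation reports, JSON for models.  JSON outputs are
written with sorted keys so that identical inputs give byte-identical
files; tabular outputs carry '#'-prefixed provenance header lines which all
readers here skip.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .background_model import BackgroundModel
from .errors import InputError
from .evaluation import EvaluationReport, SiteInterval
from .motif_model import GapPolicy, MotifAlignment, MotifProbabilityModel, resolve_gaps
from .scanner import ScoredWindow, TrainedDetector
from .sequence import BASES
from .synthetic import TruthSite


def config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def provenance(config: Mapping, seed: int | None = None) -> dict:
    return {
        "tool": f"tiscan {__version__}",
        "config_hash": config_hash(config),
        "seed": seed,
    }


def provenance_lines(config: Mapping, seed: int | None = None) -> list[str]:
    p = provenance(config, seed)
    return [f"# {p['tool']} config={p['config_hash']} seed={p['seed']}"]


# --- FASTA -------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_alignment_fasta(
    path: str | Path,
    gap_policy: GapPolicy = "drop-gapped-columns",
    factor_name: str | None = None,
) -> MotifAlignment:
    """Aligned known sites from FASTA; rows must be equal length."""
    records = read_fasta(path)
    name = factor_name if factor_name else Path(path).stem
    return resolve_gaps(
        list(records.values()), gap_policy, factor_name=name,
        site_ids=list(records.keys()),
    )


# --- models (JSON) -----------------------------------------------------------

_KINDS = {
    "motif": MotifProbabilityModel,
    "background": BackgroundModel,
    "detector": TrainedDetector,
}


def save_model(model, path: str | Path, extra: Mapping | None = None) -> None:
    d = model.to_dict()
    if extra:
        d["provenance"] = dict(extra)
    Path(path).write_text(json.dumps(d, sort_keys=True, indent=1) + "\n")


def load_model(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise InputError(f"model file not found: {path}")
    try:
        d = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise InputError(f"invalid model JSON in {path}: {e}") from e
    kind = d.get("kind")
    if kind not in _KINDS:
        raise InputError(f"unknown model kind {kind!r} in {path}")
    return _KINDS[kind].from_dict(d)


# --- BED6 --------------------------------------------------------------------

def _bed_score(ti: float) -> int:
    """TI in bits scaled by 50 and clamped to the BED score range 0-1000."""
    if math.isinf(ti):
        return 1000 if ti > 0 else 0
    return int(max(0, min(1000, round(50 * ti))))


def write_hits_bed(
    path: str | Path,
    hits: Sequence[ScoredWindow],
    factor: str,
    header: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for w in hits:
            fh.write(
                f"{w.sequence_id}\t{w.start}\t{w.end}\t{factor}\t"
                f"{_bed_score(w.ti)}\t{w.strand}\n"
            )


def write_truth_bed(
    path: str | Path, truth: Sequence[TruthSite], header: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        for t in truth:
            fh.write(
                f"{t.sequence_id}\t{t.start}\t{t.end}\t{t.factor}\t0\t{t.strand}\n"
            )


def read_bed(path: str | Path) -> list[SiteInterval]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"BED file not found: {path}")
    out: list[SiteInterval] = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}:{ln}: BED line has fewer than 3 fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as e:
            raise InputError(f"{path}:{ln}: non-integer BED coordinates") from e
        out.append(
            SiteInterval(
                sequence_id=fields[0],
                start=start,
                end=end,
                factor=fields[3] if len(fields) > 3 else "",
                strand=fields[5] if len(fields) > 5 else "+",
            )
        )
    return out


# --- spectrum TSV ------------------------------------------------------------

SPECTRUM_COLUMNS = ["sequence_id", "start", "strand", "is1", "is2", "ti", "is_hit"]


def write_spectrum_tsv(
    path: str | Path, windows: Sequence[ScoredWindow], header: Sequence[str] = ()
) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "sequence_id": w.sequence_id,
                "start": w.start,
                "strand": w.strand,
                "is1": w.is1,
                "is2": w.is2,
                "ti": w.ti,
                "is_hit": w.is_hit,
            }
            for w in windows
        ],
        columns=SPECTRUM_COLUMNS,
    )
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_spectrum_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


# --- evaluation report -------------------------------------------------------

def write_report(
    path: str | Path, report: EvaluationReport, header: Sequence[str] = ()
) -> None:
    """TSV with one row per factor plus an 'overall' row."""
    import pandas as pd

    rows = []
    for name, rep in sorted(report.per_factor.items()):
        rows.append({"factor": name, **rep.to_row()})
    rows.append({"factor": "overall", **report.to_row()})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        for line in header:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def report_to_json(report: EvaluationReport) -> dict:
    d = report.to_row()
    d["matching_policy"] = report.matching_policy
    d["per_factor"] = {k: v.to_row() for k, v in sorted(report.per_factor.items())}
    return d


# --- PWMs --------------------------------------------------------------------

def read_pwm_tsv(path: str | Path) -> np.ndarray:
    """4-row tab-separated PWM, rows labelled A/C/G/T in any order.

    Accepts counts or frequencies; columns are normalised to sum to 1.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"PWM file not found: {path}")
    rows: dict[str, list[float]] = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        base = fields[0].strip().upper()
        if base not in BASES:
            raise InputError(f"PWM row label {fields[0]!r} is not a base")
        rows[base] = [float(x) for x in fields[1:]]
    if sorted(rows) != sorted(BASES):
        raise InputError(f"PWM must have exactly rows A, C, G, T; got {sorted(rows)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise InputError("PWM rows have unequal lengths")
    mat = np.array([rows[b] for b in BASES], dtype=float)
    sums = mat.sum(axis=0)
    if (sums <= 0).any():
        raise InputError("PWM column sums to zero")
    return mat / sums


def read_jaspar_pwms(path: str | Path) -> dict[str, np.ndarray]:
    """All motifs in a JASPAR-format count-matrix file, as normalised PWMs."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"JASPAR file not found: {path}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out: dict[str, np.ndarray] = {}
    for m in parsed:
        mat = np.array([m.counts[b] for b in BASES], dtype=float)
        out[m.name or m.matrix_id] = mat / mat.sum(axis=0)
    if not out:
        raise InputError(f"no motifs in {path}")
    return out
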
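"""Gene-family recruitment: profile scoring of proteins and search import.

Candidate family members are recruited from the database's protein records
with an ungapped position-specific log-odds scorer built from a seed
alignment.  This intentionally replaces a full profile HMM (match/insert/
delete states, Viterbi): family search is an off-the-shelf step in this
pipeline, and results from a real HMMER3 run can be imported from
``--domtblout`` output instead whenever full-fidelity search is required.

Column log-odds (bits) with pseudocount ``c`` and background ``q``:

    s_col(a) = log2( (n_col(a) + c*q(a)) / (n_col + c) / q(a) )

A query scores the maximum over ungapped placements of the summed column
log-odds (leftmost placement wins ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio_db import MotherDB, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA20)}


@dataclass
class SeedAlignment:
    """A family's seed multiple alignment ('-' gaps, equal-length rows)."""

    family: str
    rows: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("seed alignment needs at least two rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("aligned rows must have equal length")
        if not any(all(r[i] != "-" for r in self.rows) for i in range(len(self.rows[0]))):
            raise ValueError("alignment has no ungapped column")
        self.rows = [r.upper() for r in self.rows]


def read_seed_alignment(path: str | Path, family: str | None = None) -> SeedAlignment:
    """Read an aligned FASTA into a :class:`SeedAlignment`."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return SeedAlignment(family or Path(path).stem, rows, ids)


@dataclass
class ProfileModel:
    """Per-column amino-acid log-odds (bits) over the 20-letter alphabet."""

    family: str
    columns: np.ndarray  # (n_columns, 20) bits
    pseudocount: float
    background: np.ndarray  # (20,) probabilities

    def __len__(self) -> int:
        return len(self.columns)


@dataclass
class RecruitHit:
    family: str
    sequence_id: str
    score: float  # bits
    threshold_passed: bool


def build_profile(
    aln: SeedAlignment,
    pseudocount: float = 1.0,
    gap_col_max: float = 0.5,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Build the log-odds profile from a seed alignment.

    Columns whose gap fraction exceeds ``gap_col_max`` are dropped.  The
    pseudocount is the *total* prior weight per column, distributed over
    letters by the background (uniform 1/20 by default).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not 0 <= gap_col_max < 1:
        raise ValueError("gap_col_max must be in [0, 1)")
    bg = np.full(20, 1.0 / 20) if background is None else np.asarray(background, float)
    ncol = len(aln.rows[0])
    cols = []
    for j in range(ncol):
        letters = [r[j] for r in aln.rows]
        gap_frac = letters.count("-") / len(letters)
        if gap_frac > gap_col_max:
            continue
        counts = np.zeros(20)
        for a in letters:
            if a in _AA_IDX:
                counts[_AA_IDX[a]] += 1
        n = counts.sum()
        freq = (counts + pseudocount * bg) / (n + pseudocount)
        cols.append(np.log2(freq / bg))
    if not cols:
        raise ValueError("all alignment columns were gap-dropped")
    return ProfileModel(aln.family, np.array(cols), pseudocount, bg)


def score_sequence(model: ProfileModel, seq: str) -> float:
    """Best ungapped placement score of ``seq`` against the profile, in bits.

    Deterministic; ties between placements resolve to the leftmost (the
    maximum is unaffected).  Letters outside the 20-letter alphabet (X, *)
    score 0 at their column.
    """
    L = len(model)
    if len(seq) < L:
        raise ValueError(f"sequence length {len(seq)} < model length {L}")
    idx = np.array([_AA_IDX.get(a, -1) for a in seq.upper()])
    n_place = len(seq) - L + 1
    cols = model.columns
    best = -math.inf
    col_range = np.arange(L)
    for p in range(n_place):
        window = idx[p : p + L]
        valid = window >= 0
        s = cols[col_range[valid], window[valid]].sum()
        if s > best:
            best = s
    return float(best)


def self_score_threshold(model: ProfileModel, aln: SeedAlignment, fraction: float = 0.6) -> float:
    """Default recruitment threshold: ``fraction`` × the minimum self-score
    of the (degapped) seed rows."""
    selfs = [score_sequence(model, r.replace("-", "")) for r in aln.rows]
    return fraction * min(selfs)


def recruit(
    db: MotherDB | Iterable[SequenceRecord],
    model: ProfileModel,
    threshold: float,
) -> list[RecruitHit]:
    """Score every protein record against the profile.

    Hits are sorted by score descending; only ``threshold_passed`` members
    should enter probe design.  An empty database yields an empty list.
    """
    if isinstance(db, MotherDB):
        proteins: Iterable[SequenceRecord] = db.proteins.values()
    else:
        proteins = db
    hits = []
    for rec in proteins:
        if len(rec.seq) < len(model):
            continue
        s = score_sequence(model, rec.seq)
        hits.append(RecruitHit(model.family, rec.id, s, s >= threshold))
    hits.sort(key=lambda h: (-h.score, h.sequence_id))
    return hits


# ---------------------------------------------------------------------------
# HMMER3 --domtblout import
# ---------------------------------------------------------------------------

def read_domtblout(path: str | Path, evalue_max: float = 1e-3) -> list[RecruitHit]:
    """Import HMMER3 ``--domtblout`` per-domain hits.

    Keeps the best (lowest independent E-value) domain per
    (query family, target sequence) pair; ``threshold_passed`` means the
    independent E-value is at most ``evalue_max``.  The hit score is the
    domain bit score.  Comment lines ('#') are ignored; a malformed data
    line is a hard error naming the line number.
    """
    best: dict[tuple[str, str], tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 23:
                raise ValueError(
                    f"{path}:{lineno}: expected >=23 domtblout columns, got {len(fields)}"
                )
            target, query = fields[0], fields[3]
            try:
                i_evalue = float(fields[12])
                dom_score = float(fields[13])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            key = (query, target)
            if key not in best or i_evalue < best[key][0]:
                best[key] = (i_evalue, dom_score)
    hits = [
        RecruitHit(family=q, sequence_id=t, score=score, threshold_passed=ev <= evalue_max)
        for (q, t), (ev, score) in best.items()
    ]
    hits.sort(key=lambda h: (-h.score, h.family, h.sequence_id))
    return hits


def write_hits_tsv(hits: Sequence[RecruitHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tseq_id\tscore\tpassed\n")
        for h in hits:
            fh.write(f"{h.family}\t{h.sequence_id}\t{h.score:.4f}\t{int(h.threshold_passed)}\n")
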
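"""Probe design: enumerate, filter, screen for specificity, and select.

Every window of the requested probe length along a recruited CDS is a
candidate.  Candidates pass physicochemical filters (Tm, GC, self
structure), then each survivor is screened against the whole reference
database.  A candidate becomes

* **sequence-specific** when it covers exactly one target CDS and its
  worst-case identity / continuous stretch / duplex ΔG against every other
  sequence stay inside the non-target thresholds;
* **group-specific** when it covers two or more same-family CDS at the
  within-group thresholds while staying inside the non-target thresholds
  against everything outside the group;
* **rejected** otherwise.

Candidate cross-hybridization partners are found by k-mer seed lookup in
the database index; each seeded subject is then scanned exhaustively.  A
subject sharing no k-mer with the probe cannot carry a long continuous
stretch (>= k) and is reported at identity 0 / stretch < k / ΔG 0 —
similarity below the seed-detectable regime is far inside the rejection
thresholds and does not affect classification.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio_db import MotherDB, SequenceRecord
from .specificity import (
    AlignmentHit,
    NNParameterSet,
    best_identity,
    default_nn_params,
    gc_content,
    longest_common_substring,
    melting_temp,
    min_delta_g,
    self_structure,
)

#: fixed common-reference-standard oligo; identical across all CORS spots
CORS_SEQUENCE = "TGACCTGATCGGAAGCTTACCGTACAGTGCATTGCAGACCTTGAGTCGAT"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class PhysChemConstraints:
    """Candidate filters applied before any specificity screening."""

    probe_length: int = 50
    tm_range: tuple[float, float] = (60.0, 95.0)
    gc_range: tuple[float, float] = (30.0, 70.0)
    max_self_comp_run: int = 12
    max_homopolymer: int = 6


@dataclass
class SpecificityCriteria:
    """Thresholds separating sequence-specific, group-specific and rejected.

    ``ss_*`` bound the worst case against non-targets; ``gs_*`` are the
    minimum similarity a same-family member must show to count as covered
    by a group probe.
    """

    ss_max_identity: float = 90.0  # percent
    ss_max_stretch: int = 20  # bases
    ss_min_dg: float = -35.0  # kcal/mol
    gs_min_identity: float = 96.0
    gs_min_stretch: int = 35
    gs_max_dg: float = -60.0

    def __post_init__(self) -> None:
        if not self.ss_max_identity < self.gs_min_identity:
            raise ValueError("ss_max_identity must be below gs_min_identity")
        if not self.ss_min_dg > self.gs_max_dg:
            raise ValueError("ss_min_dg must be above gs_max_dg")


@dataclass
class ProbeCandidate:
    probe_id: str
    family: str
    source_cds: str
    offset: int  # 0-based on the source CDS, forward strand
    seq: str
    tm: float = 0.0
    gc: float = 0.0
    self_comp_run: int = 0
    homopolymer: int = 0


@dataclass
class SpecificityReport:
    candidate: ProbeCandidate
    kind: str  # sequence_specific | group_specific | rejected
    covered_targets: list[str]
    worst_nontarget: AlignmentHit
    worst_group_member: AlignmentHit | None = None


@dataclass
class ProbeSet:
    probes: list[SpecificityReport] = field(default_factory=list)
    uncovered: list[str] = field(default_factory=list)


def enumerate_candidates(
    cds: SequenceRecord,
    constraints: PhysChemConstraints | None = None,
    family: str = "",
    params: NNParameterSet | None = None,
) -> list[ProbeCandidate]:
    """All probe-length windows of the CDS passing the physicochemical
    filters, in offset order (forward strand, within-CDS only)."""
    c = constraints or PhysChemConstraints()
    params = params or default_nn_params()
    L = c.probe_length
    if len(cds.seq) < L:
        warnings.warn(f"CDS {cds.id} shorter than probe length {L}; no candidates")
        return []
    out = []
    for off in range(len(cds.seq) - L + 1):
        window = cds.seq[off : off + L]
        if "N" in window:
            continue
        gc = gc_content(window)
        if not c.gc_range[0] <= gc <= c.gc_range[1]:
            continue
        sc, hp = self_structure(window)
        if sc > c.max_self_comp_run or hp > c.max_homopolymer:
            continue
        tm = melting_temp(window, params)
        if not c.tm_range[0] <= tm <= c.tm_range[1]:
            continue
        out.append(
            ProbeCandidate(
                probe_id=f"{cds.id}_{off}",
                family=family,
                source_cds=cds.id,
                offset=off,
                seq=window,
                tm=tm,
                gc=gc,
                self_comp_run=sc,
                homopolymer=hp,
            )
        )
    return out


def _seeded_subjects(probe: str, db: MotherDB) -> set[str]:
    k = db.k
    ids: set[str] = set()
    for i in range(len(probe) - k + 1):
        for sid, _, _ in db.kmer_index.lookup(probe[i : i + k]):
            ids.add(sid)
    return ids


def _pair_stats(probe: str, subject: str, params: NNParameterSet) -> tuple[float, int, float]:
    ident, _ = best_identity(probe, subject)
    stretch = longest_common_substring(probe, subject, both_strands=True)
    dg, _ = min_delta_g(probe, subject, params)
    return ident, stretch, dg


def evaluate_specificity(
    cand: ProbeCandidate,
    db: MotherDB,
    crit: SpecificityCriteria | None = None,
    params: NNParameterSet | None = None,
) -> SpecificityReport:
    """Screen one candidate against the whole database and classify it.

    Covered targets are same-family CDS meeting all within-group
    thresholds (the source CDS, which contains the probe verbatim, is
    always covered).  Everything else is a non-target; the three worst-case
    statistics are taken independently over non-targets, so they may come
    from different sequences.
    """
    crit = crit or SpecificityCriteria()
    params = params or default_nn_params()
    family = db.targets.get(cand.family)
    members = set(family.members) if family else {cand.source_cds}

    subjects = _seeded_subjects(cand.seq, db) | members
    subjects.discard(cand.source_cds)

    covered = [cand.source_cds]
    worst_id, worst_stretch, worst_dg = 0.0, 0, 0.0
    worst_ids = {"identity": "", "stretch": "", "dg": ""}
    gmin_id, gmin_stretch, gmax_dg = 100.0, len(cand.seq), None
    gworst_sid = ""

    for sid in sorted(subjects):
        subj = db.sequences[sid].seq
        ident, stretch, dg = _pair_stats(cand.seq, subj, params)
        is_covered = (
            sid in members
            and ident >= crit.gs_min_identity
            and stretch >= crit.gs_min_stretch
            and dg <= crit.gs_max_dg
        )
        if is_covered:
            covered.append(sid)
            if ident < gmin_id:
                gmin_id, gworst_sid = ident, sid
            gmin_stretch = min(gmin_stretch, stretch)
            gmax_dg = dg if gmax_dg is None else max(gmax_dg, dg)
        else:
            if ident > worst_id:
                worst_id, worst_ids["identity"] = ident, sid
            if stretch > worst_stretch:
                worst_stretch, worst_ids["stretch"] = stretch, sid
            if dg < worst_dg:
                worst_dg, worst_ids["dg"] = dg, sid

    ss_ok = (
        worst_id <= crit.ss_max_identity
        and worst_stretch <= crit.ss_max_stretch
        and worst_dg >= crit.ss_min_dg
    )
    if len(covered) == 1 and ss_ok:
        kind = "sequence_specific"
    elif len(covered) >= 2 and ss_ok:
        kind = "group_specific"
    else:
        kind = "rejected"

    worst_nt = AlignmentHit(
        probe_id=cand.probe_id,
        subject_id=worst_ids["identity"] or worst_ids["stretch"] or worst_ids["dg"],
        identity=worst_id,
        stretch=worst_stretch,
        dg=worst_dg,
    )
    worst_gm = None
    if kind == "group_specific":
        worst_gm = AlignmentHit(
            probe_id=cand.probe_id,
            subject_id=gworst_sid or cand.source_cds,
            identity=gmin_id if len(covered) > 1 else 100.0,
            stretch=gmin_stretch,
            dg=gmax_dg if gmax_dg is not None else 0.0,
        )
    return SpecificityReport(
        candidate=cand,
        kind=kind,
        covered_targets=sorted(covered),
        worst_nontarget=worst_nt,
        worst_group_member=worst_gm,
    )


def _quality_key(rep: SpecificityReport) -> tuple:
    w = rep.worst_nontarget
    # lowest worst identity, then shortest stretch, then highest dG, then offset
    return (w.identity, w.stretch, -w.dg, rep.candidate.offset)


def select_best_probes(
    reports: Sequence[SpecificityReport],
    per_target: int = 1,
    min_spacing: int | None = None,
) -> ProbeSet:
    """Select up to ``per_target`` probes per covered target CDS.

    Greedy in lexicographic quality order (lowest worst non-target
    identity, shortest worst stretch, highest worst ΔG; lower offset breaks
    ties), subject to a minimum spacing between the chosen probes' offsets
    on the same target (default probe_length // 2).  Targets with no
    accepted candidate are reported in ``uncovered``.
    """
    if per_target < 1:
        raise ValueError("per_target must be >= 1")
    accepted = [r for r in reports if r.kind != "rejected"]
    all_targets: set[str] = set()
    for r in reports:
        all_targets.add(r.candidate.source_cds)
        all_targets.update(r.covered_targets)

    by_target: dict[str, list[SpecificityReport]] = {}
    for r in accepted:
        for t in r.covered_targets:
            by_target.setdefault(t, []).append(r)

    chosen: dict[str, SpecificityReport] = {}
    uncovered = sorted(all_targets - set(by_target))
    for target in sorted(by_target):
        pool = sorted(by_target[target], key=_quality_key)
        spacing = min_spacing
        if spacing is None:
            spacing = len(pool[0].candidate.seq) // 2
        picked: list[SpecificityReport] = []
        for rep in pool:
            if len(picked) >= per_target:
                break
            if all(abs(rep.candidate.offset - p.candidate.offset) >= spacing for p in picked):
                picked.append(rep)
        for rep in picked:
            chosen.setdefault(rep.candidate.probe_id, rep)
    probes = sorted(chosen.values(), key=lambda r: r.candidate.probe_id)
    return ProbeSet(probes=probes, uncovered=uncovered)


def design_probes(
    db: MotherDB,
    constraints: PhysChemConstraints | None = None,
    criteria: SpecificityCriteria | None = None,
    per_target: int = 1,
    families: Iterable[str] | None = None,
) -> ProbeSet:
    """Full pipeline over every target CDS of the selected families."""
    constraints = constraints or PhysChemConstraints()
    criteria = criteria or SpecificityCriteria()
    params = default_nn_params()
    reports: list[SpecificityReport] = []
    fam_names = sorted(families) if families is not None else sorted(db.targets)
    for fname in fam_names:
        fam = db.targets[fname]
        for cds_id in fam.members:
            cands = enumerate_candidates(
                db.sequences[cds_id], constraints, family=fname, params=params
            )
            for cand in cands:
                reports.append(evaluate_specificity(cand, db, criteria, params))
    return select_best_probes(reports, per_target=per_target)


# ---------------------------------------------------------------------------
# control probes
# ---------------------------------------------------------------------------

def expand_iupac(seq: str) -> list[str]:
    """All concrete sequences of a degenerate IUPAC oligo, sorted."""
    pools = [IUPAC[c] for c in seq.upper()]
    return sorted("".join(p) for p in itertools.product(*pools))


def design_controls(
    n_cors: int,
    negatives: Sequence[SequenceRecord] = (),
    db: MotherDB | None = None,
    constraints: PhysChemConstraints | None = None,
    criteria: SpecificityCriteria | None = None,
    cors_sequence: str = CORS_SEQUENCE,
    max_per_negative: int = 3,
) -> dict[str, list[ProbeCandidate]]:
    """Design the control probe sets.

    CORS: ``n_cors`` records sharing one identical oligo (normalization
    spike-in).  Negative controls: physchem-passing windows of the supplied
    negative-source sequences that stay *below* the sequence-specific
    identity threshold against every database target; a window at or above
    the threshold is rejected.  Raises if negative sources are given but no
    valid negative control survives.
    """
    constraints = constraints or PhysChemConstraints()
    criteria = criteria or SpecificityCriteria()
    cors = [
        ProbeCandidate(
            probe_id=f"CORS_{i:05d}", family="__cors__", source_cds="CORS",
            offset=0, seq=cors_sequence,
        )
        for i in range(n_cors)
    ]
    neg: list[ProbeCandidate] = []
    target_ids = []
    if db is not None:
        target_ids = [sid for sid, r in db.sequences.items() if r.source == "target"]
    for rec in negatives:
        kept = 0
        for cand in enumerate_candidates(rec, constraints, family="__negative__"):
            if kept >= max_per_negative:
                break
            ok = True
            if db is not None:
                for tid in target_ids:
                    ident, _ = best_identity(cand.seq, db.sequences[tid].seq)
                    if ident >= criteria.ss_max_identity:
                        ok = False
                        break
            if ok:
                cand.probe_id = f"NEG_{rec.id}_{cand.offset}"
                neg.append(cand)
                kept += 1
    if negatives and not neg:
        raise ValueError("no negative-control candidate survived the identity screen")
    return {"cors": cors, "negative": neg}


# ---------------------------------------------------------------------------
# output tables
# ---------------------------------------------------------------------------

def write_probe_tsv(
    pset: ProbeSet,
    path: str | Path,
    categories: Mapping[str, str] | None = None,
) -> None:
    """Probe set TSV, deterministic for identical inputs."""
    cols = (
        "probe_id\tfamily\tcategory\ttarget_cds\toffset\tstrand\tsequence\tkind\t"
        "covered_targets\tworst_identity\tworst_stretch\tworst_dg\ttm\tgc\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for rep in pset.probes:
            c = rep.candidate
            w = rep.worst_nontarget
            fh.write(
                f"{c.probe_id}\t{c.family}\t{(categories or {}).get(c.family, '')}\t"
                f"{c.source_cds}\t{c.offset}\t+\t{c.seq}\t{rep.kind}\t"
                f"{','.join(rep.covered_targets)}\t{w.identity:.2f}\t{w.stretch}\t"
                f"{w.dg:.2f}\t{c.tm:.2f}\t{c.gc:.2f}\n"
            )


def summarize_categories(
    pset: ProbeSet, categories: Mapping[str, str]
) -> list[dict]:
    """Per-category bookkeeping: gene families, probes by kind, CDS covered."""
    rows: dict[str, dict] = {}
    for rep in pset.probes:
        cat = categories.get(rep.candidate.family, "")
        row = rows.setdefault(
            cat,
            {"category": cat, "families": set(), "probes": 0,
             "sequence_specific": 0, "group_specific": 0, "covered_cds": set()},
        )
        row["families"].add(rep.candidate.family)
        row["probes"] += 1
        if rep.kind == "sequence_specific":
            row["sequence_specific"] += 1
        elif rep.kind == "group_specific":
            row["group_specific"] += 1
        row["covered_cds"].update(rep.covered_targets)
    out = []
    for cat in sorted(rows):
        r = rows[cat]
        out.append(
            {"category": cat, "n_families": len(r["families"]), "n_probes": r["probes"],
             "n_sequence_specific": r["sequence_specific"],
             "n_group_specific": r["group_specific"],
             "n_covered_cds": len(r["covered_cds"])}
        )
    return out
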
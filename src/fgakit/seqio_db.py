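"""Sequence I/O and the target/background reference database.

The reference database ("mother database") collects every coding sequence a
probe could possibly cross-hybridize with: the target CDS, organised into
gene families, plus background sequences (other genomes / metagenome ORFs).
All probe specificity is judged against this universe.  Sequences are
indexed by k-mer on both strands so that candidate cross-hybridization
partners can be found by seed lookup instead of all-vs-all scanning.

Coordinates are 0-based, half-open; strand is ``'+'`` or ``'-'``.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a normalized nucleotide string (N stays N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A single normalized sequence with provenance.

    ``alphabet`` is ``'nt'`` (uppercase A/C/G/T/N, U folded to T) or
    ``'aa'``.  ``source`` marks whether the record belongs to the target
    set (probe design substrate) or the background (specificity screen
    only).
    """

    id: str
    seq: str
    description: str = ""
    source: str = "target"
    alphabet: str = "nt"

    def __len__(self) -> int:
        return len(self.seq)


def _normalize(raw: str, alphabet: str, rec_id: str) -> str:
    s = raw.upper()
    if alphabet == "nt":
        s = s.replace("U", "T")
        bad = set(s) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec_id!r}: ambiguity codes not supported in nucleotide "
                f"input (found {sorted(bad)}); only A/C/G/T/N accepted"
            )
    elif alphabet == "aa":
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"record {rec_id!r}: invalid amino-acid letters {sorted(bad)}")
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return s


def read_fasta(path: str | Path, alphabet: str = "nt", source: str = "target") -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Nucleotide records are uppercased with U folded to T; ambiguity codes
    other than N are a hard error.  Duplicate ids are a hard error.  An
    empty file yields an empty list with a warning.  Input order is
    preserved.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seen.add(rec.id)
            records.append(
                SequenceRecord(
                    id=rec.id,
                    seq=_normalize(str(rec.seq), alphabet, rec.id),
                    description=rec.description,
                    source=source,
                    alphabet=alphabet,
                )
            )
    if not records:
        warnings.warn(f"no records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (fixed line width so round trips are stable)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def link_cds(
    proteins: Sequence[SequenceRecord],
    cds: Sequence[SequenceRecord],
    id_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Link protein records to the coding sequences they were called from.

    When ``id_map`` (protein id -> CDS id) is absent, records pair by
    identical id.  Every accepted link is verified by translating the CDS
    (standard code, frame 1) and comparing to the protein, allowing a
    terminal stop on the CDS.  Mismatching pairs are excluded and logged,
    not fatal.

    Returns ``(links, unmapped)`` where ``links`` maps protein id -> CDS id
    and ``unmapped`` lists protein ids with no verified partner.
    """
    cds_by_id = {r.id: r for r in cds}
    prot_by_id = {r.id: r for r in proteins}
    if id_map is None:
        id_map = {pid: pid for pid in prot_by_id if pid in cds_by_id}
    links: dict[str, str] = {}
    unmapped: list[str] = []
    for prot in proteins:
        cid = id_map.get(prot.id)
        rec = cds_by_id.get(cid) if cid is not None else None
        if rec is None:
            unmapped.append(prot.id)
            continue
        translated = str(Seq(rec.seq).translate(to_stop=False))
        if translated.endswith("*"):
            translated = translated[:-1]
        if translated == prot.seq:
            links[prot.id] = rec.id
        else:
            logger.warning(
                "CDS %s does not translate to protein %s; pair excluded", rec.id, prot.id
            )
            unmapped.append(prot.id)
    return links, unmapped


@dataclass
class GeneFamily:
    """A functional gene family: a named group of target CDS ids."""

    name: str
    category: str = ""
    members: list[str] = field(default_factory=list)


class KmerIndex:
    """Both-strand exact k-mer index over a set of sequences.

    Postings are ``(seq_id, start, strand)`` with ``start`` the 0-based
    offset of the k-mer window *on the forward strand* of the stored
    sequence.  k-mers containing N are never indexed (N matches nothing).
    """

    def __init__(self, k: int):
        if not 8 <= k <= 16:
            raise ValueError(f"k must be in [8, 16], got {k}")
        self.k = k
        self._index: dict[str, list[tuple[str, int, str]]] = {}

    def add(self, seq_id: str, seq: str) -> None:
        k = self.k
        n = len(seq)
        if n < k:
            warnings.warn(f"sequence {seq_id!r} shorter than k={k}; indexed as zero k-mers")
            return
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                self._index.setdefault(w, []).append((seq_id, i, "+"))
        rc = revcomp(seq)
        for j in range(n - k + 1):
            w = rc[j : j + k]
            if "N" not in w:
                # forward-strand start of the window whose revcomp is w
                self._index.setdefault(w, []).append((seq_id, n - k - j, "-"))

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        return self._index.get(kmer, [])

    def __len__(self) -> int:
        return len(self._index)


class MotherDB:
    """Targets (by gene family) + background sequences + k-mer index.

    The database also carries optional protein records and protein->CDS
    links so that family recruitment can hand verified coding sequences to
    probe design.
    """

    def __init__(self, k: int = 12):
        self.k = k
        self.sequences: dict[str, SequenceRecord] = {}
        self.targets: dict[str, GeneFamily] = {}
        self.proteins: dict[str, SequenceRecord] = {}
        self.cds_links: dict[str, str] = {}
        self.kmer_index = KmerIndex(k)
        self._encoded: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- construction -------------------------------------------------
    def add_sequence(self, rec: SequenceRecord) -> None:
        if rec.id in self.sequences:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        self.sequences[rec.id] = rec
        self.kmer_index.add(rec.id, rec.seq)
        fwd = np.frombuffer(rec.seq.encode("ascii"), dtype=np.uint8)
        rev = np.frombuffer(revcomp(rec.seq).encode("ascii"), dtype=np.uint8)
        self._encoded[rec.id] = (fwd, rev)

    def family_of(self, seq_id: str) -> str | None:
        for fam in self.targets.values():
            if seq_id in fam.members:
                return fam.name
        return None

    def encoded(self, seq_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(forward, reverse-complement) uint8 views of a stored sequence."""
        return self._encoded[seq_id]

    # -- persistence (text formats; index rebuilt on load) ------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences.values(), directory / "sequences.fasta")
        with open(directory / "families.tsv", "w") as fh:
            fh.write("family\tcategory\tmember_id\n")
            for fam in self.targets.values():
                for mid in fam.members:
                    fh.write(f"{fam.name}\t{fam.category}\t{mid}\n")
        meta = {
            "k": self.k,
            "sources": {sid: r.source for sid, r in self.sequences.items()},
        }
        with open(directory / "meta.json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, directory: str | Path) -> "MotherDB":
        directory = Path(directory)
        with open(directory / "meta.json") as fh:
            meta = json.load(fh)
        db = cls(k=meta["k"])
        for rec in read_fasta(directory / "sequences.fasta"):
            rec.source = meta["sources"].get(rec.id, "target")
            db.add_sequence(rec)
        with open(directory / "families.tsv") as fh:
            header = fh.readline()
            assert header.startswith("family")
            for line in fh:
                name, category, mid = line.rstrip("\n").split("\t")
                fam = db.targets.setdefault(name, GeneFamily(name, category))
                fam.members.append(mid)
        return db


def build_motherdb(
    targets: Iterable[tuple[str, SequenceRecord]],
    background: Iterable[SequenceRecord] = (),
    k: int = 12,
    categories: Mapping[str, str] | None = None,
) -> MotherDB:
    """Assemble the reference database from (family, record) pairs plus
    background records.

    Every sequence is k-mer-indexed on both strands.  ``categories``
    optionally maps family name -> functional category label.
    """
    db = MotherDB(k=k)
    for family, rec in targets:
        rec.source = "target"
        db.add_sequence(rec)
        fam = db.targets.setdefault(
            family, GeneFamily(family, (categories or {}).get(family, ""))
        )
        fam.members.append(rec.id)
    for rec in background:
        rec.source = "background"
        db.add_sequence(rec)
    return db


def read_family_table(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a family/category/member TSV; returns (member->family, family->category)."""
    member_family: dict[str, str] = {}
    family_category: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        rows = [] if first.startswith("family\t") else [first]
        rows.extend(fh)
        for line in rows:
            line = line.rstrip("\n")
            if not line:
                continue
            fam, cat, mid = line.split("\t")
            member_family[mid] = fam
            family_category[fam] = cat
    return member_family, family_category
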
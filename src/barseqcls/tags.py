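"""Barcode reference database construction.

Each deletion strain carries up to two strain-specific 20-bp barcodes (an
"uptag" and a "downtag") flanked by universal priming sequence. A counting
run reads, from its 5' end: a 4-bp multiplex index, an 18-bp universal
primer, the 20-bp tag, and 9 bp of trailing universal primer — 51 bp in
total. The reference database therefore holds one 51-nt entry per
(decoded tag) x (multiplex index) combination, so demultiplexing and tag
identification happen in a single matching step.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")
TAG_LEN = 20
FLANK_LEN = 33
INDEX_LEN = 4
FWD_PRIMER_LEN = 18
TRAIL_PRIMER_LEN = 9
ENTRY_LEN = INDEX_LEN + FWD_PRIMER_LEN + TAG_LEN + TRAIL_PRIMER_LEN  # 51

TAG_KINDS = ("up", "dn")


class TagTableError(ValueError):
    """Raised when a tag table contains invalid rows; message lists each one."""


@dataclass(frozen=True)
class TagRecord:
    """One decoded barcode: a gene, a tag kind, the 20-mer, and its
    expected 33-bp flanking genomic sequence (optional for counting-only use)."""

    gene_id: str
    tag_kind: str  # "up" | "dn"
    tag_seq: str
    expected_flank: str | None = None

    def validate(self) -> list[str]:
        problems = []
        if self.tag_kind not in TAG_KINDS:
            problems.append(f"tag_kind must be one of {TAG_KINDS}, got {self.tag_kind!r}")
        if len(self.tag_seq) != TAG_LEN:
            problems.append(f"tag_seq must be {TAG_LEN} nt, got {len(self.tag_seq)}")
        if not set(self.tag_seq) <= DNA_ALPHABET:
            problems.append(f"tag_seq contains non-ACGTN characters: {self.tag_seq!r}")
        if self.expected_flank is not None:
            if len(self.expected_flank) != FLANK_LEN:
                problems.append(
                    f"expected_flank must be {FLANK_LEN} nt, got {len(self.expected_flank)}"
                )
            elif not set(self.expected_flank) <= DNA_ALPHABET:
                problems.append("expected_flank contains non-ACGTN characters")
        return problems


@dataclass(frozen=True)
class PrimerSet:
    """Universal primer segments bracketing the tag in a counting read."""

    up_forward: str
    up_trailing: str
    dn_forward: str
    dn_trailing: str

    def __post_init__(self):
        for name in ("up_forward", "dn_forward"):
            if len(getattr(self, name)) != FWD_PRIMER_LEN:
                raise ValueError(f"{name} must be {FWD_PRIMER_LEN} nt")
        for name in ("up_trailing", "dn_trailing"):
            if len(getattr(self, name)) != TRAIL_PRIMER_LEN:
                raise ValueError(f"{name} must be {TRAIL_PRIMER_LEN} nt")

    def forward(self, tag_kind: str) -> str:
        return self.up_forward if tag_kind == "up" else self.dn_forward

    def trailing(self, tag_kind: str) -> str:
        return self.up_trailing if tag_kind == "up" else self.dn_trailing


# Forward primers are the gene-cassette-specific 18-mers of the round-1 PCR
# primers; trailing 9-mers are the first 9 nt read through into the
# reverse-complemented reverse-primer annealing site.
DEFAULT_PRIMERS = PrimerSet(
    up_forward="GAGGCAAGCTAAGATATC",
    up_trailing="TAAATGCGA",
    dn_forward="CCAGTGTCGAAAAGTATC",
    dn_trailing="CCTACGCAA",
)

# The study multiplexed 20 samples per lane with 4-nt indexes; the actual
# sequences are not published, so these stand-ins are arbitrary distinct
# 4-mers (configurable everywhere an index set is accepted).
DEFAULT_INDEXES = (
    "AACG", "ACTG", "AGAC", "ATCA", "CAGT", "CCAA", "CGTC", "CTAG",
    "GACT", "GCGA", "GGTA", "GTAC", "TAGC", "TCCG", "TGGT", "TTAA",
    "ACGT", "CATG", "GTCA", "TGCA",
)


@dataclass(frozen=True)
class DatabaseEntry:
    """One 51-nt reference sequence: index + forward primer + tag + trailing primer."""

    seq: str
    gene_id: str
    tag_kind: str
    index_id: int  # 1-based

    def __post_init__(self):
        if len(self.seq) != ENTRY_LEN:
            raise ValueError(f"entry sequence must be {ENTRY_LEN} nt, got {len(self.seq)}")

    @property
    def index_seq(self) -> str:
        return self.seq[:INDEX_LEN]

    @property
    def tag_seq(self) -> str:
        start = INDEX_LEN + FWD_PRIMER_LEN
        return self.seq[start : start + TAG_LEN]


@dataclass
class BarcodeDatabase:
    """The full set of 51-nt reference entries plus provenance.

    ``duplicate_seqs`` records sequences shared by more than one entry
    (possible with degenerate tags); the matcher treats reads hitting them
    as ambiguous.
    """

    entries: list[DatabaseEntry]
    index_table: dict[int, str]
    primers: PrimerSet
    duplicate_seqs: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.entries)

    def __post_init__(self):
        if not self.duplicate_seqs:
            seen = collections.Counter(e.seq for e in self.entries)
            self.duplicate_seqs = {s for s, n in seen.items() if n > 1}


def read_tag_table(path: str | Path) -> list[TagRecord]:
    """Read a decoded-tag table (TSV) into validated ``TagRecord``s.

    Expected columns: ``gene_id``, ``tag_kind`` (or ``tag``), ``tag_seq``,
    and optionally ``expected_flank`` (or ``flank``). Invalid rows and
    duplicate (gene_id, tag_kind) pairs raise :class:`TagTableError` with
    row-level diagnostics (row numbers count data rows from 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df = df.rename(columns={"tag": "tag_kind", "flank": "expected_flank"})
    required = {"gene_id", "tag_kind", "tag_seq"}
    missing = required - set(df.columns)
    if missing:
        raise TagTableError(f"tag table missing columns: {sorted(missing)}")

    records: list[TagRecord] = []
    errors: list[str] = []
    seen: set[tuple[str, str]] = set()
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        flank = getattr(row, "expected_flank", "") or None
        rec = TagRecord(row.gene_id, row.tag_kind, row.tag_seq.upper(),
                        flank.upper() if flank else None)
        problems = rec.validate()
        key = (rec.gene_id, rec.tag_kind)
        if key in seen:
            problems.append(f"duplicate (gene_id, tag_kind) = {key}")
        if problems:
            errors.extend(f"row {rownum}: {p}" for p in problems)
        else:
            seen.add(key)
            records.append(rec)
    if errors:
        raise TagTableError("invalid tag table:\n" + "\n".join(errors))
    return records


def single_tag_genes(tags: Sequence[TagRecord]) -> dict[str, str]:
    """Genes represented by only one decoded tag, mapped to that tag's kind."""
    kinds: dict[str, set[str]] = collections.defaultdict(set)
    for t in tags:
        kinds[t.gene_id].add(t.tag_kind)
    return {g: next(iter(k)) for g, k in kinds.items() if len(k) == 1}


def write_tag_table(tags: Sequence[TagRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": t.gene_id,
            "tag_kind": t.tag_kind,
            "tag_seq": t.tag_seq,
            "expected_flank": t.expected_flank or "",
        }
        for t in tags
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_database(
    tags: Sequence[TagRecord],
    indexes: Sequence[str] = DEFAULT_INDEXES,
    primers: PrimerSet = DEFAULT_PRIMERS,
) -> BarcodeDatabase:
    """Build the 51-nt reference database: one entry per tag x index.

    A gene with both tags decoded contributes ``2 * len(indexes)`` entries;
    a single-tag gene contributes ``len(indexes)``. Entries are ordered by
    (gene_id, tag_kind, index_id).
    """
    if not tags:
        raise ValueError("cannot build a database from an empty tag list")
    if not indexes:
        raise ValueError("at least one multiplex index is required")
    for idx in indexes:
        if len(idx) != INDEX_LEN or not set(idx) <= DNA_ALPHABET:
            raise ValueError(f"multiplex index must be a 4-nt DNA sequence, got {idx!r}")
    if len(set(indexes)) != len(indexes):
        raise ValueError("multiplex indexes must be distinct")

    entries = []
    for tag in sorted(tags, key=lambda t: (t.gene_id, t.tag_kind)):
        fwd = primers.forward(tag.tag_kind)
        trail = primers.trailing(tag.tag_kind)
        for index_id, idx_seq in enumerate(indexes, start=1):
            entries.append(
                DatabaseEntry(
                    seq=idx_seq + fwd + tag.tag_seq + trail,
                    gene_id=tag.gene_id,
                    tag_kind=tag.tag_kind,
                    index_id=index_id,
                )
            )
    index_table = {i: s for i, s in enumerate(indexes, start=1)}
    return BarcodeDatabase(entries=entries, index_table=index_table, primers=primers)


def write_database_fasta(db: BarcodeDatabase, path: str | Path) -> None:
    """Serialize a database to FASTA; headers encode gene|tag_kind|index_id."""
    records = [
        SeqRecord(Seq(e.seq), id=f"{e.gene_id}|{e.tag_kind}|{e.index_id}", description="")
        for e in db.entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_database_fasta(path: str | Path, primers: PrimerSet = DEFAULT_PRIMERS) -> BarcodeDatabase:
    """Read a database FASTA written by :func:`write_database_fasta`."""
    entries = []
    index_table: dict[int, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id, tag_kind, index_id = rec.id.rsplit("|", 2)
        entry = DatabaseEntry(str(rec.seq).upper(), gene_id, tag_kind, int(index_id))
        entries.append(entry)
        index_table.setdefault(entry.index_id, entry.index_seq)
    return BarcodeDatabase(entries=entries, index_table=index_table, primers=primers)
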
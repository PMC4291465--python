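"""Assigning counting-run reads to barcode database entries.

Matching is ungapped and substitution-only over the first 42 nt of each
read (index + forward primer + tag), the discriminating portion of the
51-nt reference entries; the trailing 9-nt universal primer is constant
and carries no information. At most one mismatch is tolerated, and a read
is counted only when it identifies a single best entry across the whole
database: an exact (distance-0) hit beats distance-1 hits, and any tie at
the best distance discards the read as ambiguous.

The matcher indexes the 42-mer as two 21-nt halves; with at most one
substitution, at least one half is error-free (pigeonhole), so candidate
lookup is two dictionary probes followed by Hamming verification.
"""

from __future__ import annotations

import collections
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from barseqcls.tags import BarcodeDatabase, DatabaseEntry

MATCH_LEN = 42
_HALF = MATCH_LEN // 2


class _Sentinel:
    def __init__(self, name: str):
        self.name = name

    def __repr__(self):
        return self.name


AMBIGUOUS = _Sentinel("AMBIGUOUS")
NO_MATCH = _Sentinel("NO_MATCH")


@dataclass(frozen=True)
class SampleMeta:
    """Identity and design role of one sequenced sample."""

    sample_id: str
    replicate: int
    timepoint: float
    unit: str  # "weeks" | "minutes"
    role: str  # "reference" | "aged"
    index_id: int = 1
    fastq: str | None = None


@dataclass
class MatchReport:
    """Read-level accounting for one sample; categories partition the input."""

    total_reads: int = 0
    matched_unique: int = 0
    discarded_ambiguous: int = 0
    discarded_unmatched: int = 0
    short_reads: int = 0  # subset of discarded_unmatched

    def check(self) -> None:
        assert (
            self.matched_unique + self.discarded_ambiguous + self.discarded_unmatched
            == self.total_reads
        ), "match report categories must partition the reads"


@dataclass
class CountMatrix:
    """Raw read counts per (gene_id, tag_kind) per sample.

    ``counts`` is indexed by a (gene_id, tag_kind) MultiIndex with one
    column per sample_id; ``depth`` holds the per-sample totals of matched
    reads used for normalization.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    depth: pd.Series = field(init=False)

    def __post_init__(self):
        self.counts = self.counts.sort_index()
        self.depth = self.counts.sum(axis=0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def meta(self, sample_id: str) -> SampleMeta:
        for m in self.samples:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, samples: list[SampleMeta]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tag_kind": str})
        df = df.set_index(["gene_id", "tag_kind"])
        sample_ids = [m.sample_id for m in samples]
        return cls(counts=df[sample_ids], samples=samples)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


class ReadMatcher:
    """Pigeonhole-indexed 1-mismatch matcher over a barcode database."""

    def __init__(self, db: BarcodeDatabase, strict_index: bool = False):
        self.db = db
        self.strict_index = strict_index
        self._exact: dict[str, list[int]] = collections.defaultdict(list)
        self._left: dict[str, list[int]] = collections.defaultdict(list)
        self._right: dict[str, list[int]] = collections.defaultdict(list)
        for i, entry in enumerate(db.entries):
            prefix = entry.seq[:MATCH_LEN]
            self._exact[prefix].append(i)
            self._left[prefix[:_HALF]].append(i)
            self._right[prefix[_HALF:]].append(i)

    def match(
        self, read: str, expected_index: str | None = None
    ) -> DatabaseEntry | _Sentinel:
        """Classify one read: a unique entry, AMBIGUOUS, or NO_MATCH."""
        if len(read) < MATCH_LEN:
            return NO_MATCH
        prefix = read[:MATCH_LEN].upper()
        if self.strict_index and expected_index is not None:
            if prefix[:4] != expected_index:
                return NO_MATCH

        candidates = set(self._exact.get(prefix, ()))
        candidates.update(self._left.get(prefix[:_HALF], ()))
        candidates.update(self._right.get(prefix[_HALF:], ()))

        d0: list[int] = []
        d1: list[int] = []
        for i in candidates:
            d = hamming(prefix, self.db.entries[i].seq[:MATCH_LEN])
            if d == 0:
                d0.append(i)
            elif d == 1:
                d1.append(i)
        best = d0 if d0 else d1
        if not best:
            return NO_MATCH
        if len(best) > 1:
            return AMBIGUOUS
        entry = self.db.entries[best[0]]
        if entry.seq in self.db.duplicate_seqs:
            return AMBIGUOUS
        return entry


def match_read(read: str, db: BarcodeDatabase) -> DatabaseEntry | _Sentinel:
    """One-shot convenience wrapper around :class:`ReadMatcher`."""
    return ReadMatcher(db).match(read)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (optionally gzipped)."""
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield str(rec.seq).upper()


def count_sample(
    fastq: str | Path,
    db: BarcodeDatabase,
    meta: SampleMeta,
    matcher: ReadMatcher | None = None,
) -> tuple[dict[tuple[str, str], int], MatchReport]:
    """Count uniquely matched reads per (gene_id, tag_kind) for one sample.

    Counts are aggregated over multiplex index (demultiplexing is implicit
    in the 42-nt match). Every read lands in exactly one MatchReport
    category.
    """
    if matcher is None:
        matcher = ReadMatcher(db)
    counts: dict[tuple[str, str], int] = collections.defaultdict(int)
    report = MatchReport()
    expected_index = db.index_table.get(meta.index_id)
    for read in iter_fastq(fastq):
        report.total_reads += 1
        if len(read) < MATCH_LEN:
            report.short_reads += 1
            report.discarded_unmatched += 1
            continue
        result = matcher.match(read, expected_index=expected_index)
        if result is NO_MATCH:
            report.discarded_unmatched += 1
        elif result is AMBIGUOUS:
            report.discarded_ambiguous += 1
        else:
            counts[(result.gene_id, result.tag_kind)] += 1
            report.matched_unique += 1
    report.check()
    return dict(counts), report


def assemble_count_matrix(
    per_sample: dict[str, dict[tuple[str, str], int]],
    samples: list[SampleMeta],
) -> CountMatrix:
    """Merge per-sample count dicts into one CountMatrix; absent cells are 0."""
    ids = [m.sample_id for m in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in sample sheet")
    missing = set(per_sample) - set(ids)
    if missing:
        raise ValueError(f"counts provided for unknown samples: {sorted(missing)}")
    keys = sorted({k for c in per_sample.values() for k in c})
    index = pd.MultiIndex.from_tuples(keys, names=["gene_id", "tag_kind"])
    df = pd.DataFrame(0, index=index, columns=ids, dtype=int)
    for sid, counts in per_sample.items():
        for key, n in counts.items():
            df.loc[key, sid] = n
    return CountMatrix(counts=df, samples=samples)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a sample sheet TSV: sample_id, replicate, timepoint, unit, role[, index_id, fastq]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                replicate=int(row.replicate),
                timepoint=float(row.timepoint),
                unit=str(row.unit),
                role=str(row.role),
                index_id=int(getattr(row, "index_id", 1)),
                fastq=str(row.fastq) if hasattr(row, "fastq") else None,
            )
        )
    return metas


def write_sample_sheet(samples: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "replicate": m.replicate,
                "timepoint": m.timepoint,
                "unit": m.unit,
                "role": m.role,
                "index_id": m.index_id,
                "fastq": m.fastq or "",
            }
            for m in samples
        ]
    ).to_csv(path, sep="\t", index=False)
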
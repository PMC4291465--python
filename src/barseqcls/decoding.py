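"""Barcode decoding from 101-cycle reads.

A decode run reads each barcode together with 33 bp of adjacent genomic
sequence: 4-bp multiplex index, 18-bp primer, 20-bp barcode, 26-bp
universal spacer, 33-bp genomic flank. Reads are grouped on the exact
20-mer barcode; each group's per-position majority flank consensus is
compared against the expected flanks of all deletion cassettes, and the
group is assigned to the unique gene/tag whose expected flank is closest
(within a configurable Hamming radius with a unique-best requirement).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from barseqcls.matching import hamming, iter_fastq
from barseqcls.tags import FLANK_LEN, TagRecord

SEGMENTS = (("index", 4), ("primer", 18), ("barcode", 20), ("spacer", 26), ("flank", 33))
DECODE_READ_LEN = sum(n for _, n in SEGMENTS)  # 101


class ShortReadError(ValueError):
    pass


@dataclass(frozen=True)
class DecodeRead:
    index: str
    primer: str
    barcode: str
    spacer: str
    flank: str


@dataclass(frozen=True)
class BarcodeCluster:
    barcode: str
    n_reads: int
    flank_consensus: str
    flank_support: float  # fraction of member reads whose flank equals the consensus


@dataclass
class AssignmentReport:
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0
    conflicting_genes: list[str] = None

    def __post_init__(self):
        if self.conflicting_genes is None:
            self.conflicting_genes = []


def parse_decode_read(raw: str) -> DecodeRead:
    """Segment the first 101 nt of a decode-run read at fixed offsets."""
    if len(raw) < DECODE_READ_LEN:
        raise ShortReadError(f"decode read shorter than {DECODE_READ_LEN} nt ({len(raw)})")
    raw = raw[:DECODE_READ_LEN].upper()
    fields = {}
    offset = 0
    for name, length in SEGMENTS:
        fields[name] = raw[offset : offset + length]
        offset += length
    return DecodeRead(**fields)


def _consensus(seqs: Sequence[str]) -> str:
    """Per-position majority base; ties broken to the lexicographically
    smallest base so the result is deterministic."""
    out = []
    for pos in range(len(seqs[0])):
        votes = collections.Counter(s[pos] for s in seqs)
        best = max(votes.items(), key=lambda kv: (kv[1], -ord(kv[0][0])))
        out.append(best[0])
    return "".join(out)


def cluster_by_barcode(
    reads: Iterable[DecodeRead], min_cluster_size: int = 2
) -> list[BarcodeCluster]:
    """Group reads by exact barcode; drop groups below ``min_cluster_size``.

    Sequencing-error barcode variants are not merged — a singleton produced
    by an error is removed by the size filter instead.
    """
    groups: dict[str, list[str]] = collections.defaultdict(list)
    for read in reads:
        groups[read.barcode].append(read.flank)
    clusters = []
    for barcode in sorted(groups):
        flanks = groups[barcode]
        if len(flanks) < min_cluster_size:
            continue
        cons = _consensus(flanks)
        support = sum(f == cons for f in flanks) / len(flanks)
        clusters.append(
            BarcodeCluster(
                barcode=barcode,
                n_reads=len(flanks),
                flank_consensus=cons,
                flank_support=support,
            )
        )
    return clusters


def assign_clusters(
    clusters: Sequence[BarcodeCluster],
    expected: Sequence[TagRecord],
    d_max: int = 3,
) -> tuple[list[TagRecord], AssignmentReport]:
    """Assign barcode clusters to genes by nearest expected flank.

    A cluster is assigned iff the minimum Hamming distance to any expected
    flank is <= d_max AND the second-best distance strictly exceeds the
    best (unique-best). Two clusters decoding different barcodes to the
    same (gene, tag_kind) are both kept and the gene is flagged as a
    conflicting decode.
    """
    targets = [t for t in expected if t.expected_flank is not None]
    for t in targets:
        if len(t.expected_flank) != FLANK_LEN:
            raise ValueError(f"expected flank for {t.gene_id}/{t.tag_kind} is not {FLANK_LEN} nt")
    if not targets:
        raise ValueError("no expected flanks provided")

    report = AssignmentReport()
    decoded: list[TagRecord] = []
    by_slot: dict[tuple[str, str], set[str]] = collections.defaultdict(set)
    for cluster in clusters:
        dists = [(hamming(cluster.flank_consensus, t.expected_flank), t) for t in targets]
        dists.sort(key=lambda dt: dt[0])
        best_d, best_t = dists[0]
        second_d = dists[1][0] if len(dists) > 1 else best_d + d_max + 1
        if best_d > d_max:
            report.unassigned += 1
            continue
        if second_d <= best_d:
            report.ambiguous += 1
            continue
        report.assigned += 1
        rec = TagRecord(
            gene_id=best_t.gene_id,
            tag_kind=best_t.tag_kind,
            tag_seq=cluster.barcode,
            expected_flank=best_t.expected_flank,
        )
        decoded.append(rec)
        by_slot[(best_t.gene_id, best_t.tag_kind)].add(cluster.barcode)

    for (gene_id, _), barcodes in by_slot.items():
        if len(barcodes) > 1 and gene_id not in report.conflicting_genes:
            report.conflicting_genes.append(gene_id)
    return decoded, report


def decode_fastq(
    fastq: str | Path,
    expected: Sequence[TagRecord],
    min_cluster_size: int = 2,
    d_max: int = 3,
) -> tuple[list[TagRecord], AssignmentReport, int]:
    """Full decode: parse, cluster, assign. Returns (tags, report, n_parseable)."""
    reads = []
    for seq in iter_fastq(fastq):
        try:
            reads.append(parse_decode_read(seq))
        except ShortReadError:
            continue
    clusters = cluster_by_barcode(reads, min_cluster_size=min_cluster_size)
    tags, report = assign_clusters(clusters, expected, d_max=d_max)
    return tags, report, len(reads)
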
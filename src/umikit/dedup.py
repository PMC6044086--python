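"""PCR-duplicate identification.

RNA-seq: alignments whose templates share mapping coordinates (reference,
orientation, unclipped 5' positions of both mates) form a read group;
within a group the UMIs parsed from read names are clustered with the
directional graph and one template per cluster is retained, the rest are
flagged with the standard duplicate flag (0x400).

Small RNA-seq reads often arise from many genomic loci, so grouping by
coordinate is replaced by grouping on the exact insert sequence.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pysam

from .extract import ExtractedRead, parse_umi_from_name
from .graph import cluster_umis


@dataclass
class DedupReport:
    """Accounting for one duplicate-marking run."""

    templates: int = 0
    groups: int = 0
    molecules: int = 0
    duplicates_flagged: int = 0
    passthrough_records: int = 0


def unclipped_start(aln: pysam.AlignedSegment) -> int:
    """Unclipped 5' coordinate of an alignment.

    Forward reads: reference start minus leading clips; reverse reads:
    reference end plus trailing clips.  Using unclipped positions keeps
    reads with different soft-clipping in the same duplicate group.
    """
    cig = aln.cigartuples or []
    CLIP = (4, 5)  # soft, hard
    if aln.is_reverse:
        tail = 0
        for op, ln in reversed(cig):
            if op in CLIP:
                tail += ln
            else:
                break
        return aln.reference_end + tail
    head = 0
    for op, ln in cig:
        if op in CLIP:
            head += ln
        else:
            break
    return aln.reference_start - head


@dataclass
class _Template:
    name: str
    umi: str | None
    qual_sum: int = 0
    # (reference_id, is_reverse, unclipped 5') per primary mapped mate
    ends: list[tuple[int, bool, int]] = field(default_factory=list)

    @property
    def key(self) -> tuple:
        # order-independent in the mates: sort the per-mate end tuples
        return tuple(sorted(self.ends))


def _considered(aln: pysam.AlignedSegment) -> bool:
    return not (aln.is_unmapped or aln.is_secondary or aln.is_supplementary)


def _collect_templates(path: str, use_umi: bool) -> tuple[dict[str, _Template], int]:
    templates: dict[str, _Template] = {}
    passthrough = 0
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if not _considered(aln):
                passthrough += 1
                continue
            name = aln.query_name
            t = templates.get(name)
            if t is None:
                umi = None
                if use_umi:
                    try:
                        umi = parse_umi_from_name(name)
                    except ValueError as exc:
                        raise ValueError(f"cannot parse UMI from record {name!r}") from exc
                t = templates[name] = _Template(name=name, umi=umi)
            t.ends.append((aln.reference_id, aln.is_reverse, unclipped_start(aln)))
            if aln.query_qualities is not None:
                t.qual_sum += int(sum(aln.query_qualities))
    return templates, passthrough


def _select_duplicates(templates: Iterable[_Template], use_umi: bool) -> tuple[set[str], DedupReport]:
    """Decide which template names to flag; shared by mark/remove paths."""
    report = DedupReport()
    groups: dict[tuple, list[_Template]] = defaultdict(list)
    for t in templates:
        report.templates += 1
        groups[t.key].append(t)

    dup_names: set[str] = set()
    for members in groups.values():
        report.groups += 1
        if use_umi:
            counts = Counter(t.umi for t in members)
            clusters = cluster_umis(counts)
            rep_of = {u: c.representative for c in clusters for u in c.members}
            by_cluster: dict[str, list[_Template]] = defaultdict(list)
            for t in members:
                by_cluster[rep_of[t.umi]].append(t)
            partitions: Sequence[list[_Template]] = list(by_cluster.values())
        else:
            partitions = [members]
        for part in partitions:
            report.molecules += 1
            # retain highest total base quality; tie -> smallest name
            keep = min(part, key=lambda t: (-t.qual_sum, t.name))
            for t in part:
                if t is not keep:
                    dup_names.add(t.name)
    report.duplicates_flagged = len(dup_names)
    return dup_names, report


def _out_mode(path: str) -> str:
    if path.endswith(".bam"):
        return "wb"
    if path.endswith(".cram"):
        return "wc"
    return "wh"


def mark_duplicates(
    in_path: str,
    out_path: str,
    use_umi: bool = True,
    remove: bool = False,
) -> DedupReport:
    """Mark (or remove) PCR duplicates in a coordinate-sorted SAM/BAM file.

    With ``use_umi`` the UMI is taken from the read-name suffix after the
    last underscore and clustered per coordinate group; without it, every
    template in a coordinate group beyond the best one is a duplicate.
    Unmapped, secondary, and supplementary records pass through untouched.
    """
    templates, passthrough = _collect_templates(in_path, use_umi)
    dup_names, report = _select_duplicates(templates.values(), use_umi)
    report.passthrough_records = passthrough

    with pysam.AlignmentFile(in_path, check_sq=False) as src:
        with pysam.AlignmentFile(out_path, _out_mode(out_path), template=src) as dst:
            for aln in src:
                if _considered(aln):
                    flag = aln.query_name in dup_names
                    aln.is_duplicate = flag
                    if remove and flag:
                        continue
                dst.write(aln)
    return report


@dataclass(frozen=True)
class MoleculeCount:
    """Per-insert-sequence tally after small-RNA deduplication."""

    sequence: str
    molecule_count: int
    read_count: int


def dedup_smallrna(
    reads: Iterable[ExtractedRead],
) -> tuple[list[ExtractedRead], list[MoleculeCount]]:
    """Collapse small-RNA reads to molecules.

    Reads are grouped by exact insert sequence; within a group UMIs are
    clustered with the directional graph.  One representative read per
    cluster is returned (highest mean base quality, tie broken on read
    id), along with a per-sequence table of molecule and read counts.
    """
    by_seq: dict[str, list[ExtractedRead]] = defaultdict(list)
    for r in reads:
        if not r.accepted:
            continue
        by_seq[r.insert_seq].append(r)

    unique_reads: list[ExtractedRead] = []
    table: list[MoleculeCount] = []
    for seq in sorted(by_seq):
        members = by_seq[seq]
        counts = Counter(r.umi for r in members)
        clusters = cluster_umis(counts)
        rep_of = {u: c.representative for c in clusters for u in c.members}
        by_cluster: dict[str, list[ExtractedRead]] = defaultdict(list)
        for r in members:
            by_cluster[rep_of[r.umi]].append(r)
        for rep in sorted(by_cluster):
            group = by_cluster[rep]
            keep = min(group, key=lambda r: (-sum(ord(q) for q in r.insert_quals), r.read_id))
            unique_reads.append(keep)
        table.append(MoleculeCount(seq, len(clusters), len(members)))
    return unique_reads, table
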
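"""Read reformatting: parse raw reads into (UMI, insert) per the adapter layouts.

Accepted reads get their combined UMI appended to the read name
(``name_UMI``) so downstream duplicate marking can recover it from
alignment records without auxiliary files.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import pysam

from .layouts import RnaSeqLayout, SmallRnaLayout

ACCEPTED = "accepted"


@dataclass(frozen=True)
class FastqRecord:
    name: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"record {self.name!r}: sequence/quality length mismatch")


@dataclass(frozen=True)
class ExtractedRead:
    """A read after UMI/locator parsing."""

    read_id: str
    umi: str
    insert_seq: str
    insert_quals: str
    status: str  # ACCEPTED or a rejection reason
    source_layout: str  # "rnaseq" | "smallrna"

    @property
    def accepted(self) -> bool:
        return self.status == ACCEPTED


@dataclass
class ExtractionReport:
    """Per-run accounting: total = accepted + sum of per-reason rejections."""

    total: int = 0
    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)

    def add(self, status: str) -> None:
        self.total += 1
        if status == ACCEPTED:
            self.accepted += 1
        else:
            self.rejected[status] += 1

    def to_tsv(self) -> str:
        lines = [f"total\t{self.total}", f"accepted\t{self.accepted}"]
        for reason in sorted(self.rejected):
            lines.append(f"rejected_{reason}\t{self.rejected[reason]}")
        return "\n".join(lines) + "\n"


def tag_read_name(read_id: str, umi: str) -> str:
    """Append ``_UMI`` to the token before the first whitespace."""
    if not umi or any(c not in "ACGT" for c in umi):
        raise ValueError(f"invalid UMI {umi!r}")
    head, sep, rest = read_id.partition(" ")
    if "\t" in head:
        head, sep, rest = read_id.partition("\t")
    return f"{head}_{umi}{sep}{rest}"


def parse_umi_from_name(read_id: str) -> str:
    """Inverse of :func:`tag_read_name`: UMI = suffix after the last ``_``."""
    head = read_id.split()[0]
    if "_" not in head:
        raise ValueError(f"read name {read_id!r} carries no UMI suffix")
    umi = head.rsplit("_", 1)[1]
    if not umi or any(c not in "ACGT" for c in umi):
        raise ValueError(f"read name {read_id!r} carries no valid UMI suffix")
    return umi


def _reject_pair(r1: FastqRecord, r2: FastqRecord, reason: str) -> tuple[ExtractedRead, ExtractedRead]:
    return (
        ExtractedRead(r1.name, "", r1.sequence, r1.quality, reason, "rnaseq"),
        ExtractedRead(r2.name, "", r2.sequence, r2.quality, reason, "rnaseq"),
    )


def _mate_token(name: str) -> str:
    tok = name.split()[0]
    if tok.endswith("/1") or tok.endswith("/2"):
        tok = tok[:-2]
    return tok


def reformat_rnaseq_pair(
    read1: FastqRecord, read2: FastqRecord, layout: RnaSeqLayout | None = None
) -> tuple[ExtractedRead, ExtractedRead]:
    """Parse one RNA-seq read pair.

    Positions 1-5 of each mate are its UMI half, 6-8 the locator, 9 the
    ligation base; the locator must be an exact member of the allowed set.
    The ligation base is trimmed but not validated.  The combined UMI
    (mate1 UMI + mate2 UMI) is attached to both output records.
    """
    layout = layout or RnaSeqLayout()
    if _mate_token(read1.name) != _mate_token(read2.name):
        raise ValueError(f"mismatched read IDs: {read1.name!r} vs {read2.name!r}")

    t = layout.trim_length
    if len(read1.sequence) < t or len(read2.sequence) < t:
        return _reject_pair(read1, read2, "short_read")

    u, l = layout.umi_length, layout.locator_length
    umis, locators = [], []
    for r in (read1, read2):
        seq = r.sequence.upper()
        umis.append(seq[:u])
        locators.append(seq[u : u + l])
    if any(loc not in layout.allowed_locators for loc in locators):
        return _reject_pair(read1, read2, "bad_locator")
    if any("N" in umi for umi in umis):
        return _reject_pair(read1, read2, "n_in_umi")

    combined = umis[0] + umis[1]
    out = []
    for r in (read1, read2):
        out.append(
            ExtractedRead(
                r.name, combined, r.sequence[t:], r.quality[t:], ACCEPTED, "rnaseq"
            )
        )
    return out[0], out[1]


def find_adapter(sequence: str, layout: SmallRnaLayout) -> int:
    """Leftmost start of the 3' adapter prefix in ``sequence``, or -1.

    Matches the first ``adapter_match_length`` bases of the configured
    adapter, allowing ``adapter_mismatches`` substitutions.
    """
    probe = layout.adapter3[: layout.adapter_match_length].upper()
    seq = sequence.upper()
    n, k = len(seq), len(probe)
    if k == 0:
        raise ValueError("adapter sequence is empty")
    if layout.adapter_mismatches == 0:
        return seq.find(probe)
    for i in range(n - k + 1):
        mm = sum(1 for a, b in zip(seq[i : i + k], probe) if a != b)
        if mm <= layout.adapter_mismatches:
            return i
    return -1


def _smallrna_locator_umi(
    five_block: str, three_block: str, layout: SmallRnaLayout
) -> str | None:
    """Combined 18-nt UMI if both locator blocks validate, else None."""
    mm3 = layout.three_prime_scheme.mismatches(three_block)
    best5 = min(s.mismatches(five_block) for s in layout.five_prime_schemes)
    if layout.mismatch_budget == "per-block":
        ok = best5 <= layout.locator_mismatches and mm3 <= layout.locator_mismatches
    else:
        ok = best5 + mm3 <= layout.locator_mismatches
    if not ok:
        return None
    # All schemes share the N layout, so either 5' scheme extracts the same bases.
    return layout.five_prime_schemes[0].extract_umi(five_block) + layout.three_prime_scheme.extract_umi(three_block)


def reformat_smallrna_read(
    read: FastqRecord, layout: SmallRnaLayout | None = None
) -> ExtractedRead:
    """Parse one small RNA-seq read.

    The 3' sequencing adapter is located and removed; the first and last
    15 nt of the remainder are the UMI blocks, the middle is the insert.
    A read is accepted iff both locator blocks validate, the insert length
    is within bounds, and no UMI base is N.
    """
    layout = layout or SmallRnaLayout()
    seq = read.sequence.upper()

    def reject(reason: str) -> ExtractedRead:
        return ExtractedRead(read.name, "", read.sequence, read.quality, reason, "smallrna")

    hit = find_adapter(seq, layout)
    if hit < 0:
        return reject("no_adapter")
    remainder = seq[:hit]
    quals = read.quality[:hit]
    b = layout.umi_block_length
    if len(remainder) < layout.min_trimmed_length:
        return reject("short_read")

    five_block, three_block = remainder[:b], remainder[-b:]
    insert, insert_quals = remainder[b:-b], quals[b:-b]
    umi = _smallrna_locator_umi(five_block, three_block, layout)
    if umi is None:
        return reject("bad_locator")
    if not layout.insert_min <= len(insert) <= layout.insert_max:
        return reject("length_filter")
    if "N" in umi:
        return reject("n_in_umi")
    return ExtractedRead(read.name, umi, insert, insert_quals, ACCEPTED, "smallrna")


# ---------------------------------------------------------------------------
# file-level drivers


def read_fastq(path: str) -> Iterator[FastqRecord]:
    """Iterate FASTQ records (plain or gzipped) via pysam/htslib."""
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            name = entry.name if entry.comment is None else f"{entry.name} {entry.comment}"
            if entry.quality is None:
                raise ValueError(f"record {entry.name!r} has no quality string (FASTA input?)")
            yield FastqRecord(name, entry.sequence, entry.quality)


def _open_out(path: str) -> IO[str]:
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_fastq(records: Iterable[FastqRecord], handle: IO[str]) -> None:
    for r in records:
        handle.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def _as_fastq(x: ExtractedRead) -> FastqRecord:
    return FastqRecord(tag_read_name(x.read_id, x.umi), x.insert_seq, x.insert_quals)


def reformat_fastq_files(
    r1_path: str,
    r2_path: str,
    out1_path: str,
    out2_path: str,
    layout: RnaSeqLayout | None = None,
) -> ExtractionReport:
    """Reformat a paired-end RNA-seq FASTQ pair; returns the run report."""
    layout = layout or RnaSeqLayout()
    report = ExtractionReport()
    it1, it2 = read_fastq(r1_path), read_fastq(r2_path)
    with _open_out(out1_path) as o1, _open_out(out2_path) as o2:
        for r1 in it1:
            r2 = next(it2, None)
            if r2 is None:
                raise ValueError(f"{r2_path} ended before {r1_path} (unpaired record {r1.name!r})")
            x1, x2 = reformat_rnaseq_pair(r1, r2, layout)
            report.add(x1.status)
            if x1.accepted:
                write_fastq([_as_fastq(x1)], o1)
                write_fastq([_as_fastq(x2)], o2)
    if next(it2, None) is not None:
        raise ValueError(f"{r1_path} ended before {r2_path}")
    return report


def reformat_smallrna_file(
    in_path: str, out_path: str, layout: SmallRnaLayout | None = None
) -> ExtractionReport:
    """Reformat a single-end small RNA-seq FASTQ file; returns the run report."""
    layout = layout or SmallRnaLayout()
    report = ExtractionReport()
    with _open_out(out_path) as out:
        for rec in read_fastq(in_path):
            x = reformat_smallrna_read(rec, layout)
            report.add(x.status)
            if x.accepted:
                write_fastq([_as_fastq(x)], out)
    return report
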
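"""Synthetic FASTQ/SAM fixtures with known ground truth.

The generator builds reads that follow the RNA-seq or small RNA-seq
adapter layout exactly, then optionally corrupts them (locator
substitutions, frame-shifting indels, single-base UMI errors) while
recording per read what extraction and deduplication *should* decide.
Ground truth is constructed directly from the layout definitions — never
by running the extraction code under test.

Inserts are random sequences with no genome behind them; the emitted SAM
reference is synthetic, since coordinate grouping rather than alignment
accuracy is what downstream consumers exercise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .extract import FastqRecord, tag_read_name, write_fastq
from .layouts import RnaSeqLayout, SmallRnaLayout

BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters for one synthetic library."""

    layout: str  # "rnaseq" | "smallrna"
    n_molecules: int = 10
    read_multiplicity: int | Sequence[int] = 1  # reads per molecule
    umi_error_rate: float = 0.0  # per read: one-base UMI corruption
    locator_corruption_rate: float = 0.0  # per read: locator broken -> reject
    indel_injection_rate: float = 0.0  # per read: frameshift in UMI region -> reject
    insert_length: tuple[int, int] = (20, 30)
    reference_length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in ("rnaseq", "smallrna"):
            raise ValueError("layout must be 'rnaseq' or 'smallrna'")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        for name in ("umi_error_rate", "locator_corruption_rate", "indel_injection_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")

    def multiplicities(self) -> list[int]:
        if isinstance(self.read_multiplicity, int):
            return [self.read_multiplicity] * self.n_molecules
        m = list(self.read_multiplicity)
        if len(m) != self.n_molecules:
            raise ValueError("read_multiplicity list length != n_molecules")
        return m


@dataclass
class Fixture:
    """Generated reads plus their ground truth."""

    spec: FixtureSpec
    reads1: list[FastqRecord]
    reads2: list[FastqRecord] | None
    truth: pd.DataFrame  # read_id, molecule_id, true_umi, observed_umi, is_duplicate, expected_status
    molecules: list[dict] = field(default_factory=list)


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def _point_mutation(rng: random.Random, seq: str, pos: int) -> str:
    alt = rng.choice([b for b in BASES if b != seq[pos]])
    return seq[:pos] + alt + seq[pos + 1 :]


def _mutate_one_base(rng: random.Random, seq: str) -> str:
    return _point_mutation(rng, seq, rng.randrange(len(seq)))


# --- RNA-seq ---------------------------------------------------------------

_BAD_LOCATORS = ("AAA", "CCC", "TTT", "GAG")  # guaranteed non-members


def _truth_row(read_id, mol, umi, obs, dup, status):
    return {
        "read_id": read_id,
        "molecule_id": mol,
        "true_umi": umi,
        "observed_umi": obs,
        "is_duplicate": dup,
        "expected_status": status,
    }


def make_rnaseq_fixture(spec: FixtureSpec) -> Fixture:
    """Paired-end RNA-seq reads following the UMI(5)+locator(3)+T layout."""
    if spec.layout != "rnaseq":
        raise ValueError("spec.layout must be 'rnaseq'")
    rng = random.Random(spec.seed)
    layout = RnaSeqLayout()
    locators = sorted(layout.allowed_locators)
    reads1: list[FastqRecord] = []
    reads2: list[FastqRecord] = []
    rows: list[dict] = []
    molecules: list[dict] = []

    lo, hi = spec.insert_length
    for mol_id, mult in enumerate(spec.multiplicities()):
        umi1, umi2 = _rand_seq(rng, 5), _rand_seq(rng, 5)
        ins1, ins2 = _rand_seq(rng, rng.randint(lo, hi)), _rand_seq(rng, rng.randint(lo, hi))
        molecules.append({"molecule_id": mol_id, "umi": umi1 + umi2, "insert1": ins1, "insert2": ins2})
        for rep in range(mult):
            rid = f"mol{mol_id}.r{rep}"
            loc1, loc2 = rng.choice(locators), rng.choice(locators)
            ou1, ou2 = umi1, umi2
            status = "accepted"
            if rng.random() < spec.umi_error_rate:
                if rng.random() < 0.5:
                    ou1 = _mutate_one_base(rng, ou1)
                else:
                    ou2 = _mutate_one_base(rng, ou2)
            s1 = ou1 + loc1 + "T" + ins1
            s2 = ou2 + loc2 + "T" + ins2
            if rng.random() < spec.locator_corruption_rate:
                bad = rng.choice(_BAD_LOCATORS)
                s1 = s1[:5] + bad + s1[8:]
                status = "bad_locator"
            elif rng.random() < spec.indel_injection_rate:
                # drop the first base: the locator frame shifts left
                s1 = s1[1:] + rng.choice(BASES)
                # guard against the shifted window forming a valid locator
                if s1[5:8] in layout.allowed_locators:
                    s1 = s1[:5] + _point_mutation(rng, s1, 5)[5] + s1[6:]
                status = "bad_locator"
            reads1.append(FastqRecord(rid, s1, "I" * len(s1)))
            reads2.append(FastqRecord(rid, s2, "I" * len(s2)))
            rows.append(_truth_row(rid, mol_id, umi1 + umi2, ou1 + ou2, rep > 0, status))
    return Fixture(spec, reads1, reads2, pd.DataFrame(rows), molecules)


# --- small RNA-seq ---------------------------------------------------------


def _fill_pattern(rng: random.Random, pattern: str) -> str:
    return "".join(rng.choice(BASES) if c == "N" else c for c in pattern)


def make_smallrna_fixture(spec: FixtureSpec) -> Fixture:
    """Single-end small RNA reads: 5' UMI block + insert + 3' UMI block + adapter."""
    if spec.layout != "smallrna":
        raise ValueError("spec.layout must be 'smallrna'")
    rng = random.Random(spec.seed)
    layout = SmallRnaLayout()
    five_patterns = [s.pattern for s in layout.five_prime_schemes]
    three_pattern = layout.three_prime_scheme.pattern
    lo = max(spec.insert_length[0], layout.insert_min)
    hi = min(spec.insert_length[1], layout.insert_max)

    reads: list[FastqRecord] = []
    rows: list[dict] = []
    molecules: list[dict] = []
    for mol_id, mult in enumerate(spec.multiplicities()):
        pat5 = rng.choice(five_patterns)
        block5 = _fill_pattern(rng, pat5)
        block3 = _fill_pattern(rng, three_pattern)
        insert = _rand_seq(rng, rng.randint(lo, hi))
        scheme5 = layout.five_prime_schemes[five_patterns.index(pat5)]
        true_umi = scheme5.extract_umi(block5) + layout.three_prime_scheme.extract_umi(block3)
        molecules.append({"molecule_id": mol_id, "umi": true_umi, "insert": insert})
        for rep in range(mult):
            rid = f"mol{mol_id}.r{rep}"
            b5, b3 = block5, block3
            status = "accepted"
            if rng.random() < spec.umi_error_rate:
                # flip one N-position base: UMI changes, read stays acceptable
                pos = rng.choice(scheme5.umi_positions)
                b5 = _point_mutation(rng, b5, pos)
            if rng.random() < spec.locator_corruption_rate:
                # two fixed-position errors defeat the 1-mismatch allowance
                # of the built scheme (and the alternative scheme differs at
                # every fixed position, so it cannot rescue the block)
                p1, p2 = rng.sample(scheme5.fixed_positions, 2)
                b5 = _point_mutation(rng, _point_mutation(rng, b5, p1), p2)
                status = "bad_locator"
            elif rng.random() < spec.indel_injection_rate:
                # delete the first base: both locator frames shift
                b5 = b5[1:] + insert[0]
                insert_shifted = insert[1:]
                seq = b5 + insert_shifted + b3 + layout.adapter3
                status = "bad_locator"
                obs_umi = ""
                reads.append(FastqRecord(rid, seq, "I" * len(seq)))
                rows.append(_truth_row(rid, mol_id, true_umi, obs_umi, rep > 0, status))
                continue
            obs_umi = scheme5.extract_umi(b5) + layout.three_prime_scheme.extract_umi(b3)
            seq = b5 + insert + b3 + layout.adapter3
            reads.append(FastqRecord(rid, seq, "I" * len(seq)))
            rows.append(
                _truth_row(rid, mol_id, true_umi, obs_umi if status == "accepted" else "", rep > 0, status)
            )
    return Fixture(spec, reads, None, pd.DataFrame(rows), molecules)


def make_fixture(spec: FixtureSpec) -> Fixture:
    if spec.layout == "rnaseq":
        return make_rnaseq_fixture(spec)
    return make_smallrna_fixture(spec)


# --- SAM emission ----------------------------------------------------------


def emit_sam(fixture: Fixture, out_sam: str, out_fasta: str | None = None) -> None:
    """Write the fixture as aligned, properly paired SAM plus a toy reference.

    Each molecule gets its own locus (spaced along one synthetic
    reference), so reads from one molecule share a coordinate group and
    different molecules never collide.  Read names carry the observed UMI
    so duplicate marking can run directly on the output.
    """
    if fixture.spec.layout != "rnaseq":
        raise ValueError("SAM emission is defined for rnaseq fixtures")
    spacing = 200
    ref_len = max(fixture.spec.reference_length, spacing * (len(fixture.molecules) + 2))
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "synthetic_ref", "LN": ref_len}],
    }
    truth = fixture.truth.set_index("read_id")
    entries = []
    for r1, r2 in zip(fixture.reads1, fixture.reads2 or []):
        row = truth.loc[r1.name]
        if row.expected_status != "accepted":
            continue
        mol = fixture.molecules[int(row.molecule_id)]
        pos1 = spacing * (int(row.molecule_id) + 1)
        ins1, ins2 = mol["insert1"], mol["insert2"]
        pos2 = pos1 + 120
        name = tag_read_name(r1.name, str(row.observed_umi))
        entries.append((pos1, name, ins1, ins2, pos2))

    with pysam.AlignmentFile(out_sam, "wh", header=header) as out:
        for pos1, name, ins1, ins2, pos2 in sorted(entries):
            a1 = pysam.AlignedSegment(out.header)
            a1.query_name = name
            a1.query_sequence = ins1
            a1.flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate-reverse, first
            a1.reference_id = 0
            a1.reference_start = pos1
            a1.mapping_quality = 60
            a1.cigarstring = f"{len(ins1)}M"
            a1.next_reference_id = 0
            a1.next_reference_start = pos2
            a1.template_length = pos2 + len(ins2) - pos1
            a1.query_qualities = pysam.qualitystring_to_array("I" * len(ins1))

            a2 = pysam.AlignedSegment(out.header)
            a2.query_name = name
            a2.query_sequence = ins2
            a2.flag = 0x1 | 0x2 | 0x10 | 0x80  # paired, proper, reverse, second
            a2.reference_id = 0
            a2.reference_start = pos2
            a2.mapping_quality = 60
            a2.cigarstring = f"{len(ins2)}M"
            a2.next_reference_id = 0
            a2.next_reference_start = pos1
            a2.template_length = -(pos2 + len(ins2) - pos1)
            a2.query_qualities = pysam.qualitystring_to_array("I" * len(ins2))
            out.write(a1)
            out.write(a2)

    if out_fasta is not None:
        seq = "".join(random.Random(fixture.spec.seed).choice(BASES) for _ in range(ref_len))
        with open(out_fasta, "w") as fh:
            fh.write(">synthetic_ref\n")
            for i in range(0, ref_len, 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fixture(fixture: Fixture, out_dir: str) -> dict[str, str]:
    """Write FASTQ(s) and the ground-truth table; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    if fixture.spec.layout == "rnaseq":
        p1, p2 = out / "reads_R1.fastq", out / "reads_R2.fastq"
        with open(p1, "w") as fh:
            write_fastq(fixture.reads1, fh)
        with open(p2, "w") as fh:
            write_fastq(fixture.reads2 or [], fh)
        paths["r1"], paths["r2"] = str(p1), str(p2)
    else:
        p = out / "reads.fastq"
        with open(p, "w") as fh:
            write_fastq(fixture.reads1, fh)
        paths["reads"] = str(p)
    tpath = out / "ground_truth.tsv"
    fixture.truth.to_csv(tpath, sep="\t", index=False)
    paths["truth"] = str(tpath)
    return paths
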
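# Methods

## The problem

PCR duplicates — multiple sequenced reads amplified from one original
cDNA molecule — inflate apparent abundance in RNA-seq and small RNA-seq
libraries. Unique molecular identifiers (UMIs), random-nucleotide tags
ligated to each molecule before amplification, let duplicates be told
apart from genuinely identical molecules. umikit implements the three
computational pieces of a UMI workflow: extracting UMIs from raw reads,
identifying duplicates through a directional UMI graph, and a
Monte-Carlo simulator that quantifies when UMI error correction matters.

## Adapter layouts and UMI locators

Both supported layouts interleave the random UMI bases with short fixed
*locator* sequences. The locator anchors the UMI reading frame: an
insertion or deletion in or near the UMI shifts the locator out of
register and shows up as locator mismatches, so indel-bearing reads can
be discarded rather than entering the UMI space as phantom molecules.
This is why UMI comparison downstream can use plain Hamming distance.

**RNA-seq (paired-end).** Each mate begins with a 5-nt UMI, a 3-nt
locator from the set {GGG, TCA, ATC} (three alternatives, pooled, to
keep early sequencing cycles diverse), and the ligation thymidine —
a 9-nt prefix. The locator must match exactly; the ligation T is trimmed
but *not* validated, since a sequencing error at one fixed position
should not discard an otherwise valid read and no such filter is part of
the layout's definition. The combined 10-nt UMI is mate1-UMI followed by
mate2-UMI; the order is a convention (any fixed order is equivalent for
deduplication). Rejection reasons: `short_read`, `bad_locator`,
`n_in_umi` (an N would masquerade as extra UMI diversity).

**Small RNA-seq (single-end).** After 3'-adapter removal, the first and
last 15 nt of the read are UMI blocks of the form `NNN-xxx-NNN-yyy-NNN`
(9 random + 6 fixed bases each); the middle is the insert. Two
alternative 5' locator sets (`NNNCGANNNTACNNN`, `NNNATCNNNAGTNNN`) and
one 3' set (`NNNGTCNNNTAGNNN`) are recognised, each allowing one
mismatch across its fixed positions. The 1-mismatch allowance is applied
*per block* by default; a shared budget across both blocks is available
via `mismatch_budget="total"` — the per-block reading follows from each
pattern being validated as a separate entity. Insert length must fall in
the gel-purification window 18–35 nt (configurable). Adapter location is
an exact, leftmost match of the first 10 nt of the configured adapter
sequence (match length and mismatch allowance configurable); reads
without a hit are rejected (`no_adapter`).

Qualities are carried through untouched; no quality trimming is
performed.

## Directional UMI graph

Within a read group (same mapping coordinates for RNA-seq; identical
insert sequence for small RNA, which can arise from many loci), each
distinct UMI is a node holding its read count. For UMIs a, b at Hamming
distance 1, a directed edge a→b is added when

    n_a >= 2 * n_b - 1.

The twofold factor is the worst case of an error in the first PCR cycle
(the erroneous lineage can at most match half the parent's copies); the
−1 lets 1-vs-1 singletons connect, where the error most plausibly arose
at sequencing. Nodes are visited most-abundant-first (ties broken
lexicographically); each unvisited node seeds a cluster and claims, by
breadth-first traversal through unvisited nodes, everything reachable
along directed edges. Each cluster is one inferred molecule; its
representative is the seed. Chains a→b→c therefore collapse onto a —
two or more UMI errors are corrected provided the intermediate UMIs are
observed.

Traversal choices the edge rule does not fix — the total visiting order
and first-claim-wins assignment of nodes reachable from two seeds — are
pinned down as above for determinism, and the whole procedure is tested
against a brute-force re-implementation over all-random small groups.

One property worth noting: cluster counts are *not* monotone under
adding reads to an arbitrary UMI. {X:3, Y:2} is one cluster (3 ≥ 2·2−1)
but {X:3, Y:3} is two (3 < 2·3−1): extra reads on a minor UMI can
promote it to an independent molecule. This is intended behaviour of the
count-ratio rule, not an artifact; monotonicity does hold when reads are
added to a group's most abundant UMI, and that restricted form is what
the property suite asserts.

## Duplicate marking

RNA-seq templates are grouped by (reference, per-mate orientation,
per-mate unclipped 5' coordinate) — unclipped so that soft-clipping
differences do not split a group; the mate pair is sorted inside the key
so mate order in the file is irrelevant. Within each group, UMI clusters
are resolved and one template per cluster is kept: highest summed base
quality, ties broken by read name. All others receive the standard
duplicate flag (0x400); flagging rather than removal is the
non-destructive default (`--remove` drops them). Unmapped, secondary and
supplementary records pass through unconsidered. A coordinate-only mode
(`--no-umi`) applies the same grouping and retention with every group
treated as one molecule, for comparisons of UMI-aware against
coordinate-only deduplication.

Small-RNA deduplication replaces the coordinate key with the exact
insert sequence and reports, per sequence, the molecule count (number of
UMI clusters) and read count.

## The simulator

Seven parameters, with the **baseline condition** as defaults:

| parameter | meaning | baseline |
|---|---|---|
| `n_initial` | starting molecules | 100 |
| `umi_length` | UMI length, nt | 18 |
| `n_cycles` | PCR cycles | 10 |
| `min_amp_prob` (m) | lower bound of per-cycle duplication probability | 0.8 |
| `pcr_error_rate` | per-nt substitution probability per duplication | 3×10⁻⁵ |
| `seq_error_rate` | per-nt substitution probability at sequencing | 10⁻³ |
| `seq_depth` | molecules sequenced | 100 |

Each molecule's duplication probability is redrawn per molecule per
cycle from Uniform(m, 1), making duplication marginally a
Bernoulli((1+m)/2) event and the expected pool size
n_initial·((3+m)/2)^n_cycles — 61,310 at baseline. The alternative
reading, one probability per molecule lifetime, is available as
`amp_prob_mode="per-lifetime"`; it yields a different pool-size law and
is not the default because only per-cycle redrawing reproduces the
baseline pool mean of about 61,000. (Describing the per-cycle
*efficiency* of Uniform(m,1) as "(1−m)/2" is a slip one sometimes sees;
its mean is (1+m)/2.)

Errors are simulated on the UMI only; the insert is one fixed locus, so
insert errors could not affect any computed metric. Substitutions pick
uniformly among the three alternative bases. Sequencing samples
`seq_depth` molecules *without* replacement (physical molecules are
consumed; at 100 from ~61,000 the with/without distinction is
negligible anyway). Truth is defined by founder identity, not UMI
string, so founder UMI collisions — relevant at short UMI lengths —
count against the estimator exactly as they would in a real library.

Per trial, three quantities are scored over the sequenced reads: truth
(distinct founders), the uncorrected estimate (distinct observed UMI
strings) and the corrected estimate (directional-graph clusters), with
duplicate fractions (depth − count)/depth and relative errors
(estimate − truth)/truth.

**Engines.** The default engine compresses the pool into (founder, UMI)
groups with counts: molecules within a group are exchangeable, so
per-group binomial draws for duplication and error events are
distributionally identical to per-molecule coin flips, and the erroneous
copies (which are rare) are expanded individually with a
truncated-binomial draw of their error count. A literal per-molecule
engine (`engine="per-molecule"`) exists for cross-checking — the test
suite compares the two dup-fraction distributions with a two-sample
Kolmogorov–Smirnov test — and is the execution path for per-lifetime
mode, where molecules carry individual probabilities and are not
exchangeable.

**Reproducibility.** Per-trial seeds are spawned from the master seed
with `numpy.random.SeedSequence.spawn`, so trials are independent,
order-insensitive, and a sweep re-run with the same seed is identical.

## Library metrics

Per-feature duplicate fractions assign each primary alignment to every
feature it overlaps (no fractional assignment — the simplest defensible
rule, stated rather than hidden) and report the flagged fraction per
feature plus the median across features; features with zero assigned
reads are omitted. Feature intervals come from BED6 (0-based half-open)
or GFF3 (1-based closed, converted internally).

Cross-library reproducibility uses the coefficient of variation
CV = SD/mean per feature across libraries, with the sample (n−1) SD by
default (population SD via `ddof=0`; printed totals in the source
material cannot adjudicate the convention, so it is explicit and
configurable), and the **total CV** — the sum of per-feature CVs, a
single scalar per matrix. The irreproducibility count between two
libraries is the number of features with max/min ratio ≥ a fold
threshold (default 1.25, i.e. a ≥25% difference); features observed in
exactly one library count as differing, features observed in neither are
excluded (both choices configurable).

## Fixture generator

Fixtures emulate the *structure* UMI processing assumes — known
molecules, known UMIs, controlled read multiplicities, and controlled
corruption (locator damage, frame-shifting indels, single-base UMI
errors) — with ground truth recorded per read from the layout
definitions, never by running the extraction code under test. They do
not emulate base-quality profiles, instrument artifacts, or
polymerase-specific error spectra, so passing fixture tests shows
layout/graph logic is correct, not that real libraries will behave.
Inserts are random sequences with no genome; the emitted SAM places each
molecule at its own locus on a synthetic reference, since coordinate
grouping rather than alignment accuracy is what is under test. All
fixtures are generated programmatically at test time.

## Problem sizes and tolerances

The bundled acceptance script runs 10,000 trials per condition (about
40 s total); the test suite's simulation checks run at 2,000-trial smoke
scale, where the Monte-Carlo standard error of a duplicate-fraction mean
is ~0.07 percentage points, comfortably inside the 0.5-point bands the
checks assert. Trend checks (cycle-count invariance, monotonicity in
starting material and depth) use 400 trials per grid point, enough for
orderings driven by multi-point effects. The graph oracle comparison
enumerates 10,000 random small groups exhaustively checkable by brute
force.

## Known limitations

- Multi-mapping reads are taken at their primary alignment; no
  multi-mapping resolution.
- Small-RNA processing is single-end only.
- The simulator models one locus and no amplification-efficiency decay,
  GC bias, or chimera formation.
- The relaxed graph variant connecting UMIs two or more substitutions
  apart is not implemented.
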
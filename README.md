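# umikit

UMI processing for bulk RNA-seq and small RNA-seq: extraction of unique
molecular identifiers (UMIs) from raw reads using UMI-locator adapter
layouts, PCR-duplicate identification through a directional UMI graph,
and a Monte-Carlo simulator of PCR amplification and sequencing that
quantifies when UMI error correction matters.

## Who this is for

Anyone building or analysing UMI-tagged sequencing libraries who needs
to (a) turn raw FASTQ reads into UMI-tagged, adapter-trimmed reads,
(b) mark or remove PCR duplicates in aligned data with UMI awareness,
or (c) reason quantitatively about how starting material, PCR cycles,
sequencing depth and error rates determine the PCR-duplicate fraction
and the accuracy of UMI-based duplicate detection.

## The core method

**Extraction.** Reads follow fixed adapter layouts in which random UMI
bases are anchored by short pre-defined *locator* sequences (RNA-seq:
5-nt UMI + locator ∈ {GGG, TCA, ATC} + ligation T per mate, combined
10-nt UMI; small RNA-seq: two 15-nt `NNN-xxx-NNN-yyy-NNN` blocks
flanking the insert, combined 18-nt UMI). A read whose locators do not
validate — including any read with an indel in the UMI region, which
shifts the locator frame — is discarded, so UMIs downstream are
fixed-length and substitution-only.

**Directional graph.** Within a read group (same mapping coordinates,
or identical sequence for small RNA), distinct UMIs are nodes with read
counts n. For UMIs at Hamming distance 1 an edge a→b is drawn when

    n_a ≥ 2·n_b − 1,

i.e. b is consistent with being an amplified error of a. Clusters are
claimed from the most abundant node outward; each cluster is one
molecule, and all but one read per cluster are PCR duplicates.

**Simulation.** Molecules tagged with random UMIs are amplified for
`n_cycles`; each molecule duplicates per cycle with probability drawn
from Uniform(m, 1), copies acquire UMI substitutions at the PCR error
rate, `seq_depth` molecules are sequenced (without replacement) through
a substitution channel, and the true duplicate fraction is compared
with the UMI-based estimates with and without graph correction.

See `docs/methods.md` for assumptions, parameter meanings and numerical
choices.

## Worked example

Simulate the baseline condition (100 molecules, 18-nt UMIs, 10 cycles,
m = 0.8, PCR error 3×10⁻⁵, sequencing error 10⁻³, depth 100):

```python
from umikit import SimParams, run_experiment

summary = run_experiment(SimParams(n_trials=2000, seed=7))
for metric in ("pool_size", "dup_frac_truth", "dup_frac_uncorrected",
               "dup_frac_corrected", "rel_err_uncorrected", "rel_err_corrected"):
    print(f"{metric:22s} {summary.mean[metric]:10.4f}  ± {summary.sd[metric]:.4f}")
```

prints

```
pool_size              61322.6335  ± 1429.1603
dup_frac_truth             0.3775  ± 0.0317
dup_frac_uncorrected       0.3643  ± 0.0330
dup_frac_corrected         0.3773  ± 0.0317
rel_err_uncorrected        0.0213  ± 0.0184
rel_err_corrected          0.0003  ± 0.0023
```

Ten cycles at m = 0.8 amplify 100 molecules into a pool of ~61,300.
Sequencing 100 of them, 37.7% of reads are true PCR duplicates.
Counting distinct raw UMIs underestimates that fraction (36.4%) because
UMI errors masquerade as extra molecules — a +2.1% relative error in
the molecule count — while directional-graph correction recovers the
truth almost exactly (37.7%, relative error 0.03%).

The same machinery runs from the shell:

```
umikit simulate --trials 2000 --seed 7 --out baseline.tsv
umikit simulate --trials 1000 --seed 7 --vary n_initial \
    --grid 50,100,200,400 --out sweep.tsv
```

A complete read-level round trip on synthetic data:

```
umikit make-fixture --layout rnaseq --n-molecules 50 --multiplicity 3 \
    --seed 1 --sam --out-dir fx
umikit reformat-fastq --r1 fx/reads_R1.fastq --r2 fx/reads_R2.fastq \
    --out1 fx/tagged_R1.fastq --out2 fx/tagged_R2.fastq
umikit mark-duplicates --in fx/reads.sam --out fx/marked.sam
```

Subcommands: `reformat-fastq`, `reformat-sra-fastq`, `mark-duplicates`,
`dedup-smallrna`, `simulate`, `dup-fraction`, `cv`, `irreproducible`,
`make-fixture`.

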
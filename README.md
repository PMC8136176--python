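# numt-sieve

Screening of protein-coding DNA barcode and metabarcode sequences for
apparent pseudogenes — in particular nuMTs, nuclear copies of
mitochondrial genes that co-amplify with the true mitochondrial marker
(e.g. COI) and inflate richness estimates in biodiversity surveys.

Once inserted into the nuclear genome a mitochondrial copy escapes both
the mitochondrial reading machinery and purifying selection, so it
accumulates frameshifting indels, premature stop codons and a drift
toward the AT-rich nuclear background. `numt-sieve` exploits exactly
these signatures with two dataset-relative filters:

1. **ORF-length outlier filtering** — every sequence is translated in
   all three plus-strand frames under the invertebrate mitochondrial
   code (NCBI table 5), its longest open reading frame is retained, and
   sequences whose longest-ORF length falls outside the Tukey fences

   `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`

   of the dataset's ORF lengths are removed (sequences yielding no
   qualifying ORF at all are likewise removed).

2. **Profile-HMM bit-score outlier filtering** (optional second stage) —
   the surviving longest-ORF amino-acid sequences are scored against a
   profile hidden Markov model built from a reference alignment of
   trusted barcodes. The reported score is the log-odds, in bits, of the
   forward likelihood under the profile versus an i.i.d. background:

   `bit = ( ln P(x | HMM) − ln P(x | null) ) / ln 2`

   Sequences whose bit score falls below the one-sided low fence
   `Q1 − 1.5·IQR` of the dataset's scores are removed.

The package also ships the machinery used to characterize these
filters: a seeded simulator that builds codon-clean COI-like communities
and converts a chosen fraction (default 19%) into simulated nuMTs by
GC→AT substitution (default −2.5 GC percentage points) or frameshift
indels (default 2.5% of bases), a sensitivity/specificity benchmark
harness, and supporting diagnostics (GC content, Nei–Gojobori dN/dS
with a synonymous-divergence exclusion rule, K2P distances,
neighbor-joining trees with bootstrap majority-rule consensus and
midpoint rooting).

## Worked example

Simulate a 200-sequence community in which 19% of the barcodes have been
turned into nuMTs by indel mutations, then filter and score the result:

```sh
$ numt-sieve simulate --n 200 --mode frameshift --numt-fraction 0.19 \
      --edit-rate 0.025 --seed 7 --out community.fasta --labels labels.tsv
$ numt-sieve filter --in community.fasta --method orf_only \
      --report report.tsv --kept kept.fasta --removed removed.fasta
INFO numt_sieve: removed 38 / 200 records; report -> report.tsv
$ numt-sieve evaluate --report report.tsv --labels labels.tsv \
      --method orf_only --mode frameshift --out metrics.tsv
$ cat metrics.tsv
method	mode	fragment	tp	fp	tn	fn	sensitivity	specificity
orf_only	frameshift		38	0	162	0	100.0	100.0
```

All 38 simulated nuMTs (19% of 200) were removed (sensitivity 100%) and
all 162 intact barcodes retained (specificity 100%): the intact
sequences share a full-length 657-nt reading frame, so the length fences
collapse onto 657 and every frame-broken copy falls below them.
The per-record report shows the measured diagnostics and fences:

```
record_id  kept  reason  orf_length_nt  bit_score  lower_fence_len  upper_fence_len  score_fence
seq_0000   True  ok      657                       657.0            657.0
```

The same workflow with `--method orf_hmm --hmm coi.phmm` adds the
bit-score stage; a model is built from a reference amino-acid alignment
with `numt-sieve build-hmm --aln ref.sto --out coi.phmm`.

The full benchmark over the frozen perturbation presets (full/half
length × GC→AT/frameshift × nuMT proportion 9.5/19/38%) is driven by:

```sh
numt-sieve experiment --n 1000 --seeds 1,2,3 --outdir experiment_out
```

which writes the per-dataset communities, labels, filter reports and a
`metrics.tsv` with mean sensitivity/specificity per method. Typical
behaviour: frameshifted nuMTs are detected far more reliably than
GC-shifted ones, halving amplicon length lowers sensitivity, doubling
the nuMT proportion collapses it (the fences themselves shift once
pseudogenes dominate the length distribution), while specificity stays
near 100% throughout.

## Library layout

| module              | contents                                              |
|---------------------|-------------------------------------------------------|
| `seqrecords`        | sequence/alignment types, FASTA & Stockholm I/O, GC   |
| `genetic_codes`     | NCBI tables 1 and 5, frame-aware translation          |
| `orffinder`         | plus-strand maximal-ORF extraction                    |
| `profile_hmm`       | profile-HMM build, forward-algorithm bit scores       |
| `pseudogene_filter` | IQR fences and the two-stage filter                   |
| `numt_simulator`    | community generator and nuMT perturbations            |
| `evaluation`        | confusion matrix, sensitivity/specificity             |
| `evolution_metrics` | NG86 dN/dS with exclusion rule, K2P distances         |
| `phylo`             | NJ trees, bootstrap consensus, midpoint root, Newick  |
| `cli`               | `numt-sieve` subcommands and the experiment driver    |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
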
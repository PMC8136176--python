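# Methods

This note documents the models and procedures implemented in
`numt-sieve`, the defaults they run with, and what the synthetic
benchmark does and does not demonstrate.

## The screening problem

Nuclear mitochondrial pseudogenes (nuMTs) are copies of mitochondrial
protein-coding sequence inserted into the nuclear genome. They amplify
with the same primers as the genuine marker (COI in the animal-barcoding
case) but, being released from function, accumulate frameshifts,
premature stop codons and AT-biased substitutions. In a metabarcoding
dataset they masquerade as extra species. `numt-sieve` removes them by
screening for loss of reading-frame integrity and loss of fit to a
protein profile — properties of the sequence itself, requiring no
taxonomic reference.

## ORF extraction

Sequences are translated in the three plus-strand frames only (barcode
protocols orient reads; the minus strand is out of scope). An ORF is a
*maximal stop-free run of complete codons*, bounded by stop codons or
the sequence ends — deliberately not anchored at ATG, because the
barcode amplicon is an arbitrary window of the gene and its first codon
is rarely a start. A `require_start` switch provides the stricter
convention. Minimum length is 30 nt, counted without the bounding stop
codon; both the threshold and its unit are parameters, since ORF-finder
conventions differ. Codons containing `N` translate to `X` and count as
sense codons (conservative toward keeping genes). With
`ignore_nested=True` (default), a candidate whose span — including its
bounding stop codon, when present — lies inside an already-retained
candidate's span in any frame is dropped; retention order is by length,
then smaller start, then smaller frame. Per record the longest ORF is
kept, ties broken the same way.

Coordinates everywhere are 0-based, half-open.

## Profile HMM

The model is the classic match/insert/delete profile over the 20 amino
acids, estimated from a reference multiple alignment:

* columns with gap fraction ≤ 0.5 become match states;
* match emissions are Laplace-smoothed column frequencies,
  `(count + 1) / (total + 20)`;
* insert emissions equal the background distribution;
* transition probabilities are counted from each row's observed state
  path with a pseudocount of 1 per transition type
  (M→M/M→I/M→D, I→M/I→I, D→M/D→D);
* the null model is the alignment-wide residue frequency,
  Laplace-smoothed.

Scoring uses the forward algorithm in log space (no scaling tricks are
needed at these model sizes; the delete-state chain is evaluated with a
prefix-sum in log space so the recursion stays vectorized). The default
alignment mode is local on the model side — uniform entry over match
states and free exit after any match state — so truncated amplicon
fragments are not penalized for missing model columns. A `glocal` mode
(entry through node 0, exit through node M, deletes absorbing missing
flanks) is available. In both modes the entire query is emitted and
paths begin and end on a match state; there are no flanking
(N/C-terminal) insert states, so a query carrying residues outside the
modelled region scores poorly — acceptable for amplicons that are
sub-windows of the modelled gene. `X` emits with probability 1 under
both model and null (score-neutral); `*` is rejected (a longest ORF
never contains one).

Deliberately out of scope: HMMER's Dirichlet-mixture priors, null2 bias
composition correction, E-values and file-format compatibility. The
filter consumes only the *rank order* of full-sequence bit scores
within one dataset, for which Laplace pseudocounts suffice; numeric
parity with HMMER scores is not claimed.

## Outlier fences

Quartiles use linear interpolation (R type 7, the numpy default).
Length outliers are two-sided (`Q1 − 1.5·IQR`, `Q3 + 1.5·IQR`):
frame-broken pseudogenes are short, but anomalously long ORFs are also
suspect. Score outliers are one-sided (low fence only): an unusually
*good* fit to the profile is unproblematic. Fences are recomputed per
input dataset, never fixed absolutely, and the verdict order is fixed:
no-ORF removal first, then length, then score, with the length fences
computed over the post-ORF survivors and the score fence over the
post-length survivors.

Edge behaviour: fewer than 4 surviving values make fences undefined
(`InsufficientDataError`, CLI exit 4). Identical values collapse the
fences onto the common value; records *at* a fence are kept (strict
inequality removes).

## Synthetic communities

The generator stands in for a large curated barcode collection. All
sequences are mutated descendants of one random ancestor, so the set is
alignable without an external aligner; each sequence is one pad base
plus `(length−1)/3` complete sense codons under the invertebrate
mitochondrial code, giving a clean full-length reading frame at offset 1
and no internal stops. Defaults: length 658 nt (the canonical COI
barcode), GC target 0.40 (animal mitochondrial range), per-site
divergence 0.05 from the ancestor (a mixed intra/inter-specific
community scale). Proposed substitutions that would create an in-frame
stop are reverted; rows drifting more than 5 GC points from target are
redrawn. All randomness flows from a single integer seed.

Perturbations convert `round(f·n)` uniformly chosen records into
simulated nuMTs:

* **GC→AT** — `k = round(rate·L)` distinct G/C sites substituted G→A and
  C→T (transition-like, the columnwise reading of "GC to AT"); GC
  content drops by exactly `k/L`. The default rate 0.025 therefore
  lowers GC by 2.5 *percentage points*; a relative-reduction variant and
  a uniform-A/T variant exist as flags but are off by default.
* **frameshift** — `k = round(rate·L)` indel events at distinct source
  positions, each independently an insertion of a uniform base (placed
  before the position) or a deletion with probability ½, resolved
  left-to-right on source coordinates.

Defaults follow the benchmark design: nuMT fraction 0.19, edit rate
0.025, with 0.38 and 0.095 as the stressed presets. Every edit is
recorded as provenance and replaying the edit list on the source
reproduces the perturbed sequence exactly. Fragment variants truncate
*every* record to its 5′ (`floor(L/2)` bases) or 3′ half after
perturbation, emulating short amplicons.

What the simulator does **not** model: transition/transversion bias,
codon-usage drift, selection on the gene partition, chimeras,
sequencing error, abundance structure, or the deep taxonomic divergence
of a real community (all sequences descend from one ancestor). Passing
the benchmark therefore demonstrates the *mechanics* of the filters —
fence placement, frame-breaking detection, the collapse at high
pseudogene load — not their field sensitivity on real communities, and
in particular says nothing about cryptic pseudogenes that preserve a
full-length frame.

## Benchmark metrics

A removed labelled pseudogene is a true positive, a retained labelled
gene a true negative; sensitivity = 100·tp/(tp+fn), specificity =
100·tn/(tn+fp), reported to one decimal. Fragment datasets are scored
separately for the 5′ and 3′ halves. The experiment driver runs the six
frozen presets (`full_gc`, `full_frameshift`, `half_gc`,
`half_frameshift`, `double_numt`, `half_numt`; the proportion presets
under both mutation modes) across seeds and reports per-seed and
mean tables. The expected qualitative pattern: frameshift mode is
detected far better than GC→AT mode (indels break the frame almost
surely, whereas GC→AT edits only sometimes create an in-frame stop);
halving amplicon length lowers frameshift-mode sensitivity; doubling the
nuMT fraction to 38% pushes the lower length quartile into the
pseudogene range, widening the IQR and collapsing sensitivity — the
fences themselves are contaminated; specificity stays near 100%.
The test suite asserts these orderings over 10 matched seeds at
community size 1000, a desk-scale stand-in chosen to keep the full
suite fast while leaving the orderings far from their decision
boundaries.

## dN/dS and distances

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous-site
fractions with stop-producing changes excluded from the denominators,
difference counts averaged over equally weighted mutational pathways
(pathways through stop codons discarded when any stop-free pathway
exists), sites averaged over the two sequences, and a Jukes–Cantor
multiple-hit correction. Codons containing a gap, an `N`, or a stop in
either sequence are pairwise-deleted. Pairs with synonymous divergence
ks < 0.01 (too similar for a stable ratio) or ks > 2 (saturated) are
excluded, as are pairs whose JC correction is undefined. NG86 was
chosen because it is fully specifiable; numeric parity with
Li-1993-family implementations (e.g. seqinr's `kaks`) is not expected,
and the ratio is used descriptively (pseudogenes drift toward 1, genes
sit well below it), not inferentially.

The K2P distance is `d = −½·ln((1−2P−Q)·√(1−2Q))` with transition (P)
and transversion (Q) fractions over pairwise-complete sites; arguments
≤ 0 raise a saturation error rather than returning a clamped value.

## Trees

Neighbor joining, bootstrap and consensus delegate to dendropy:
Saitou–Nei NJ on the K2P matrix (negative branch estimates clamped to 0
with a warning; the basal bifurcation collapsed so unrooted trees have
a degree-3 root), column bootstrap with replicates whose distances
saturate skipped and counted, plain >50% majority-rule consensus with
supports reported as percentages of replicates containing each
bipartition. Supports can alternatively be mapped onto the
original-alignment NJ phylogram (which retains branch lengths and can
be midpoint-rooted; the consensus topology carries no lengths, so the
CLI skips midpoint rooting there). Midpoint rooting ties are resolved
by dendropy's deterministic internal order; exact ties do not arise on
continuous distance data. Newick serialization keeps 12 significant
digits and stores supports as internal-node labels.

## Numerical and interface conventions

* Only `N` is accepted as a nucleotide ambiguity code; other IUPAC
  codes are rejected at parse time so translation and scoring never
  guess.
* FASTA parsing reports the offending line on error; Stockholm reading
  covers the minimal single-block dialect.
* The HMM text format round-trips bit-exact (floats serialized via
  `repr`).
* CLI exit codes: 0 success, 2 usage, 3 data error, 4 degenerate
  statistics. Every run logs its resolved configuration; identical
  configurations and seeds reproduce outputs byte-identically.

## Known limitations

* Cryptic pseudogenes — recent nuMTs with intact frames and near-gene
  scores — pass both filters by construction.
* Dataset-relative fences assume pseudogenes are a minority; at ~40%
  contamination the method degrades (demonstrated in the benchmark) and
  an absolute-threshold strategy would be needed.
* The HMM has no flanking states: queries containing residues outside
  the modelled region (e.g. primer read-through into non-coding
  sequence) are penalized beyond their true mismatch.
* Bit scores are dataset-relative ranks, not calibrated E-values.
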
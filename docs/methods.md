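# Methods

This note records the models and procedures implemented in `smallrna`,
the defaults and why they were chosen, the numerical conventions, and the
known limitations — in particular what the synthetic-data generator does
and does not emulate.

## Adapter trimming

A 3′ adapter match is either (a) the full adapter aligned to a substring
`read[s:t]`, or (b) an adapter prefix of length `L` aligned to the read
suffix `read[s:]` (the sequencer ran off the insert into the adapter).
Errors are unit-cost edits (substitutions and indels); a candidate
matching `L` adapter bases with `E` errors is admissible iff
`L ≥ min_overlap` and `E ≤ ⌊e·L⌋`. Among admissible candidates the winner
has minimal `E`, then the 5′-most start, then the earliest adapter in the
configured list; everything from the match start to the read end is
removed and the quality string is cut in lockstep.

Implementation: a fast path finds zero-error candidates by plain substring
search (the overwhelmingly common case); otherwise a semi-global dynamic
program computes, per adapter-prefix length and read position, the minimal
edit distance over all starts together with the smallest start achieving
it. The equivalence of this single-pass DP to exhaustive enumeration over
every `(start, length)` pair is asserted by tests against an independent
brute-force oracle on thousands of random reads.

Defaults: `e = 0.1`, `min_overlap = 3` (common trimmer practice);
`min_length = 15` inclusive (sub-15-nt inserts are too short to map
uniquely); quality filtering keeps reads with mean Phred ≥ 20 (the
criterion is deliberately a simple monotone mean; base-resolved quality
trimming is out of scope). `N` bases mismatch everything, including other
`N`s.

## Annotation cascade

References are searched with substitutions only (Hamming). This makes the
hit set exactly enumerable — the index is validated against a naive
all-positions scan — and keeps counts integral and deterministic;
indel-tolerant mapping of 15–40 nt reads against short references buys
little and costs reproducibility. Default mismatch allowances: 0 for
miRNA and piRNA (short references, a single substitution can jump between
paralogs), 1 for tRNA/rRNA/mRNA/other (longer references, fragment reads).

The cascade order miRNA → tRNA → rRNA → mRNA → piRNA → other assigns each
collapsed sequence, with its full multiplicity, to the first class with a
hit; within a library a multi-mapping read is counted once at its best hit
(fewest mismatches, then entry order, then leftmost offset) — no
fractional counts. Consequences: class totals plus unassigned always
partition the input exactly, and raising a mismatch allowance can only
move reads out of "unassigned", never between earlier classes.

The index is pigeonhole seed-and-verify: a query allowed `m` mismatches is
split into `m+1` chunks, at least one of which must occur exactly; exact
chunk occurrences come from per-length substring hash tables over the
concatenated references and each candidate placement is verified in full.

isomiR calls compare the mapped interval to the canonical mature interval
(supplied as `canonical=START-END` on the FASTA header when the entry
carries genomic flanks; otherwise the whole entry): equality of sequence
and interval ⇒ canonical; only the 3′ end differs ⇒ `3p_shift`; only the
5′ end ⇒ `5p_shift`; anything else ⇒ `both_shift`. Without flanks only
3′-trimmed variants are observable — a documented limitation. Non-templated
3′ additions (A/U tailing) are not modelled.

## Count filtering and corrected fold-change

A feature counts as expressed in a sample iff its count reaches the cutoff
(inclusive). The percentile cutoff is nearest-rank (`⌈q/100·n⌉`-th
smallest) over the sample's *nonzero* counts — a feature absent from a
sample is "not detected", not an observation of zero; `include_zeros`
restores the naive behaviour. A feature row is dropped only when it is
below cutoff in every sample.

The correction factor `k` defaults to the median of the pooled nonzero
counts of the samples under comparison (even n: mean of the two middle
values); the user may supply any value or disable it. The signed
fold-change `(a+k)/(b+k)`, reported as `−1/r` when `r < 1`, is strictly
decreasing in `k` for `a > b` and tends to 1 as `k → ∞`, so `k` acts as a
tunable damper on low-count ratios. Arithmetic is full precision;
rounding to two decimals happens only in reports. `a + k = 0` with
`b + k > 0` yields −∞ (absent in test, present in control).

## Differential expression without replicates

Pipeline: quantile-normalize the two columns (rank-mean; ties within a
column receive the exact mean of the rank means they span), round to
integers (half away from zero — Fisher needs counts), two-sided Fisher's
exact test per feature against the normalized column totals
(minimum-likelihood two-sided definition, the feature-vs-rest 2×2
construction standard for digital expression data), Benjamini–Hochberg
adjustment, then calls at `|FC| ≥ 1.5` and raw `p ≤ 0.05`. Adjusted p is
always reported; `use_adjusted_p` switches the call criterion. The
correction factor applies to the fold-change only, never to the test.

Statistical behaviour, measured on simulated ground truth: under a pure
null (two multinomial draws from one composition) the per-feature
p ≤ 0.05 fraction stays at or below the nominal 0.05 — the exact test is
conservative, and quantile normalization of two same-distribution columns
leaves differences comparable to raw sampling noise. When a sizable
fraction of features truly changes, however, quantile normalization pairs
*displaced* order statistics for null features (every perturbed feature
that crosses a null feature's rank shifts which rank mean it receives).
The induced spurious difference scales roughly with
`f · ln(FC) · sqrt(count/2)` for perturbed fraction `f`, so deeply counted
null features acquire inflated significance (measured: ~8–12% of nulls at
p ≤ 0.05 with 10% of features at 4-fold, 200k reads/sample) while their
fold-changes stay near 1 — the joint p + fold-change call criterion is
what keeps false calls at the nominal rate. This is an inherent property
of the normalize-then-exact-test design, not an implementation artifact;
with replicates a dispersion-aware model (e.g. DESeq-style) should be used
instead, and the pipeline accepts externally computed replicate-aware
tables for that purpose.

Clustering uses 1 − Pearson correlation with average linkage (constant
columns are assigned distance 1 to everything — no shared signal); PCA
centers features and reports sample coordinates with variance fractions.
Both delegate the numerics to scipy/numpy.

## Seed-site scan

Site motifs derive from the miRNA seed (nt 2–8): 8mer = revcomp(2–8)+A,
7mer-m8 = revcomp(2–8), 7mer-A1 = revcomp(2–7)+A (the A1 adenosine is
recognized directly, so it is a literal A, not a complement). The scanner
anchors on occurrences of the 6-nt core revcomp(2–7) and classifies each
occurrence once by whether the m8 base and/or the A1 anchor are present,
giving the 8mer > 7mer-m8 > 7mer-A1 precedence without double counting; a
bare 6mer is not reported. Coordinates are 0-based on the UTR sense
strand; no reverse-strand scanning. Context/conservation scoring and
hybridization energy are out of scope; external score tables can be merged
downstream.

## Synthetic data

The generator emulates a deeply sequenced, miRNA-dominated small-RNA
library, scaled to desk size: default composition 55% miRNA, 1% tRNA, 3%
rRNA, 10% mRNA fragments, 1% piRNA, 5% other, and 25% unassignable
background (uniform random sequence standing in for genomic/degradation
reads). Reference libraries default to 450 miRNAs (20–24 nt, mode 22),
50 tRNAs (~75 nt), 4 rRNAs, 300 mRNA fragments, 80 piRNAs (26–31 nt) and
20 others, matching the scale of a deeply sequenced human cell line.
Feature abundances are log-normal (σ = 1); reads are insert + TruSeq
small-RNA 3′ adapter truncated to 40 nt, with independent substitution
errors at 0.001/base. miRNAs are rejection-sampled to pairwise Hamming
distance ≥ 3 so cascade assignment is unambiguous at ≤ 1 mismatch. All
randomness flows from one integer seed; identical profiles produce
byte-identical FASTQ.

Not emulated: realistic quality-score models, ligation bias, PCR
duplicates, isomiR end heterogeneity, adapter dimers, and homology between
classes (references are independent random sequences). Passing tests on
this generator therefore demonstrate the pipeline's accounting,
determinism and statistical behaviour under clean conditions; they do not
certify performance on real libraries, where cross-class homology and
non-uniform errors make annotation genuinely harder.

Test problem sizes were chosen to exercise each claim at desk scale:
oracle equivalences run on ~10³ random instances, conservation on a
50,000-read library, parameter recovery on two 200,000-read conditions.

## Error handling conventions

Malformed FASTQ records raise a parse error naming the line; duplicate
FASTA ids, empty libraries, negative or non-numeric count cells, unknown
sample names and invalid parameter ranges raise `ValueError`/`KeyError`.
The CLI maps configuration errors to exit code 2 and data errors to 3.
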
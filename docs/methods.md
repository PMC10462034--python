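# Methods

This note documents the model behind `squigbin`, the numerical and
design choices made where the design was genuinely open, what the
bundled simulator does and does not emulate, and known limitations.

## Signal model and pipeline

A nanopore emits a regular sequence of ionic-current samples (pA); each
k-mer occupying the pore produces an approximately constant level for a
random dwell. The pipeline reduces this to symbols:

1. **Event detection.** A two-window rolling Welch t-test compares the
   `w` samples before and after each position; boundaries are local
   maxima of the t-statistic exceeding a threshold, for a short window
   (default 3 samples, threshold 3.5, catching abrupt level changes) and
   a long window (6 samples, threshold 2.5, catching subtle ones), with
   minimum peak prominence 0.5. Candidate boundaries closer than 3
   samples are merged, keeping the stronger. Sample variances are
   floored at 1e-4 pA² so the statistic stays finite on noise-free
   signal (which also pins boundaries exactly at clean steps). These
   five constants are configuration, not hard-coded truth: they were
   chosen to balance stay errors (over-segmentation, absorbed by the
   later run compression) against skip errors (missed boundaries, which
   truncate matches and are not recoverable) on simulated signal at the
   generator's default noise, and every run records them in its config
   JSON.

2. **Normalization.** Event means are affinely mapped so their mean and
   population sd (maintained with Welford's streaming update) match the
   mean and sd of the pore model's level means. This removes per-read
   gain/offset drift but is *not* the identity even on perfectly
   calibrated signal: a read window's k-mer composition differs from
   the model's global composition, so normalized levels shift by
   O(σ/√n_events), flipping a small fraction of symbols near bin edges.
   `signal_to_binseq(..., normalize=False)` is the calibrated path used
   by the exact zero-noise closure tests; classification runs keep the
   default. Degenerate input (fewer than two events, or zero variance)
   skips normalization with a warning instead of failing, so constant
   signal still yields its single-symbol sequence.

3. **Quantization.** The pore model's level-mean range `[min_p, max_p]`
   is split into `n_bins = 6` equal picoamp ranges (bin width
   `sp = (max_p − min_p)/6`). Bins are left-closed/right-open, values
   below/above the range clamp to the extreme bins, and `v = max_p`
   belongs to the top bin — the floor formula leaves the exact boundary
   open, so this is fixed by convention. Six bins trade noise
   robustness (wide bins) against match specificity (alphabet size).

4. **Run compression (HPC).** Adjacent equal symbols collapse to one on
   both the query and the reference, absorbing stay errors; true
   reference repeats compress identically and therefore remain
   queryable.

Reference k-mers containing ambiguous bases map to a sentinel symbol
outside the bin alphabet (internally above all bins, below no query
symbol), so unknown sequence can never attract matches. Both strands of
every record are indexed because reads sample either strand and signal
space has no reverse-complement symmetry; this is a config flag
(`include_reverse`, default on).

## Index and pseudo-matching lengths

The concatenated bin text (one terminator per strand-sequence;
terminators sort lowest and never match) is indexed through its BWT.
Construction uses exact prefix-doubling suffix sorting and Kasai's LCP
algorithm as scaffolding; the persisted index keeps only run-length
structures: run symbols/lengths, per-run-boundary document labels, and
per-run-gap thresholds. The threshold between consecutive runs of a
symbol is the rightmost minimum of the LCP values between them, so that
a mismatching row repositions to whichever neighbouring run of the
needed symbol shares the longer common prefix with its current suffix,
with ties breaking toward the preceding run (determinism).

The backward pass holds a small state: the BWT range `[lo, hi)` of the
current match, one tracked row inside it, the running length, and the
current document. Per query symbol (right to left):

- if some occurrence of the current match is preceded by the symbol
  (`rank(hi) > rank(lo)`), the match extends: length increments, the
  range maps through LF, and the tracked row either takes the LF step
  directly (if its BWT symbol already matches) or repositions via the
  thresholds first;
- otherwise the match truncates: length restarts at 1 on the symbol's
  full range, with the row repositioned via thresholds;
- a symbol absent from the whole index scores 0 and resets the state to
  the full range.

The produced `P[i]` is a truncated matching statistic: always
`0 ≤ P[i] ≤ MS[i]` (the half-MEM matching statistic), with
`P[i+1] ≥ P[i] − 1`, and exactly `[m, …, 1]` when the query occurs
verbatim. Using the range for the extend/truncate decision (rather than
the tracked row alone) is a deliberate strengthening: it makes those
guarantees exact while keeping the pass single-loop and the state a
few integers. The row exists purely for document attribution: labels
are exact wherever the row lands on a run boundary — in particular
after every reposition, which is where match restarts happen — and are
propagated through LF steps in between, so mid-run labels can lag by a
shred boundary. That is acceptable because classification consumes
labels at match peaks, which follow restarts.

`resume_pml` exposes the pass chunk-wise with the same state. Because
the pass is right-to-left, chunk sequences resume latest-first;
fragments concatenated in reverse delivery order equal the batch
computation bit-for-bit. Streaming classification over signal arriving
left-to-right (`classify_stream`) instead recomputes the profile over
the accumulated bin sequence after each chunk: a prefix's PML values
near its right edge legitimately change once more signal arrives, so
recomputation is the only exact contract. At read-until scale (~20
chunks of 4,000 samples for a 10 kb read) the cost is a few tens of
milliseconds per chunk, and the final streamed decision is identical to
the batch decision by construction.

## Shreds, complexity, and the vote

References are partitioned into equal-length shreds (default 100,000
post-HPC symbols) so that matches carry sub-genome locality; equal
sizing already guards against length bias, and the final partial shred
keeps its own document id. Reverse-strand shreds share the document id
of the mirrored forward region so votes aggregate per locus; since HPC
destroys exact nucleotide correspondence between strands, the mirror is
proportional in post-HPC coordinates (midpoint-mapped), which is exact
for whole-strand shreds and approximate within a few hundred symbols
otherwise. One terminator per strand (not per shred) means matches may
span shred boundaries; a position's document is the shred containing
the suffix start.

Per-document complexity `C_d` is the order-0 empirical entropy of the
shred's bin symbols divided by `log2(n_bins)`, computed once at build
time and stored with the index (deterministic and index-resident; the
alternative of computing complexity over the concatenation of observed
matches is out of scope). Scores are
`C_d · Σ P[i]·I[D[i]=d]·I[peak(i)]` with peaks at `P[i] ≥ P[i−1]` and
position 0 a peak by convention (the predicate is defined only for
`i ≥ 1`). Argmax ties break toward the lexicographically smallest
reference name, then smallest document id.

Binary mode: ratio of the top positive-class document score to the top
null-class score, positive iff `ratio > τ` (strict, matching a
threshold stated as "greater than"). Degenerate denominators: zero null
with zero positive is unclassified; zero null with positive evidence is
positive (ratio +∞). `calibrate_threshold` sets τ to the
`(1 − f)` linear-interpolation quantile of burn-in ratios, so the
expected call rate matches the expected positive fraction `f`; infinite
burn-in ratios are clipped to a large finite value first. Raising τ
never increases the number of positive calls.

Every read receives a decision; the only abstention is an all-zero
score vector, which is counted and reported (`n_unclassified`).

## Simulator

`simulate_read` emits, per k-mer of a reference window: nothing with
probability `skip_prob`; one extra emission with probability
`stay_prob`; and per emission `round(max(1, N(dwell_mean, dwell_sd)))`
samples at `N(level_mean, noise_factor · level_sd)`. Defaults — 10 kb
mean read length (Normal, sd = mean/4, truncated at 500 bp), amplitude
noise factor 2.0, dwell mean 9 samples, dwell sd 8.0, stay/skip 0 —
are the package's standard study conditions. The generator is
deliberately simple: Gaussian amplitude and truncated-Gaussian dwell
are its own documented distribution choices. It emits signal on the
pore-model pA scale and does not model channel gain drift, adapter or
stall signal, pore clogging, or signal autocorrelation within events.
Consequently, passing tests demonstrate correctness of the matching and
voting machinery and robustness to level noise and dwell variation —
not performance on real flowcell data, where segmentation error rates
and reference relatedness are harsher.

The default synthetic pore model draws 4^6 level means uniformly over
~65–130 pA and per-k-mer spreads over 1.2–3 pA. Uniform independent
levels make the bin alphabet near-uniform (shred complexities ≈ 1),
which is mildly optimistic relative to real pore chemistries whose
k-mer levels are correlated through shared central bases. Real model
tables (TSV: `kmer`, `level_mean`, `level_stdv`) load directly.

Synthetic benchmark references are i.i.d. random nucleotides, so the
two classes share no homology: near-perfect accuracy on the default
two-class benchmark is the expected behaviour and validates the
plumbing, while the noise/dwell settings stress segmentation and
quantization. Distinguishing related genomes is a harder task that
these fixtures intentionally do not represent.

## Problem sizes and numerics

The bundled benchmarks use two 50 kbp references (≈166 k indexed
symbols over both strands), 200 noisy reads (100 per class) and 50-read
closure/streaming sets — sizes chosen so the full suite and the
acceptance script each run in minutes on one CPU while leaving every
statistical conclusion comfortably away from its threshold. Suffix
sorting is exact (no heuristics); all floating-point comparisons in
tests use explicit tolerances; all randomness flows from explicit seeds
(`--seed` in the acceptance script, fixed seeds in fixtures).

## Known limitations

- No O(r)-space locate: PMLs deliberately avoid suffix-array sampling,
  so matches report shreds, not coordinates.
- Dwell times are carried but unused in matching.
- SLOW5/POD5 readers are not included (plain-text fixture format and
  FAST5-via-HDF5 are); minimizer digestion and graph pangenomes are out
  of scope.
- In-memory rank structures are uncompressed (O(n) words); the
  persisted form is run-length, and query semantics are defined
  run-wise so a compressed rank implementation is drop-in.
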
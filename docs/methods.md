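# Methods

## Scores

**Global match-fraction.** For mature sequences *A*, *B* the score is
S = matches / max(|A|, |B|), where *matches* is the maximum number of
identically aligned positions over all gapped alignments in which
mismatches and gaps are free. Maximizing matches under free gaps is
exactly the longest-common-subsequence (LCS) problem; we solve it with the
LCS dynamic program, vectorizing each row with a running maximum (valid
because LCS rows are monotone non-decreasing). Dividing by the *longer*
length makes S = 1 hold only for identical sequences and penalizes length
mismatch; S is symmetric and lies in [0, 1]. Only the optimal score is
reported — co-optimal alignments and tracebacks are irrelevant to the
screen and never computed.

**Seed local score.** The seed windows (1-based inclusive positions 2–8 of
both sequences by default; configurable, and applied identically to both
kingdoms) are compared with a local (Smith–Waterman) alignment under an
affine gap model (Gotoh three-state recurrence): match +1, mismatch −0.5,
gap open −1, gap extend −1, score floored at 0. "Open/extend" here means
the *first position* of a gap run costs the open penalty and each further
position the extend penalty, so a g-position run costs open + (g−1)·extend;
with the default open = extend = −1 the model coincides with a linear
−1/position cost, but the machinery supports unequal values. The 2–8
window is the canonical metazoan seed; plant miRNAs pair more uniformly
along their length, which is why the window is a parameter rather than a
constant.

## Scramble null and t-test

Per pair, the animal sequence *B* is scrambled n = 100 times (default).
A scramble is a uniform random permutation of *B*'s characters, so every
scramble conserves *B*'s nucleotide multiset — and hence its nucleotide
percentages — exactly; i.i.d. resampling from those percentages is
available as `scramble_mode="iid"` but conserves composition only in
expectation. For the seed score the *full-length* B is scrambled and the
seed window re-extracted from each scramble (preserving whole-sequence
composition); scrambling the 7-mer alone is available via
`scramble_scope="seed_only"`. The global and seed nulls use independent
scramble draws.

The observed score is then tested against the scramble sample with a
one-sample Student-t tail probability. Because the observed score is a
*single draw* to be compared with the null population — not a sample mean
— the statistic uses the predictive standard error:

    t = (S_obs − mean) / (sd · √(1 + 1/n)),   df = n − 1,
    p = P(T_df > t)   (upper tail)

Under a normal approximation to the score distribution this is the exact
predictive t-test and its type-I rate is the nominal α. The alternative
scaling sd/√n tests whether the observed score equals the null *mean* and
rejects unrelated random pairs at a ~40% rate at α = 0.05 (measured by
simulation at length 22, n = 100), which would make the screen's filter
meaningless; the predictive form measures ~5% on the same simulation. The
test is one-sided (upper) because the screen asks only whether a pair is
*more* similar than chance; `test_tail="two_sided"` is available.

Degenerate nulls (sd = 0, e.g. a homopolymer B) take the limiting
convention p = 0 if the observed score strictly exceeds the constant null
and p = 1 otherwise, avoiding NaN propagation. A constant score sample is
detected exactly (max = min) so floating-point noise in the sample sd
cannot leak into the t statistic.

**Reproducibility.** Every pair owns an RNG stream derived from the master
seed and the CRC-32 of the two record ids (`pair_rng`). Results are
therefore bit-identical across runs and invariant to library order;
reordering input FASTA files permutes output rows without changing any
number. Scrambles are drawn per comparison, not cached per B sequence:
statistically cleaner, and the screen sizes used here make the saving
irrelevant.

## Screen and filtering

The screen is the full Cartesian product (plant-major order). A pair is
selected iff both p-values clear their thresholds simultaneously; the
default is raw p < 0.05 on each test. The double requirement — whole
sequence *and* seed — is the functional-homology criterion. Optional
Benjamini–Hochberg adjustment (`p_adjust="BH"`) runs separately on the
global and seed p-value vectors across all screened pairs before
thresholding. Selected plant miRNAs inherit their animal homolog's target
genes from a user-supplied TSV (id → genes); within-miRNA gene order is
preserved so pre-ranked tables stay ranked, and output is deduplicated per
(plant miRNA, gene).

## Overrepresentation analysis

For a query gene set against a GMT collection: p = P(X ≥ k) with
X ~ Hypergeom(N, K, n) — N the universe size, K the term's genes inside
the universe, n the query genes inside the universe, k the overlap. The
universe defaults to the union of the collection's genes; callers supply
their own when the assayable background is known (recommended — the
default understates N and is conservative only by accident). Every term
with at least one gene in the universe is tested and counts toward the
multiple-testing burden m; terms with zero query overlap are dropped from
the *output* only, since dropping them from m would inflate significance.
BH is the default adjustment (Bonferroni and none available). Rows are
sorted by (p_adj, p, term_id) and truncated to `top` (default 50).

## Synthetic fixtures

`make_screen_fixture` emulates a screening study with planted truth:
an animal library of i.i.d. random sequences (default 20 sequences,
22 nt — the modal mature-miRNA length — uniform composition), plant
homologs of the first 5 animal records, and 15 fresh decoys. A homolog
keeps the seed window untouched and carries exactly 2 substitutions at
distinct non-seed positions (each to a different nucleotide), so the seed
test and the global test can be powered independently: truth pairs always
score the full seed length locally, and 20/22 ≈ 0.909 globally. Decoys
come from the same generator as the animal library, so the decoy selection
rate estimates the screen's realized false-positive rate. A GC-rich
composition preset (A/C/G/U = 0.15/0.35/0.35/0.15) exists because scramble
nulls are composition-sensitive.

What the generator does *not* emulate: miRBase's empirical length and
composition distributions, sequence families/paralogy, or hairpin context.
Passing the planted-recovery benchmark therefore shows the statistics and
plumbing are correct at realistic sizes, not that any particular real
plant miRNA is a functional homolog.

## Numerical and interface choices

- FASTA input is normalized to uppercase RNA (T→U); ambiguity codes are
  rejected outright because the scores are defined only over concrete
  nucleotides. Ids are the first whitespace-delimited header token.
- Result TSVs render floats with 6 significant digits, LF endings, '.'
  decimals; identical inputs give byte-identical files.
- Problem sizes in the shipped benchmarks — 20 × 20 screen, 100 scrambles,
  500 calibration pairs, exhaustive oracle checks over {A,C} strings of
  length ≤ 6 — were chosen as the smallest sizes at which the stochastic
  properties (calibration band, planted recovery) are stable across seeds.
- The t-test's sidedness, the seed window, the scramble scope and the
  filter thresholds are all configuration with the defaults documented
  above; none is hard-coded.

## Limitations

- The scramble null conditions on composition but not on dinucleotide or
  positional structure; the observed pair is not literally a draw from it,
  so calibration is approximate (empirically ~5% at α = 0.05 for unrelated
  uniform-composition pairs).
- Sequence similarity is a proxy: the screen predicts *candidate*
  functional homologs, and target transfer assumes the plant miRNA acts
  through the same sites as its animal counterpart. Neither claim is
  experimental evidence.
- The hypergeometric ORA treats genes as exchangeable; gene-length or
  expression biases in how targets were ascertained are not modelled.
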
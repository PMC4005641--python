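# Methods

## The problem and the model

`toxsar` addresses a sequence-level structure–activity question: given
short LNA gapmer antisense oligonucleotides (14-mers, 3-8-3 design)
labeled hepatotoxic or not from mouse tolerability studies, find
nucleotide motifs whose presence predicts the toxic outcome, and build
a classifier that flags risky candidate sequences at the design stage.
The chemistry (phosphorothioate backbone, LNA wing placement) is
deliberately excluded from the descriptors: all sequences in a study
share the same design, so it carries no discriminating information,
and the wing/gap layout is kept only as record metadata.

The modeling pipeline has three statistical stages, each a standard
tool applied in a fixed order:

**Descriptors.** A sequence is encoded as the ordered vector of
occurrence counts of every contiguous motif of length 2–5 over
{A, C, G, T}: 16 + 64 + 256 + 1024 = 1360 positions, ordered
length-major and lexicographically within a length. Occurrences are
counted with a sliding window, so overlapping matches count
separately; consequently, for a length-L sequence the counts over all
motifs of one length k sum to L − k + 1 (13 + 12 + 11 + 10 = 46 for a
14-mer), a conservation law used throughout the tests. Counts (not
presence bits) feed the classifier; binarization is available as an
option (`featurize(..., binarize=True)`) since the two encodings are
nearly identical for 14-mers, where counts rarely exceed 2.

**Screen.** Each motif is reduced to presence/absence and crossed with
the label in a 2×2 table (a = toxic carriers, b = toxic non-carriers,
c = non-toxic carriers, d = non-toxic non-carriers). The statistic is
the Pearson χ², closed form n(ad − bc)²/((a+b)(c+d)(a+c)(b+d)), 1 df,
without continuity correction (Yates is a config flag); selection uses
the raw p < α with α = 0.05 and no multiplicity correction, because
the screen is a variable-reduction filter, not an inferential
endpoint. Benjamini–Hochberg is available behind `fdr_method="bh"`.
Motifs present in no sequence (or in all) have a degenerate presence
margin: they are flagged untestable, given χ² = 0, p = 1, and are
never selected. No minimum-expected-count filter is applied; instead a
warning is logged whenever a testable motif has an expected cell below
5, where the asymptotic p-value is rough.

**Forest.** A Breiman-style bagged classification forest on the
screened counts: `n_tree` (default 1000) CART trees (Gini impurity,
unlimited depth, minimum node size 1 — classification-forest
conventions, stated here as this package's assumptions), each fit on a
bootstrap resample of the sequences with `m_try` descriptors sampled
per split. `m_try` defaults to ⌊p/3⌋ of the p screened features,
matching the regression-style default of the classic Fortran/R
implementation this workflow descends from; ⌊√p⌋ and explicit values
are options. Evaluation is out-of-bag: each sequence is scored by the
majority vote of the trees whose bootstrap excluded it (expected ~37%
of trees), yielding sensitivity and specificity without a held-out
set. An exact 50:50 OOB vote resolves to non-toxic; the tie-break is
arbitrary but fixed for determinism, and the vote threshold is
configurable.

Variable importance is mean decrease accuracy: for each tree, its OOB
accuracy is recomputed after permuting one feature's OOB values, and
the per-tree drops are averaged. The raw average defines the primary
ranking; the z-scaled variant (mean divided by its standard error over
trees, the display convention of the classic R implementation) is also
reported. A constant feature has exactly zero importance under both.
The bagging bookkeeping is implemented in this package on top of
individual scikit-learn decision trees because per-sequence OOB votes
and per-tree OOB permutation are required outputs that an off-the-shelf
forest object does not expose.

**Rule.** Separately from the forest, an any-of motif-presence rule
(canonical motifs {TGC, TCC}) predicts toxic iff any rule motif occurs
anywhere in the sequence — unweighted and position-free, since carrier
status, not position or LNA overlap, is what tracks the outcome in the
motivating data. The pipeline's default rule is derived from the
screen itself (selected motifs with zero non-toxic carriers), falling
back to {TGC, TCC} with a warning when no such motif exists (typical
for very small inputs). The rule is a flag-raiser with documented
exceptions in both directions; `evaluate_rule` reports every mismatch
rather than adjudicating them.

## Sequence editors

`introduce_motif` overwrites a window with a motif (length-preserving,
reporting exactly the changed positions). `remove_motif` eliminates
every occurrence of a motif by a minimal set of single-base
substitutions, found by iterative deepening on the edit count with
backtracking, under the constraint that no *newly created* occurrence
of any forbidden motif appears (forbidden occurrences already present
in the input and not targeted are tolerated — removing TCC from a
sequence that also carries TGC cannot be asked to fix both in one
call). Among equally small solutions, edits at DNA-gap positions are
preferred over LNA-wing positions so the wing composition stays
intact, with ties broken by leftmost position and alphabetic
replacement base; the search is therefore fully deterministic. Note
that a motif-free edit is not a detoxification guarantee: the
motivating data include a lesion-positive sequence with no flagged
motif, and the gap-preferred removal of TCC from AAGTCTGTTTCCCC
reproduces exactly such a sequence.

## Synthetic data: what it emulates and what it does not

The generator draws datasets with the statistical skeleton the
analysis assumes: `n_toxic` = 51 and `n_nontoxic` = 20 14-mer 3-8-3
gapmers; a seeded random ⌈penetrance · n_toxic⌉ subset of the toxic
class (penetrance default 27/51) each carries one planted motif
(default TGC or TCC, chosen uniformly, written at a uniform valid
position); every other sequence — all non-toxic and the toxic
non-carriers — is rejection-sampled i.i.d.-uniform until it contains
no planted motif, with a bounded retry count that raises a diagnostic
error when the planted set is so dense that motif-free sequences are
improbable. The zero-carrier non-toxic class is thus exact by
construction, matching the striking all-or-nothing carrier asymmetry
of the motivating data, and the generator's own truth table provably
agrees with the k-mer scanner on every record.

What it does not emulate: real antisense 14-mers are reverse
complements of transcript regions chosen by a design workflow with
composition and complexity filters, not i.i.d. letters; and the real
toxic non-carriers presumably harbor additional, unidentified toxicity
motifs, whereas synthetic toxic non-carriers are pure noise. Two
consequences for interpreting passing tests: synthetic non-toxic
sequences are harder to tell apart from toxic non-carriers than real
ones appear to be, so synthetic OOB specificity (typically 0.15–0.45
across seeds at study size) runs below the ~0.55 seen on real data;
and background k-mer frequencies are unrealistically flat. Passing
tests therefore demonstrate the machinery recovers planted structure
at study-scale sample sizes — not that the real effect sizes are
reproduced.

## Numerical and calibration notes

- **Determinism.** All randomness flows through seeded NumPy
  generators. The forest uses two independent streams (bootstraps vs
  importance permutations), so disabling the importance pass
  (`compute_importance=False`, used in null experiments where only OOB
  accuracy matters) leaves OOB predictions bitwise identical.
  Importance ranks break ties by catalogue position (stable sort).
- **Discreteness of the screen.** At n = 71 the χ² screen is
  conservative as a whole: a motif present in exactly one sequence can
  never reach χ² > 3.84 however the labels fall, and low-prevalence
  motifs reach the rejection region only under extreme label skews of
  small null probability. Under label shuffling the attained
  type-I fraction is therefore ≈ 0.03 at nominal α = 0.05, not 0.05;
  the correct calibration guarantee — and the one the test suite
  asserts — is validity (attained level ≤ α), not exactness.
  Similarly, the asymptotic χ²₁ tail deviates from the exact
  conditional (permutation) null by tens of percent on tables with
  expected cells near 5; the package warns when this regime is
  entered, and the permutation utility provides the exact alternative.
- **Selection leakage.** Screening motifs and then evaluating the
  forest out-of-bag on the same sequences is mildly optimistic: the
  screen already used every label. Measured on label-shuffled
  synthetic data, re-screening per shuffle inflates null OOB balanced
  accuracy from ~0.48 (fixed, label-independent features) to ~0.65.
  Null-model experiments in this package therefore fix the feature set
  independently of the shuffled labels; users comparing OOB numbers to
  external data should keep this caveat in mind for the screen-then-OOB
  protocol itself.
- **Importance dilution.** The screen co-selects many mutually
  correlated motifs (substrings, superstrings and overlaps of the true
  signal carriers). Permutation importance divides credit among
  correlated features, so a genuinely causal motif need not rank at
  the very top in any single replicate; at default synthetic
  conditions at least one planted motif lands in the top ten of ~40–60
  ranked motifs in roughly three-quarters of replicates (and a
  reference R forest implementation behaves the same). Rankings should
  be read in cohorts, not as a strict ordering.
- **Problem sizes in the test suite.** The suite runs the full study
  size (71 sequences, 1360 motifs, 1000 trees) where the claim depends
  on it (recovery and reproduction checks) and smaller forests
  (50–300 trees) or datasets elsewhere, chosen so the complete suite
  and the acceptance script each finish in a few minutes on one core.

## Known limitations

- Single-strand, exact-match motifs only: no IUPAC degeneracy, no
  reverse-complement scanning, no positional encodings.
- The rule and forest share training data with the screen; no external
  validation set exists at study scale.
- ALT/AST values and lesion grades are carried as annotations but not
  modeled; labels are strictly binary.
- The generator's i.i.d. background is a deliberate simplification
  (see above); transcriptome-derived backgrounds are out of scope.
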
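# toxsar

Structure–toxicity analysis of LNA-modified antisense gapmers.

Locked-nucleic-acid (LNA) gapmer antisense oligonucleotides — 14-mers
with a 3-8-3 layout of LNA wings around a DNA core — are potent RNase
H recruiters, but a substantial fraction of candidate sequences cause
liver injury in mouse tolerability studies, and the risk tracks the
base sequence itself rather than the target or the chemistry.
`toxsar` implements the standard sequence-descriptor workflow for
finding and exploiting that signal, for oligonucleotide designers and
safety scientists who want to flag risky candidates before animal
testing:

1. **k-mer descriptors** — every sequence becomes an ordered vector of
   occurrence counts over all contiguous motifs of length 2–5
   (16 + 64 + 256 + 1024 = 1360 positions, length-major and
   lexicographic).
2. **χ² motif screen** — each motif's presence/absence is crossed with
   the binary hepatotoxicity label in a 2×2 table and tested with the
   Pearson statistic, χ² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), 1 df,
   no continuity correction; motifs with raw p < α (default 0.05) form
   the reduced descriptor set.
3. **random forest with OOB evaluation** — a Breiman-style bagged
   forest (default n_tree = 1000, m_try = ⌊p/3⌋) on the screened
   counts; every sequence is scored out-of-bag, giving sensitivity and
   specificity without a held-out set, and features are ranked by mean
   decrease accuracy (per-tree OOB permutation importance).
4. **motif-presence rules** — an any-of presence rule (canonically
   {TGC, TCC}, trinucleotides observed only in hepatotoxic sequences)
   plus sequence editors that introduce a motif at a position or remove
   one by minimal substitutions without creating new flagged motifs.
5. **synthetic data** — a planted-motif generator reproducing the
   study-scale statistical structure (51 toxic / 20 non-toxic 14-mers,
   carrier penetrance 27/51, zero non-toxic carriers), so the whole
   pipeline is testable without the original annotated dataset.

## Worked example

```python
import toxsar as tx

# a synthetic study at the default conditions
dataset, truth = tx.generate(tx.SyntheticSpec(), seed=1)
features = tx.featurize(dataset)                     # 71 x 1360 counts
screen = tx.screen_motifs(features, alpha=0.05)
selected = tx.selected_motifs(screen)
print(len(selected), "motifs selected")

forest = tx.train_forest(
    features.subset_motifs(selected),
    tx.ForestConfig(n_tree=1000, seed=1),
)
print(f"OOB sensitivity {forest.sensitivity:.2f}, "
      f"specificity {forest.specificity:.2f}")
print(forest.importance_table().head(3).to_string(index=False))

confusion, _ = tx.evaluate_rule(dataset)             # TGC/TCC presence rule
print(f"rule TP={confusion.tp} FP={confusion.fp}")
```

Output (seed 1):

```
39 motifs selected
OOB sensitivity 0.96, specificity 0.40
motif  mean_decrease_accuracy  mean_decrease_accuracy_scaled  rank
 AACC                0.018870                      17.192939     1
   TC                0.018253                       9.844038     2
  TCC                0.016138                      13.212996     3
rule TP=27 FP=0
```

Read: 39 of the 1360 motifs associate with the label at p < 0.05; the
forest recovers 96% of toxic and 40% of non-toxic sequences from its
out-of-bag votes; one planted trinucleotide (TCC) ranks third by
permutation importance; and the presence rule flags exactly the 27
toxic carriers with no false positives — non-toxic carriers do not
exist by construction, mirroring the observed data.

The same workflow runs from the shell:

```bash
toxsar simulate --out study.tsv --seed 1
toxsar run --input study.tsv --outdir reports --seed 1
toxsar rule-predict TCAGTGCATCCTTG         # -> toxic  TCC@8 TGC@4
toxsar edit remove AAGTCTGTTTCCCC TCC      # -> AAGTCTGTTACCCC  9:T->A
```

`toxsar run` writes the normalized dataset, feature matrix, screen
table, motif distribution, forest summary, importance ranking, rule
agreement table and a JSON run manifest into `reports/`.

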
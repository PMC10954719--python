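# droshascan

Discovery and characterisation of Drosha-cleaved stem-loops from
Degradome-seq and small-RNA-seq read coordinates.

## The problem

The RNase III enzyme Drosha releases stem-loop intermediates from primary
miRNA transcripts, but it also cleaves structurally similar stem-loops
embedded in mRNAs. Degradome-seq (PARE) captures polyA RNA fragments with a
5′ monophosphate — the hallmark of RNase III cleavage — so read 5′ ends
stack precisely at the cleavage position on the 3′ arm of a cleaved
stem-loop (a *pile-up site*, `D`). The opposite-arm cleavage site `S` is
not visible to Degradome-seq; it is inferred from small-RNA-seq, where
product-like reads carry `S` as their 5′ terminus and offset-RNA
(moRNA-like) reads abut it with exonucleolytically ragged distal ends.

`droshascan` implements the full computational chain:

1. **Pile-up detection** — per genomic locus *i*, the counting vector
   `C_i = (C5_{i−10}, …, C5_i, …, C5_{i+10})` of RPM-normalised read-start
   depths is classified by a cross-validated lasso-regularised logistic
   model trained on known cleavage sites against resampled random negative
   loci; a locus is accepted only if positively classified in >90% of
   resampling iterations in every control replicate. Training must reach
   sensitivity, specificity and AUC all >0.9.
2. **Condition dependence** — raw counts per locus are TMM-normalised and
   tested with a negative-binomial likelihood-ratio test (Cox–Reid common
   dispersion, empirical-Bayes shrinkage); a site is Drosha-dependent when
   log₂FC < −1.5 at BH FDR < 0.05.
3. **Stem-loop reconstruction** — sRNA terminus stacks >1 RPM whose implied
   cleavage site lies 25–100 nt from `D` (either direction) are paired with
   `D`; the window with 15-nt flanks is folded and the candidate is
   accepted when the two sites bound a duplex end with a 3′ overhang of
   2 ± 2 nt — the RNase III signature.
4. **Feature analysis** — MFE, length, base-pair frequency, maximal stack,
   ensemble diversity and positional entropy; cleavage-anchored P/F/I/B/T
   structural annotation from a constrained 25-nt-flank refold;
   internal-loop catalogues; information-bit matrices; pri-miRNA processing
   motifs (basal UG, apical UGU, CNNC, mGHG); Welch tests between miRNA and
   non-miRNA substrate cohorts.

Folding runs on a built-in stacking model (stack of two G-C pairs −3,
mixed −2, other −1; min loop 3; no lonely pairs) whose partition function,
base-pair probabilities, positional entropy and ensemble diversity are
exactly verifiable by structure enumeration; a ViennaRNA adapter
(`droshascan.vienna`) provides production thermodynamics behind the same
interface.

Because the study's real libraries live in GEO, the package ships a
first-class synthetic-data module that plants hairpins with known cleavage
geometry, motifs and knockout depletion into a toy genome and simulates
both read types, so every stage is tested against ground truth.

## Worked example

```python
from droshascan import RunConfig, run_pipeline

report = run_pipeline(RunConfig(outdir="run1", seed=1))
print(report["stages"]["pileup"]["classifier"]["control_rep1"])
print(report["stages"]["stemloop"], report["recovery"])
```

prints (desk preset: 100 kb genome, 100 miRNA-like + 100 mRNA-like planted
hairpins, 2 control + 2 knockout Degradome replicates, 100 consensus
iterations):

```
{'sensitivity': 1.0, 'specificity': 1.0, 'auc': 1.0, 'trained_ok': True}
{'anchors': 200, 'resolved': 200, 'unresolved': 0}
{'planted': 200, 'exact_pairs_in_feature_table': 200, 'fraction': 1.0}
```

The classifier reaches the >0.9 training-success rule with margin, all 200
accepted pile-up sites pass the dependence gate, and every planted hairpin
is reconstructed with the exact `(S, D)` pair and its planted 2-nt
overhang. The run directory contains the genome, truth table, per-library
BED files, pile-up/differential/stem-loop/feature tables, information-bit
matrices and a JSON report. The same stages are available as CLI
subcommands (`droshascan run --seed 1 --outdir run1`, `droshascan
simulate`, `droshascan report run1/report.json`).

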
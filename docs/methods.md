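# Methods

## Coordinate and orientation conventions

Coordinates are 0-based half-open throughout; BED intervals are native.
For a + strand read the biological 5′ end is the BED start, for a − strand
read it is BED end − 1 (3′ ends mirrored). Counting-vector offsets,
scan windows and flank arithmetic all follow transcript orientation: on
the − strand, offset +1 is one genomic position to the left. DNA (`T`) is
used in FASTA output and converted to RNA (`U`) at the folding boundary.

`S` denotes the 5′-arm cleavage site (first nucleotide of the excised
product), `D` the Degradome pile-up site (first nucleotide of the
downstream polyA-bearing fragment). Cleavage-anchored positions put +1 at
the first product nucleotide of each arm, the cut between −1 and +1, with
negative positions running into the lower stem and flanking ssRNA.

## The built-in folding model

The default energy model assigns energy only to stacks of adjacent base
pairs: −3 for two G-C pairs, −2 when exactly one pair is G-C, −1
otherwise, with Watson–Crick and G-U wobble pairs, hairpin loops ≥ 3 nt,
and lonely pairs disallowed (mirroring the `--noLP` convention). Unpaired
bases are free. This model is deliberately small: every ensemble quantity
it produces — partition function, base-pair probabilities `p_ij`,
positional entropy `H_i = −Σ_j p_ij ln p_ij − q_i ln q_i` (natural log;
`q_i` the unpaired probability), ensemble diversity
`Σ_{i<j} 2 p_ij (1 − p_ij)` (the expected base-pair distance between two
independent ensemble draws) — is checked against exhaustive structure
enumeration to 1e−9 on sequences up to length 12.

The MFE and partition-function dynamic programmes share an unambiguous
grammar: an open region decomposes by its rightmost position; a pair
introduced at region top level is "unsupported" and must stack inward when
lonely pairs are banned, while a pair supported by an enclosing stack may
close an open interior. Unambiguity is what makes the inside–outside pass
yield exact pair probabilities. Hard constraints (forced specific pairs,
forced-unpaired positions) enter as masks on the pairability matrix and on
the "leave unpaired" branch. Ties between co-optimal MFE structures are
broken by a fixed traceback branch order (outermost pair first, stacking
preferred); a strict lexicographic minimisation over co-optimal
dot-brackets was considered and rejected as needlessly expensive — every
geometry decision downstream depends only on the duplex end at the
cleavage sites, which co-optimal shuffling does not move in the regimes
the pipeline accepts.

Temperature enters as a single scale on the Boltzmann weights
(`temperature_scale`, default 1 model unit). The ViennaRNA adapter
(`droshascan.vienna`, options equivalent to `-p -d2 --noLP`) returns the
same container types, so the geometry and feature code is backend-blind;
the overhang test uses the MFE structure (the MEA structure is not
computed — which structure the original analysis fed to the overhang test
is not stated, and MFE is the reproducible choice).

## Synthetic study conditions

The generator's defaults are the study conditions; they are not tuned per
experiment.

* **Hairpin geometry.** A planted cassette is a continuous stem of
  `stem_length` pairs with a `lower_stem_length` = 13 bp basal segment
  (Drosha cleaves ~13 bp from the basal ssRNA–dsRNA junction), terminal
  loop, and a 2-nt 3′ overhang: the product's 3′ end extends two
  nucleotides beyond the pairing partner of `S`. miRNA-like substrates
  draw stems of 35 ± 1 bp with 10–14-nt loops, balanced G-C/A-U pairing
  (0.5/0.4/0.1 with G-U), and carry basal UG, apical UGU and CNNC motifs;
  mRNA-like substrates draw 24–28-bp stems with one asymmetric internal
  loop, G-C-skewed pairing (0.7/0.2/0.1) and no motifs — the two cohorts
  that the feature-direction analyses contrast.
* **Generation-time validation.** Every designed cassette must fold (under
  the built-in model, in the exact window the caller will fold) with the
  planted overhang, keep a planted UGU unpaired, and satisfy the 25–100 nt
  S/D spacing; failing draws are redrawn. The truth table therefore
  describes sequences as they actually behave under the model, not merely
  as intended.
* **Degradome libraries.** Signal reads start at `D` (±1 nt with
  probability `jitter` = 0.02 per side) with NB-distributed depth (mean
  100, dispersion 0.05); knockout libraries multiply the mean by
  `depletion_factor` = 0.1. Background read starts are homogeneous
  Poisson at 0.2 per position per strand. The background rate is set so
  that background is the compositional majority of a library, as in real
  Degradome data where cleavage stacks are a tiny fraction of ~20 M
  reads. This matters statistically: TMM normalisation can only separate a
  biological depletion from a smaller library size if an unchanged
  majority anchors the M-value trimmed mean. In the degenerate zero-
  background condition the depletion is unidentifiable from library size,
  which is why the clean-input exactness check (jitter 0, background 0)
  validates detection and reconstruction rather than the differential
  gate.
* **sRNA libraries.** Product-like reads carry the cleavage site as their
  proximal terminus with lengths 20–24 nt (NB mean 50); moRNA-like reads
  abut the site from the flanking side with geometric distal raggedness
  (NB mean 20); both arms are simulated, reads are collapsed to unique
  coordinates with multiplicity in the BED score, and RPM uses the
  pre-collapse total.
* **Not emulated:** sequencing error, adapters, alignment ambiguity,
  multi-mapping, transcript isoforms, non-uniform background composition.
  Passing tests therefore demonstrate the correctness of the analytical
  chain under its stated statistical assumptions, not robustness to
  alignment artefacts.

## Pile-up classification

Candidate loci are all positions with nonzero 5′-start coverage in any
replicate (zero-coverage positions cannot be pile-ups). The classifier is
logistic regression on the 21-entry counting vector, lasso-regularised
(`l1_ratio` = 1, matching the reference toolchain's default mixing
parameter) with the strength chosen by 10-fold cross-validated
classification accuracy; features are standardised inside the estimator
(again the reference default; raw RPMs are available via
`standardize=False`). Held-out sensitivity, specificity and AUC come from
cross-validated fold predictions at the selected strength, and training
"succeeds" only if all three exceed 0.9. Consensus classification redraws
the 1000 negative loci each iteration, re-verifies the success rule,
refits and votes; acceptance requires strictly more than
`accept_fraction × n_iterations` positive votes in *every* control
replicate (the desk preset runs 100 iterations — acceptance is a vote
fraction, so the iteration count scales without changing semantics).

## Differential testing

Library scaling uses TMM: reference library by upper-quartile proximity,
M/A double trimming (30% / 5%), precision-weighted mean of M, factors
rescaled to geometric mean 1 (cross-checked against the reference
implementation on fixed matrices). The per-locus test is a negative-
binomial likelihood ratio: common dispersion by maximising the Cox–Reid
adjusted profile likelihood on counts equalised to a common effective
library size (the adjustment removes the ~2× downward bias of plug-in
group means at two replicates); per-locus method-of-moments dispersions
are shrunk toward the common value with prior weight 10 df; group means
are fitted by Newton iteration in log-rate with effective-library-size
offsets; p-values come from χ²₁ and are BH-adjusted over tested loci
(all-zero rows excluded). Measured type-I error at α = 0.05 on 2000 null
loci is ~0.05. The dependence gate is one-sided (log₂FC < −1.5,
FDR < 0.05) because the biology is loss of cleavage in the knockout; a
two-sided variant is a flag. p-values are comparable to, but not
bit-identical with, the original quasi-likelihood F-test toolchain — the
gate, not the exact p, is the contract.

## Stem-loop reconstruction

For each dependent pile-up site both 25–100 nt windows are scanned; a
terminus stack qualifies at >1 RPM. 5′-start stacks imply cleavage at
their own position, 3′-end stacks at the next transcript position (the cut
lies between a moRNA's ragged side and its precise side). The canonical
orientation places the hairpin transcript-5′ of `D`; the downstream
orientation covers the single-5′-arm-cut case where the hairpin lies 3′ of
the anchor. Windows are `[S−15, D+15)` (canonical) or the mirrored
downstream equivalent; if the product's 5′ nucleotide is unpaired in the
MFE structure, the duplex end is located by sliding ≤ 2 nt inward with
compensation. The signed overhang is
`three_end − partner(five_start)`; acceptance is the closed set
{0, 1, 2, 3, 4} (2 ± 2). Among accepted candidates per anchor the deepest
supporting stack wins, ties broken by |overhang − 2|, then smaller span,
then transcript-5′-most `S`. Anchors with no accepted candidate are
reported unresolved; overlapping hairpins from different anchors are
reported independently.

## Feature analyses

Thermodynamic rows use the 15-nt-flank window: length = S–D span + 30;
base-pair frequency and the longest perfectly stacked run are normalised
to that length; ensemble diversity and mean positional entropy come from
the partition function on the same window. Structural annotation refolds
with 25-nt flanks under the hard constraint that every 15-nt-flank pair
stays paired (falling back, with a warning, to an unconstrained refold if
infeasible) and labels every position P/F/I/B/T; symmetric vs asymmetric
internal loops are distinguished by equal vs unequal unpaired run lengths
on the two arms, and multibranch interiors — not expected in genuine
hairpins — are labelled B with a warning. Internal-loop records carry the
anchored position of the 5′-arm unpaired nucleotide closest to the cut and
a signed 1-based 5-bp window index. Base-pair composition (G-C/A-U/G-U)
is split into lower stem (5′-arm nucleotide anchored ≤ −1) and upper stem
(≥ +1), each normalised to its own pair count. Information content per
anchored position is `log2 |A| + Σ_c f_c log2 f_c` with 0·log 0 = 0, no
small-sample correction, and positions covered by fewer than 5 items
masked. Group contrasts use Welch's unequal-variance two-tailed t-test
with Welch–Satterthwaite degrees of freedom and no multiplicity
correction (features are reported individually).

## Problem sizes and determinism

The desk preset — 100 kb genome, 200 planted substrates, 2 + 2 Degradome
replicates, 100 consensus iterations — is the package's reference
condition for validation and for `scripts/acceptance.py`; the full-scale
setting (1000 iterations, larger genomes) changes only runtime. One
global seed fans out through `numpy.random.SeedSequence.spawn` into
independent per-stage streams, and every estimator receives its seed from
those streams, so identical configurations reproduce byte-identical
outputs; the run manifest echoes the configuration and checksums of every
artefact.

## Known limitations

* The toy energy model ranks structures by stacking only; absolute
  energies are in model units, and fine thermodynamic effects (dangles,
  loop-size penalties, temperature in kelvin) require the ViennaRNA
  backend.
* The background model is homogeneous Poisson; structured degradation
  (3′→5′ decay gradients, positional bias) is not emulated.
* Anchoring of downstream-orientation calls uses the inferred product
  boundary as position +1; when the 5′-arm cut is the anchor the upper
  stem is defined from that boundary, which is flagged in output rather
  than resolved.
* Gene-level RNA-seq differential expression is out of scope; the same
  count-testing machinery accepts any count table, but no gene
  summarisation is provided.
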
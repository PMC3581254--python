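# Methods

## Flexibility profiles

The weighted contact number `wcn_i = Σ_{j≠i} r_ij⁻²` is computed over Cα
atoms only, with plain Euclidean distances — no periodic images, symmetry
mates, or all-atom contacts. Coincident Cα positions are rejected rather
than regularized, since they indicate a corrupt input. The inverse,
`wcn⁻¹` (Å²), is the per-residue flexibility score that SEQ and STR average.

**SEQ (window half-width `n`, default 1).** The displayed form of a windowed
average has denominator `2n+1`, but indices outside the chain are ignored;
we divide by the number of terms actually included (`edge="mean"`), so
termini are true averages rather than artificially deflated values. The
alternative fixed-denominator behavior is available as
`edge="fixed_denominator"` for sensitivity checks. For the catalytic-residue
examples this choice is immaterial (they are interior residues), and
published per-residue values are reproduced identically under both policies.

**STR (cutoff, default 3 Å).** The neighbor set contains residue *i* itself
plus every residue at distance *strictly* less than the cutoff; distances
exactly equal to the cutoff are excluded. At a 3 Å cutoff on real Cα traces
the neighbor set is usually just the residue itself, so STR ≈ inverse WCN;
the cutoff becomes informative as it grows toward the 10–20 Å range.

**Z-normalization.** Profiles are standardized per protein with the
*population* standard deviation (divide by N), so every z-track has mean 0
and SD exactly 1. The difference from the sample SD is O(1/N) — about 0.005
on a 200-residue chain, well inside the 0.02 reproduction tolerance used for
published per-residue values. Constant profiles (σ = 0) are an error
reported for the offending protein, not silently zeroed.

Defaults `n = 1` and `cutoff = 3 Å` are the settings at which the context
profiles discriminate catalytic from noncatalytic residues best; both are
exposed everywhere.

## Structure input

Chains are read with Biopython's PDB parser. Waters, ligands and other
non-protein molecules are dropped. Modified amino acids recorded as HETATM
within the chain (MSE, SEP, TPO, PTR, …) are mapped to their parent residue
so the trace is not broken; anything unmappable is removed. Alternate
locations resolve to the highest-occupancy conformer (first encountered on
ties). Multi-model files default to the first model. Residue identity is
(chain, author residue number, insertion code), matching Catalytic Site
Atlas numbering. The analysis unit is a single selected chain; profiles are
computed over that chain's residues.

## Classification protocol

* **Features.** Z-profiles are already standardized per protein and enter
  the SVM unscaled; the amino-acid one-hot block is left as 0/1; the
  conservation column keeps its native information-content scale (bits).
  RBF gamma tuning absorbs residual scale differences.
* **Balanced subsampling.** Training keeps all positives and draws an equal
  number of negatives uniformly without replacement, deterministically from
  a seed. Test-side metrics are reported both ways: balanced subsets for
  sensitivity/specificity/MCC comparisons, the untouched unbalanced fold for
  ROC analysis.
* **Cross-validation granularity.** Outer folds partition proteins, not
  residues. Residue-level folds would leak intra-protein structure (all
  residues of one chain share a normalization and a fold context) and would
  make per-protein ROC averaging ill-defined on held-out data.
* **Tuning.** Grid search over cost ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and
  gamma ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} (standard libsvm practice) by inner stratified
  5-fold CV, maximizing MCC; ties prefer the smallest cost, then the
  smallest gamma, so the selection is deterministic. The final model refits
  on the full balanced table with libsvm-style Platt scaling for
  probabilities.
* **Ranking.** Within each protein, residues are ranked by descending
  probability; exact ties break by ascending residue number, keeping ranks a
  permutation.

## Evaluation

Sensitivity, specificity and MCC come from the standard 2×2 confusion
counts; a metric whose denominator vanishes is reported as NaN, never as 0.
ROC curves are computed per protein and averaged **vertically**: each
protein's true-positive rate is linearly interpolated onto a fixed
false-positive-rate grid (0 to 1, step 0.01) and the mean is taken per grid
point. Proteins with no positive (or no negative) residues in a test fold
have no ROC and are excluded from the average with a count. The chance-level
control permutes labels within each protein against fixed held-out scores;
this isolates the ROC-averaging machinery and sits at AUC 0.50 ± 0.02 in
practice, whereas retraining on shuffled labels adds a small pessimistic
bias from fitting noise.

## Synthetic data

The generator emulates exactly the geometry the profiles respond to, and no
more:

* **Chains.** A self-avoiding random walk with fixed 3.8 Å steps, biased
  toward its running centroid (bias 0.6) with a 3.0 Å excluded-volume
  radius; dead ends unwind a few residues and regrow. This yields compact
  globules with a genuine buried/exposed WCN gradient — the property the
  profiles measure — plus an ideal α-helix (rise 1.5 Å, radius 2.3 Å, twist
  100°/residue) and a two-domain variant.
* **B-factors.** `B = 15·wcn⁻¹ + 5 + ε`, ε ~ N(0, sd²) with sd = 3 Å² by
  default, floored at 0.01 Å². Packing tracks mobility, and the noise knob
  makes the B-factor channel a strictly degraded copy of the packing signal,
  which is what produces the SEQ-beats-B-factor ordering in the recovery
  experiments.
* **Labels.** Three "catalytic" residues per 100-residue protein, drawn
  uniformly from the residues below the chain's 10th percentile of Z_SEQ
  (window 1) — rigid positions, as real catalytic residues are.

What the generator does **not** model: real secondary-structure statistics,
side chains, sequence composition biases of catalytic sites (real catalytic
residues are overwhelmingly polar/charged; synthetic sequences are uniform
random), crystal-packing artifacts in B-factors, and inter-chain contacts.
Passing recovery tests therefore demonstrates that the pipeline recovers
packing-defined rigid sites from geometry; absolute performance numbers on
real enzyme datasets depend on biology the generator deliberately omits, and
the amino-acid feature contributes nothing on synthetic sequences.

## Problem sizes and numerical choices

The end-to-end experiments run at 20 proteins × 100 residues × 3 planted
sites (60 positives among 2,000 residues), a scale at which the full
protocol — profiles, balanced training, 110-point grid search inside 5×5
folds — completes in seconds per feature set while leaving the class
imbalance (3%) severe enough to exercise the balancing machinery. The
window-size sweep averages the planted-vs-background Z_SEQ medians gap over
5 replicate datasets because the gap estimator from a single 20-protein draw
has ~±0.03 sampling jitter, comparable to the flat stretch of the trend
between windows 1 and 5; the decline is steep for windows ≥ 10.

Oracle tests compare the vectorized WCN/SEQ/STR implementations against
naive double loops at 10⁻¹² absolute tolerance; geometric invariances
(rigid motions, scaling) are asserted at 10⁻⁹ to allow for floating-point
rotation error.

## Known limitations

* B-factors are taken from the Cα atom only, not residue-averaged.
* PSSM conservation aligns to the chain by sequential position (PSSM files
  carry no author numbering); chains with unresolved interior residues will
  shift and are flagged by the letter-agreement check (>5% mismatch is an
  error).
* mmCIF input, biological-assembly generation, and multi-chain WCN unions
  are not implemented; the analysis unit is one chain.
* Probability calibration relies on libsvm's internal Platt scaling, which
  itself cross-validates on the (small, balanced) training set; with very
  few positives the probabilities are coarse, though ranks remain stable.
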
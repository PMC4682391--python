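# Methods

## Problem and model

Binding affinity of a heterodimeric protein complex is summarized by the
dissociation constant Kd (molar); pKd = −log10 Kd.  Complexes with
Kd < 10⁻⁸ M are treated as the high-affinity class, Kd ≥ 10⁻⁸ M as low.
The package predicts the class, and estimates pKd, from the two chain
sequences alone.

**Encoding.**  A complex is reduced to its amino-acid composition
w(a), the fraction of each of the 20 standard residues over both chains
pooled.  Each amino-acid property table p (AAindex1 format) contributes one
feature, the total physicochemical property

    TPCP(p) = Σᵢ w(aᵢ) · PCPₚ(aᵢ),

the composition-weighted mean of the property over the complex.  The
encoding is order-independent (invariant to residue permutation and chain
swap) and maps variable-length complexes to a fixed-length vector — one
column per property table, 580 columns for the full candidate panel (531
AAindex tables plus supplementary literature descriptors supplied by the
user in the same format).  Non-standard residues (X, B, Z, U, `*`) are
removed before anything else; complexes with a sanitized chain shorter than
50 residues are dropped.  Features are affinely rescaled to [−1, 1] using
per-column minima/maxima learned from training data only; out-of-range
values in later data are clipped.  Train-only scaling is a deliberate
choice: fitting the scaler on all data would leak test information, and the
clipping rule makes application to new data total.

**Classifier and regressor.**  A soft-margin SVM with RBF kernel
K(x, y) = exp(−γ‖x−y‖²) classifies; ε-insensitive SVR with the same kernel
estimates pKd.  Both are scikit-learn (libsvm) behind the package's module
surface.  C and γ live on the 16-point grid {2⁻⁷, …, 2⁸} indexed by 4-bit
genes.  Default SVR ε = 0.1 pKd units (of the order of the reproducibility
of careful Kd measurements).

**Metrics.**  Accuracy (percent), sensitivity (recall of the high class,
the positive class), specificity, and MCC from confusion counts;
MCC is defined 0 when its denominator vanishes, while an absent positive or
negative margin is an error (sensitivity/specificity undefined).  AUC is
the positive-outscores-negative probability with ties counted half.
Cross-validation is stratified; confusion counts and decision scores are
pooled over folds and metrics computed once on the pooled counts — pooling
is reproducible and matches reporting single per-protocol values.  Scaling
is re-fit inside every training fold.  The regression protocol is the
jackknife (leave-one-out), reporting Pearson r and MAE of the held-out
predictions.

## Feature selection (IBCGA)

Selecting m informative columns from n = 580 is the combinatorial problem
C(n, m).  The inheritable bi-objective combinatorial GA encodes a
chromosome as the 580-bit feature mask plus the two 4-bit parameter genes,
and maximizes the lexicographic objective (10-fold CV accuracy, then fewer
features).  One stage holds the feature count at r: tournament selection
(size 2), orthogonal-array crossover, popcount-preserving mutation
(swap one 1-bit with one 0-bit and/or nudge a parameter gene ±1), with the
stage best exempt from mutation and preserved by elitism.  After a fixed
generation budget the stage best is recorded, every individual flips one
random 0-bit to 1 (inheritance), and the search continues at r+1, from
r_start = 10 through r_end = 20.  The overall best across stages is
reported.

**Orthogonal-array crossover.**  Differing gene positions (mask bits; each
parameter gene atomic) are grouped into at most 7 factors — contiguous
blocks of the sorted differing positions via `np.array_split`.  The
two-level L8(2⁷) array (Hadamard construction: level(i, j) =
parity(popcount(i & j))) defines eight candidate children taking each
factor from parent 1 or 2; candidates are repaired to popcount r (random
bit clears/sets) and evaluated; per-factor main effects (mean fitness at
level 1 minus level 2) compose a predicted-best child; the best evaluated
candidate is returned.  At most nine fitness evaluations per crossover.
For additive fitness the composed child is provably the optimum over all
parent-level combinations, which the tests exploit as an exhaustive oracle
(repair disabled via `target_r=None`, since repair would perturb the
enumeration).

**Fitness determinism and caching.**  Fold assignment is a pure function of
(seed, labels); chromosome fitness is cached by (mask, genes), so converged
populations cost little.  Two runs with the same config are byte-identical.

**Search defaults** (population 50, 60 generations/stage, crossover rate
0.5, mutation rate 0.05): chosen so a 580-feature, 200-complex run
completes in a few minutes on one core.  Termination and inheritance are
ordered as: the generation-budget test applies per stage; inheritance then
fires if r < r_end, else the algorithm stops and reports.

## Feature importance

*Knock-out*: difference accuracy = CV accuracy of all m selected features
minus CV accuracy with one feature removed (same folds), per feature —
an individual, redundancy-sensitive contribution.  *Main-effect difference*
(MED): CV accuracy is evaluated over the keep/drop subsets given by the
rows of a two-level orthogonal array with ≥ m columns (L4…L32; all-drop
rows skipped); MED of a feature is the mean accuracy over rows keeping it
minus rows dropping it.  MED averages over many backgrounds, so its
magnitudes exceed knock-out differences; the two are deliberately distinct
operations and reports label which was used.  Per-class statistics: mean
composition percentages per class with their difference, and per-class
means of a property statistic with an optional residue restriction (e.g.
hydrophobic subset) under either a composition-weighted ("mean") or total
("sum") weighting — both weightings are exposed because published
per-class property summaries are reproducible under either convention.

## Synthetic data

The generator emulates the target study design at realistic defaults:
n = 200 balanced complexes (216 for the holdout arithmetic), two chains of
100–300 residues, 580 candidate tables with iid standard-normal values,
5 informative, effect size 2 pooled-SDs, pKd centered at 8 with slope 2
per planted-projection unit and N(0, 0.5²) measurement noise, giving pKd
roughly in 3–13 (the µM-to-fM span of published heterodimer sets) and
labels by thresholding Kd at 10⁻⁸ M — so labels and affinities are
consistent by construction, and at effect size 0 labels are pure noise.

Both classes share a uniform base composition w0; class profiles are
w0 ± d/2.  The shift d lies in the span of the centered informative table
vectors and is solved through the Gram system so each informative TPCP
feature separates the class means by exactly `effect_size` pooled
within-class SDs (within-class SD from multinomial residue sampling at the
mean total length).  Chains are drawn residue-by-residue from the class
profile; pKd is a linear function of the complex's empirical composition
projected on d.

**Why the noise tables are decorrelated, not merely random.**  Every TPCP
feature is a linear projection of the same ≤19-dimensional composition, so
"uninformative" is not automatic for a random table: (i) a random table
overlaps d and inherits up to ~3 pooled-SDs of class signal (more than a
planted column); (ii) even with zero overlap, the multinomial variance of
its feature differs between class profiles, which an RBF-SVM detects; and
(iii) noise columns correlated with the informative columns' sampling
fluctuations act as denoising helpers that substitute for missing planted
columns.  Any of these makes planted ground truth ill-defined — feature
sets without the planted columns reach the same accuracy.  The generator
therefore projects every non-informative table to be (a) orthogonal to the
span of the centered informative vectors (killing the mean channel and,
because multinomial noise around a near-uniform profile is isotropic on
the simplex tangent, the correlation channel to first order) and (b) free
of the residual class-variance difference ((v∘v)·d = 0), via a short
Gauss-Newton projection.  Higher moments differ only at O(1/L²).
Empirically, noise-only feature sets then classify at chance while planted
sets retain their designed effect sizes.

**The recovery experiment runs at low measurement noise.**  Planted-truth
recovery is only a well-posed experiment when the class labels actually
follow the planted features: at the default pKd noise (SD 0.5), ~2.5% of
labels fall on the wrong side of the threshold and the accuracy margin per
planted column (~0.5 points) drops below the resolution of 10-fold CV at
n = 200 (0.5 points per complex), so even an exhaustive optimizer of CV
accuracy has no reason to prefer the planted set.  The recovery tests in
this package therefore generate their datasets with pKd noise SD 0.1
(high-quality single-method measurements), where the per-column margin is
1–2 points and the top of the accuracy landscape requires the planted
columns.  The general-use default remains 0.5.

What the generator does **not** emulate: real interface biophysics,
inter-complex homology structure, composition variation unrelated to
affinity, or order-dependent sequence signal (the encoding would ignore
the latter by design).  Passing the planted-recovery tests therefore shows
the search recovers a recoverable signal at realistic scale — not that 580
real descriptors contain one.

## Numerical choices and degenerate inputs

Ties in the bi-objective ordering resolve toward fewer features; MED rank
ties resolve in selection order.  Repair clears/sets uniformly random
bits.  Constant regression predictions yield Pearson r = NaN with a
warning (MAE still reported).  Constant feature columns scale to 0.
A chromosome selecting zero columns, a single-class training set, a class
smaller than the fold count, and an empty residue restriction are errors,
not silent fallbacks.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 24–60-property, 80–150-complex instances; the planted
recovery test runs the full 580-property, 200-complex, population-50
search for five seeds; the acceptance script uses a 216-complex study with
a reduced search budget (population 30, 12 generations/stage, r 10–14) so
the end-to-end run completes in a few minutes.  These sizes are the
package's own desk-scale choices; the library accepts arbitrary sizes.

## Known limitations

Wrapper selection against a fixed fold assignment can overfit the folds by
1–3 accuracy points at n = 200; the reported CV accuracy of the selected
model is therefore optimistic, and an untouched holdout (the `evaluate`
command's 75/25 protocol) gives the honest estimate.  Composition encoding
caps the number of genuinely independent features at ~19; large candidate
panels are necessarily redundant.  Jackknifed SVR inherits the usual
leave-one-out variance at small n.
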
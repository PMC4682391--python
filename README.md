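# seqaffinity

Sequence-based prediction of heterodimeric protein–protein binding affinity.

Many protein complexes of pharmacological interest are heterodimers whose
binding strength — the dissociation constant Kd, spanning µM to fM — is
expensive to measure and usually unknown.  `seqaffinity` predicts affinity
from the two chain sequences alone: it classifies complexes into high
(Kd < 10⁻⁸ M) versus low affinity, estimates pKd = −log₁₀ Kd by regression,
and reports which amino-acid properties carry the signal.

## Method

Each complex is encoded by its amino-acid composition w(a) over both chains
pooled.  An amino-acid property table p (AAindex1 format) contributes the
feature

TPCP(p) = Σᵢ w(aᵢ) · PCPₚ(aᵢ),

the composition-weighted mean of property p over the complex — a
fixed-length, order-independent representation of a variable-length dimer.
From a large candidate panel (e.g. 531 AAindex tables plus literature
descriptors, 580 columns), an inheritable bi-objective combinatorial
genetic algorithm (IBCGA) selects a small subset of m ∈ [10, 20] columns
jointly with the parameters C, γ ∈ {2⁻⁷…2⁸} of an RBF-kernel SVM,
maximizing stratified 10-fold cross-validation accuracy and, at ties,
minimizing m.  The GA uses tournament selection, orthogonal-array (L8)
crossover with main-effect composition, popcount-preserving mutation,
elitism, and an inheritance step that grows the feature count r by one
while reusing the population.  Affinity values are estimated by jackknifed
ε-SVR on the selected columns.  Feature importance comes from knock-out
differences (accuracy drop when one selected column is removed) and
main-effect differences (MED) over an orthogonal keep/drop design.

See `docs/methods.md` for the model, parameter defaults, the synthetic
benchmark design, and known limitations.

## Worked example

Simulate a benchmark with planted ground truth, select features, and
evaluate — all from the shell:

```
seqaffinity simulate --n-complexes 80 --n-properties 24 --n-informative 3 \
    --seed 5 --out demo/data
seqaffinity encode --manifest demo/data/manifest.tsv \
    --properties demo/data/properties.aaindex --out demo/matrix.tsv
printf 'population_size = 14\ngenerations_per_stage = 4\nr_start = 3\nr_end = 4\ncv_folds = 5\nseed = 5\n' > demo/search.cfg
seqaffinity select --matrix demo/matrix.tsv --manifest demo/data/manifest.tsv \
    --config demo/search.cfg --out demo/selection
seqaffinity evaluate --matrix demo/matrix.tsv --manifest demo/data/manifest.tsv \
    --selection demo/selection/selection.json --protocol 10cv --seed 0 \
    --out demo/metrics
```

The `select` step prints the best stage result:

```
best r=3 cv_accuracy=96.25% C=128 gamma=0.0625
```

meaning the search kept 3 of the 24 candidate properties and reached 96.25%
cross-validated accuracy with the decoded SVM parameters shown, and
`evaluate` prints the pooled cross-validated confusion metrics of that
model:

```
10cv accuracy=95.00% mcc=0.900
```

(accuracy percent over the 80 complexes; MCC in [−1, 1], 0 = chance; the
selection step's figure is 5-fold as configured, the evaluation 10-fold).
`demo/selection/selection.json` lists the selected property ids — with the
demo seed, two of the three planted informative properties
(`ground_truth.json`) are among them — and `demo/metrics/metrics.json`
holds the full report (sensitivity, specificity, MCC, AUC).  The same steps run on real data: a TSV manifest
(`complex_id`, `chain_a`, `chain_b`, `kd_molar` or `pkd`, optional
`label`) or paired FASTA (`id_A`/`id_B`), plus any AAindex1 property file.
The three property tables discussed in the importance analyses
(GUYH850105 apparent partition energy, SNEP660104 principal component IV,
CHOP780101 beta-turn frequency) ship with the package (`--builtin`).

A pKd regression on the same data:

```
seqaffinity evaluate --matrix demo/matrix.tsv --manifest demo/data/manifest.tsv \
    --selection demo/selection/selection.json --protocol jackknife --out demo/svr
```

prints `jackknife r=0.892 mae=0.958` — the Pearson correlation and mean
absolute error (pKd units) of leave-one-out predictions.

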
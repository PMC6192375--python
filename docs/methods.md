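# Methods

This note documents the models and procedures implemented in `qsarcons`,
the parameters that matter, the numerical choices behind them, and what the
synthetic benchmark does and does not demonstrate.

## Structure model and curation rules

Molecules are hydrogen-complete colored graphs: after parsing (SMILES or
SDF V2000, via RDKit) hydrogens are added according to valence and formal
charge, and each atom carries its element symbol, formal charge and an
in-ring flag (cycle membership of the graph). Bond orders are deliberately
not recorded — both descriptor families operate on connectivity only.
Formal charges are read from the input, never inferred.

A structure enters modelling only if it is a single connected component,
net-electroneutral, contains carbon, and has molecular weight between 50
and 1250 Da. Multi-component records (salts, mixtures) are rejected by
default; `strip_salts=True` keeps the largest carbon-containing fragment
and re-applies the rules to it. Rejection is a value with a machine-readable
reason code, not an exception, so curation reports are complete.

Activity records are kept only when the endpoint is Ki or IC50, the value
is a positive number in nM and the relation is exactly "=". Replicates are
aggregated per compound by the median (the median of an even count is the
mean of the central pair), which is robust to the strongly skewed replicate
distributions typical of heterogeneous assay collections. Values are then
transformed to p-units, p = −log10(value·10⁻⁹), and labeled active when
p ≥ 6 (1 µM); the boundary compound counts as active, configurable via
`boundary_active`. No assay-type filter is applied: receptor datasets in
this domain mix functional antagonism and binding-affinity records that
cannot be told apart from the exported fields, which is a documented
limitation of the curation layer, not of this implementation.

The fivefold split sorts compounds ascending by aggregated activity (ties
broken by compound id so the split is reproducible) and deals fold numbers
1–5 cyclically down the list. Fold sizes differ by at most one and every
fold spans the activity range, which stabilizes external statistics on
skewed sets.

## QNA descriptors

Per atom i, with C the binary connectivity matrix and E = exp(−C/2),

    P_i = B_i Σ_k E_ik B_k ,   Q_i = B_i Σ_k E_ik B_k A_k ,

where A = (IP+EA)/2 and B = (IP−EA)^(−1/2) come from tabulated neutral-atom
ionization potentials and electron affinities (eV), shipped as a versioned
TSV (`qsarcons/data/atomic_electronic.tsv`) covering H, B, C, N, O, F, Si,
P, S, Cl, Br, I. Formal charge shifts both IP and EA by 3 eV per unit of
charge, which moves the electronegativity midpoint A while leaving B
unchanged; the shift size is a convention, chosen on the scale of valence
ionization energies. Hydrogens are included in C and in the sums, matching
the explicit-hydrogen convention of the MNA representation.

The matrix exponential is computed by symmetric eigendecomposition, exact
for the symmetric C; a 60-term Taylor series serves as the independent test
oracle. E_ik decays rapidly with topological distance, so P and Q are
whole-molecule-aware but locally dominated.

For regression, P and Q are squashed into (−1, 1) by x → x/(s+|x|) with
per-channel scales s frozen at fit time as the median |P| and |Q| over all
training atoms, and the molecule is represented by the averages over atoms
of T_m(P̂)·T_n(Q̂) for all m+n ≤ D. The default degree D = 6 gives 28 basis
terms — expressive enough for the benchmark while keeping single-model
regressions small. The nine whole-molecule descriptors are appended:
topological length (graph diameter in bonds, hydrogens included),
topological volume (total atom count — a declared surrogate, since no
standard definition exists), Crippen additive logP, counts of positive and
negative formal charges, H-bond acceptors (N/O atoms not positively
charged), aromatic atoms (parser's Hückel perception), molecular weight and
halogen count.

## MNA descriptors and the activity-spectrum engine

MNA descriptors are canonical strings built recursively on the
hydrogen-complete graph: level 0 is the atom mark (element symbol, "-"
prefix when not in a ring, explicit charge suffix), and level k+1 for atom
a is `mark(a)(D1D2…)` with the neighbors' level-k descriptors concatenated
in lexicographic order. The default depth is 2. The per-molecule descriptor
multiset is invariant under atom relabeling by construction.

The PASS-style engine estimates, for every activity in a vocabulary
(default 200 synthetic activities, standing in for the thousands of a
production activity-spectrum knowledge base), the probability Pa of being
active and Pi of being inactive. Internals: a descriptor is *selected* for
an activity when its occurrence among that activity's actives is
significantly enriched or depleted (exact hypergeometric tail probability
≤ `p_select`, default 0.01 — an exact test, so selection also works on
small corpora). A compound's raw score per activity is the sum of
Laplace-smoothed log-odds log[P(d|active)/P(d|inactive)] over its selected
descriptors. Raw scores are calibrated by rank against the leave-one-out
score distributions of the corpus (each training compound scored with its
own contribution removed from the counts, exactly as an external query is
scored): Pa is the fraction of training inactives the query outscores, Pi
the fraction of actives outscoring it, ties counted half. Pa and Pi are
probabilities that do not sum to one; Pa − Pi ∈ [−1, 1] is the decision
value. A query sharing no descriptor with the corpus gets Pa = Pi = 0.5.

Two approximations are documented: descriptor selection is frozen on the
full corpus during the leave-one-out calibration (frequencies are
re-estimated, selection is not), and training self-queries are scored with
the full table. A plain Bernoulli naive Bayes over the complete vocabulary
was evaluated and rejected: with a single informative descriptor among
roughly a thousand, the class signal is drowned by accumulated smoothing
noise and leave-one-out accuracy saturates near 0.80 on perfectly separable
corpora; the significance-selected scorer reaches ≈0.99 under the same
conditions.

The regression stage consumes Pa − Pi values for seeded random activity
subsets — a different subset per single model, which is one of the two
sources of ensemble diversity.

## Self-consistent regression

A single model is a ridge regression on standardized features with the
intercept unpenalized. The ridge strength is chosen once, on the full
variable set, by maximizing leave-one-out Q² over the grid
{0.01, 0.1, 1, 10}; exact duplicate columns are collapsed before fitting.
Variables are then eliminated backwards: first every variable with
|coefficient|/SE below `t_threshold` (default 2.0, an approximate 95%
criterion), one at a time with refitting; then the weakest remaining
variable as long as removal improves Q². The procedure is deterministic for
fixed inputs.

Leave-one-out statistics use the closed form e_i/(1−h_ii) for linear
smoothers on the fixed standardized design, which is algebraically exact
for ridge and verified in the tests against an explicit n-refit loop.
Training R² is 1 − RSS/TSS, defined as 0 when the response is constant.
Internal validation is the mean external R² over five random 80/20 splits,
reproducible from a seed; within the consensus builder the clone refitted
per split keeps the already-selected ridge strength (the elimination is
re-run), which keeps the ensemble build inexpensive without touching the
statistic's meaning.

Qualitative (SAR) models are the same fitter applied to classes coded
+1/−1 and thresholded at zero — the deliberate point of the framework is
that the qualitative and quantitative branches share data, descriptors and
algorithm, so their accuracies are directly comparable.

## Consensus, applicability domain, validation protocol

Per training set, `n_models` single models are built (default 320, the
scale used for production ensembles; the benchmark and tests use 32 to keep
a desk-scale footprint). Models alternate between the QNA family and the
MNA/Pa−Pi family when both are available; half of the builds drop a random
half of their family's feature block, every model draws its own
internal-split seed, and MNA models draw their own activity subsets. A
model is retained only if R²_train > 0.5, Q²_train > 0.5 and internal R̄² >
0.5. Zero retention is the explicit "no model" state: `predict` refuses,
and the cross-validation driver records the fold, excludes it from model
means and falls back to the training-mean (QSAR) or majority-class (SAR)
baseline so that pooled statistics remain defined — on null data this
yields R² ≈ 0 and BA ≈ 0.5 by construction, which is exactly the intended
calibration reading.

Applicability domain: per single model, query similarity is
s = 1/(1 + d̄₃), the mean Euclidean distance to the 3 nearest training
compounds in the model's standardized selected-variable space. The model's
AD threshold is the similarity at the mean + 3 SD of the training
self-distances; a compound is inside the consensus AD when at least half of
the retained models accept it. Consensus predictions are
similarity-weighted averages, hence always convex combinations of the
single-model predictions. Homogeneous series are expected to sit ~100%
inside the AD, and the benchmark reproduces this (~99%).

External validation is fivefold: build on four folds, predict the fifth;
reports carry per-fold, mean-over-folds and pooled variants (pooled
confusion counts are sums over folds; pooled R² uses per-fold training
means as reference, and the conventional test-set-mean R² is reported
separately as `r2_test_mean`). Quantitative predictions are additionally
class-transformed at the same 1 µM rule used for the truth labels, sharing
a single thresholding function. Y-randomization shuffles the response five
times, refits and averages Q². The SAR-vs-QSAR comparison uses a two-sided
Wilcoxon signed-rank test across paired datasets; with identical inputs the
p-value is defined as 1.

## Synthetic benchmark

The generator grows random spanning trees over {C, N, O, S, F, Cl, Br, I}
with strict valence bookkeeping, adds Poisson-distributed ring closures
(mean 1.5) between atoms at graph distance ≥ 3, and fills hydrogens — every
molecule passes standardization by construction. Default 8–24 heavy atoms.
The planted activity is p = intercept + 0.12·n_heavy + 0.45·n_halogen +
0.30·n_HBA + ε with ε ~ N(0, 0.2²) p-units; the intercept is placed so
that a target fraction (default 0.4) of compounds is active at 1 µM, and
the resulting p-values span roughly four log units. Each compound emits 1–5
replicate rows with lognormal scatter (σ = 0.3 log10 units, the motivation
for median aggregation), and ~10% of compounds get an extra junk row
(wrong unit or relation) to exercise the filters. The activity-spectrum
corpus plants one MNA descriptor rule per activity, drawn among descriptors
of intermediate frequency so both classes are populated.

The benchmark conditions used by the test suite and the acceptance script
are 300 compounds, noise 0.2 p-units, 32-model consensus ensembles, ten
seeds — sizes chosen to exercise every stage at desk scale. What passing
shows: the full pipeline detects a planted linear structure–activity signal
(external R² ≈ 0.95, SAR BA ≈ 0.93), reports nothing on null data (all
single models fail the thresholds), and its Q² collapses under response
shuffling. What it does not show: performance on real, chemically diverse
bioactivity data — the synthetic molecules are single-bonded random graphs
without aromatic systems, tautomers or stereochemistry, the planted signal
is linear in counts that partially coincide with the whole-molecule
descriptors (making it learnable by design), and replicate scatter is
idealized lognormal noise.

## Known limitations

* The electronic parameter table covers common organic elements only;
  exotic elements raise a named error rather than guessing.
* The charge adjustment of IP/EA and the Chebyshev squashing scales are
  conventions; both are recorded in the model so they can be swapped.
* The SAR branch is coded-label regression, not a margin-based classifier;
  probability calibration of its scores is out of scope.
* `aggregate_replicates` and the curation layer operate per endpoint and do
  not reconcile Ki with IC50 for the same compound.
* The AD similarity transform and threshold are one reasonable convention
  (nearest-neighbor distance, mean + 3 SD calibration); alternatives such
  as leverage-based domains are not implemented.
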
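# Methods

## Model and procedure

`metconc` models the negative log molar concentration of intracellular
metabolites, Y = −logC, as a function of per-metabolite descriptors.
The full pipeline is: assemble descriptors → variance filters → genetic
algorithm (GA) variable selection → add/remove hill climb → optional
MPF collapse → ε-SVR fit → internal/external validation → leverage
applicability domain.

**Response transform.** Concentrations must be positive molar values;
−logC = −log10(c). Base 10 is fixed: the packaged reference table's
values are consistent with log10 of molar concentrations. Records may
carry the concentration, the transform, or both (checked for agreement
to 1e−9). Missing values are the literal `NA` in all files.

**Network reconstruction.** The metabolite network is a simple
undirected graph built from substrate–product reactant pairs under two
screens: the pair's pathway annotation must intersect the organism's
pathway set, and pairs flagged as containing unspecified residues
(generic "R" groups) are dropped. Self-pairs create nodes but never
edges; parallel pairs collapse to one edge. Per-node descriptors are
the degree n and the clustering coefficient 2e/(n(n−1)) with e the
edge count among neighbours; nodes of degree 0 or 1 take clustering
coefficient 0 (the NetworkAnalyzer convention). The graph container and
the clustering computation are delegated to networkx; the test suite
checks the clustering coefficient against an independent brute-force
neighbour-pair count. Metabolites in the dataset but absent from the
network receive degree 0 and clustering coefficient 0 with a logged
warning, so a missing mapping degrades gracefully instead of failing.

**Feature assembly.** Molecular descriptors are consumed as delimited
text and shared between organisms; topology descriptors are
organism-specific; pathway variables are binary membership indicators.
Missing molecular cells are rejected by default (strict mode) or
mean-imputed with a logged count (lenient). Pathway variables with a
minority class below 2 rows are dropped as near-constant (the cutoff is
configurable). The variance filters then remove exactly-constant
columns and columns with sample standard deviation (n−1 denominator)
below 0.001. Features enter the SVR unscaled by default; an optional
z-scoring switch is recorded in the run manifest when enabled.

**Variable selection.** Fitness of a candidate subset is the LOO RMSE
of the downstream regressor restricted to those columns. The GA uses
fixed-length bit-vector chromosomes over the current pool, tournament
selection (size 2), uniform crossover (rate 0.8), bit-flip mutation
(rate 0.01), elitism 1, population 100 and 100 generations by default,
over three chained rounds (each round's winner is the next round's
pool). Initial bits are Bernoulli with expected subset size 40% of the
pool. All operator settings are config-exposed; the best-so-far fitness
is non-increasing by construction (elitism). The subsequent hill climb
is steepest-descent: each iteration evaluates every single deletion and
every single addition from the full filtered pool and accepts the best
strictly-improving move; ties prefer the smaller subset, then the
lexicographically first changed name, making the procedure
deterministic. It stops at a verified local minimum (worst case:
returns its input unchanged).

The fitness regressor defaults to the same ε-SVR used downstream and is
config-swappable to ridge regression for desk-scale runs. The ridge
path uses the exact linear-smoother LOO shortcut e_i/(1−h_ii), which
makes a full selection run on ~50–100 descriptors a matter of seconds;
the SVR path performs the literal n refits. Both paths are validated
against an independent per-sample refit loop in the tests.

**MPF collapse.** Pathway variables that survive the hill climb are
replaced by the single MPF descriptor (their element-wise OR) and the
model is refit. This resolves the ordering problem that the MPF
descriptor is defined by the outcome of selection.

**SVR and validation.** ε-SVR with RBF kernel exp{−γ|μ−ν|²}; default
hyperparameters γ=0.01, ε=0.20, C=11 (the reference tuned values), and
a default search grid γ∈{0.001,0.01,0.1,1}, ε∈{0.05,0.1,0.2,0.4},
C∈{1,11,100} bracketing them. Grid search minimizes cross-validated
RMSE (LOO or 10-fold) with deterministic tie-breaking toward smaller C,
then smaller γ, then smaller ε. Cross-validation assembles the
out-of-fold prediction vector and applies RMSE and Q² once to it;
10-fold folds come from a seeded shuffled partition. R² is the squared
Pearson correlation of predicted vs observed (the standard QSAR
reading); Q² on the external test set uses the test-set mean in the
denominator by default, switchable to the training-mean convention.
`repeated_trials` re-splits/refits n_trials times (default 20) and
reports mean ± sd per metric. Models persist as versioned JSON
(support vectors, dual coefficients, intercept) — no binary pickles.

**Applicability domain.** Leverage h = xᵀ(XᵀX)⁻¹x against the raw
selected-descriptor training matrix (no intercept column appended;
test-sample leverage is computed against the training X, the standard
practice). Threshold h* = 3k/n. Standardized residual = raw residual /
RMSE of training residuals, which keeps the ±3 band interpretable. A
rank-deficient XᵀX is a hard error naming the likely collinear columns;
a pseudo-inverse mode exists for diagnostics only, because domain
statistics under rank deficiency are misleading.

## Synthetic benchmark

The generator emulates the statistical structure the model assumes:
−logC = 3.5 + Σc_j·d_j + t·CC + offset·(#deviant pathway memberships)
+ N(0, sd). Defaults: 130 records across two organisms (a configurable
fraction of compounds measured in both — those share molecular and
pathway values but get organism-specific topology), 50 molecular
descriptors of which 5 are informative (coefficients 1.0, −0.8, 0.7,
−0.6, 0.5), noise sd 0.2 −logC units, topology effect t = −0.5 (denser
neighbourhoods ⇒ higher concentration ⇒ lower −logC), and offset −1.0
per membership in one of 3 "deviant" pathways (non-core pathways whose
members run at higher concentration than their polarity suggests).
The strongest informative descriptor is labelled `ClogP` and enters
with a positive coefficient, playing the polarity role (−logC rising
with the partition coefficient), so the CLogP-binned correlation report
has a meaningful column to work on in synthetic runs. Descriptor
columns are correlated Gaussians via the Cholesky factor of a random
SPD correlation matrix, so collinearity stresses selection.
Networks are Erdős–Rényi (mean degree 4) or Barabási–Albert per
organism; edges are emitted as reactant pairs tagged with organism
pathways, plus decoy pairs exercising both screening criteria.

The pathway term is additive per membership, which makes the signal
exactly linear in the assembled feature columns; consequently the
noiseless limit is perfectly recoverable by the pipeline (LOO Q² → 1),
a deliberate property used as a structural check. The truth object
records the analytic descriptor-signal variance cᵀΣc and the pathway
variance offset²·Σq_j(1−q_j); the analytic R² is exact when the
topology effect is 0 (clustering-coefficient variance has no closed
form here).

What the generator does **not** emulate: real descriptor physics (no
structures or SMILES), measurement-protocol batch effects,
heteroscedastic assay noise, or the heavy-tailed concentration
distributions of real metabolomes. Passing tests therefore demonstrate
correctness and recoverability of the procedure, not field performance
on experimental data.

## Problem sizes and numerical choices

Tests and the acceptance script run the selection study at n=120
records, 50 descriptors, GA population 40 × 40 generations × 3 rounds
with the ridge fitness configuration — sizes chosen so a full
10-seed recovery study completes in seconds on one CPU while leaving
the selection problem genuinely hard (correlated descriptors, ~70-way
pools). The end-to-end validation cycle uses the reference split sizes
91/39 on 130 records. Fitness values are cached per chromosome;
chromosome, fold and split randomness all derive from a single seed via
spawned generators, so every pipeline run is bit-reproducible
(verified by a byte-identity test on all numeric reports).

Degenerate inputs: empty chromosomes get infinite fitness; an empty
screened network is valid (with a warning); Q² is a hard error on a
constant response (zero total sum of squares); non-finite descriptor
values are rejected before the kernel matrix is formed; LOO requires
n ≥ 3; hill-climb hat diagonals are clipped below 1 to avoid division
blow-ups on exactly-interpolating ridge fits.

## Open choices made here

* The 91/39 split is unstratified by organism (the stratification
  status of the reference procedure is unknown).
* Non-overlap splitting (compounds shared between organisms kept on one
  side) assigns whole compound groups greedily by descending size,
  seeded shuffle breaking ties, to approach the target train size; no
  assignment algorithm is prescribed elsewhere.
* Concentration tertiles (Low/Medium/High vs mean clustering
  coefficient) use near-equal group sizes from the sorted
  concentrations (difference ≤ 1, remainder to the higher groups)
  rather than fixed concentration breakpoints.
* GA pool shrinkage is fitness-driven only; no per-round size quota is
  imposed.
* No currency-metabolite filtering beyond the reactant-pair convention
  itself.

## Known limitations

* The SVR fitness path is O(n) refits per subset evaluation; full
  GA budgets (100×100×3) with SVR fitness on thousands of descriptors
  are an overnight-scale computation — use the ridge fitness for
  exploration and the SVR fitness for final runs.
* Leverage assumes a full-column-rank selected matrix; heavily
  collinear selections must be pruned before domain analysis.
* The hill climb is a local optimizer; the exhaustive-optimum guarantee
  in the tests holds only at oracle scale (≤ 12 columns).
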
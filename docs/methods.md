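# Methods

## Scope and data model

The package models the potency of a small congeneric compound series as a
linear function of precomputed molecular descriptors. Descriptor values
are *inputs*: computing them from structures (3D conformers, interaction
fields, pharmacophore triplets) is out of scope. The canonical container
is a rectangular table — compound id, one or more pIC50 response columns
with missing entries allowed, numeric descriptor columns — read from CSV
(UTF-8, comma-separated, header mandatory, missing-response sentinels
`–`, `-`, empty, `NA`, `ND`). Concentrations are molar internally; potency
CSVs carry an explicit unit column (nM in the bundled data) converted on
load, which avoids silent 10⁹ errors when mixing nanomolar assay readouts
with log-molar responses. pIC50 = −log10(IC50 [M]); display convention is
3 decimals for pIC50 and 2 decimals for selectivity ratios.

The bundled study data comprise a 22-compound descriptor table with six
descriptors (IW1/IW2: hydrophilic-region interaction-energy moments;
FLEX: conformational flexibility; PSA: polar surface area; ACDODO: an
acceptor–donor–donor pharmacophore-triplet count; DD8: a
conformer-dependent hydrophobic-volume difference), pIC50 responses for
two kinases (22 values for the V600E mutant B-RAF, 9 for RAF1), the
measured kinase IC50s, a 30-kinase percent-inhibition panel, and melanoma
/ normal-skin cell-line IC50s. A consistency check verifies that every
measured IC50 reproduces the corresponding tabulated pIC50 at 3 decimals
(tolerance 5e−4 after rounding); the bundled tables pass with zero
discrepancies.

## Regression and diagnostics

Fits are ordinary least squares with an intercept always included and no
descriptor standardisation, so coefficients stay on the raw descriptor
scales practitioners quote. The solver is an orthogonal-decomposition
least squares (LAPACK via `numpy.linalg.lstsq`), never an explicit
normal-equations inverse; rank is assessed by pivoted QR with a relative
condition threshold of 1e−10 and deficiency is reported by naming the
dependent columns. Construction requires n ≥ p + 2 so that the residual
degrees of freedom n − p − 1 used by s and F are positive.

Diagnostics follow the conventions of small-n QSAR reporting:
R² = 1 − RSS/TSS (TSS about the response mean), s = sqrt(RSS/(n−p−1)),
F = (R²/p)/((1−R²)/(n−p−1)). The F form is algebraically MSR/MSE; the
tests assert that identity to 1e−10. The standard error of estimate is
the degrees-of-freedom-corrected form, not the training RMSE — refitting
the bundled 9-compound model supports this reading (s = 0.118 vs
RMSE = 0.096).

Leave-one-out cross-validation predicts each compound from a model fitted
on the remaining n − 1. The default implementation uses the exact OLS
identity (held-out residual = e_i/(1 − h_ii), h the leverage); an explicit
refit loop is provided and the two are asserted equal to 1e−10 relative
PRESS on randomised datasets. Q² = 1 − PRESS/TSS with TSS about the mean
of the *full* training response — the common QSAR convention — rather than
fold-wise means. Q² ≤ R² and PRESS ≥ RSS hold universally and are tested
as properties. LOO requires n ≥ p + 3 so each fold retains a fittable
design.

Confidence and prediction bands around the regression are the classical
t-based OLS intervals: half-widths t·s·sqrt(h) for the mean response and
t·s·sqrt(1+h) for a new observation, with n − p − 1 degrees of freedom;
the prediction band is strictly wider pointwise whenever s > 0. A
perfectly interpolating fit (RSS at rounding-noise level, detected at
s ≤ 1e−12 relative to the response scale) returns zero-width bands with a
warning flag rather than raising.

## Descriptor selection

Stage one enumerates every subset of size ≤ 2 exhaustively (guarded at
10⁶ subsets); stage two is a genetic algorithm over binary inclusion
masks for subsets up to `max_subset_size` (default 4, the largest model
size the package is designed around). The selection fitness defaults to
Q²_LOO, with R² as an option; within a search, infeasible subsets
(rank-deficient or df-violating) score −∞ instead of raising. Ranking is
deterministic: fitness descending, then smaller subsets, then
lexicographic names.

GA internals are not dictated by any single convention, so they are fixed
here as: tournament selection of size 2, uniform crossover at rate 0.9
per pair, elitism of 1, initial population of random masks with 2..cap
active bits, and mutation applied *per individual* — with probability 0.6
an individual undergoes one random bit flip. The customary GA-MLR setting
quotes a mutation rate of 0.6 alongside population 800 and 3000
generations (the package defaults); read per-bit, 0.6 would randomise
most of the chromosome each generation and destroy convergence, so the
per-individual reading is adopted deliberately. Chromosomes breaching the
size cap are repaired by randomly dropping bits. Fitness values are
cached per subset, and the search stops early after 200 generations
without improvement (configurable), which makes the default configuration
cheap on enumerable pools. Runs are bit-reproducible given the seed. On
every pool where enumeration is feasible, the tests assert the GA attains
the exhaustive optimum. No collinearity pre-filter is applied by default;
rank-deficient candidates are simply infeasible.

On the bundled pool, the search recovers the published models: {IW1,
FLEX} is the best pair for the RAF1 response and {ACDODO, IW2, DD8, PSA}
the best subset of size ≤ 4 for the V600E response. Whether those subsets
are optimal within the original software's full ~128-descriptor pool is
unknowable from the six printed descriptors, so the tests assert
agreement with the enumeration oracle, not recovery of any particular
subset on general pools.

## Synthetic data generator

The generator emulates the structure the analysis assumes: n of order
9–22 compounds; p correlated descriptors drawn from an equicorrelated
Gaussian latent (one-factor construction z = sqrt(ρ)·g + sqrt(1−ρ)·e),
each column affinely mapped so its ±2 sd interval spans a realistic
descriptor range (vector moments of order 0.01–0.05, flexibility 2.7–5,
surface areas 99–140, triplet counts 6–29, volume differences 0–3,
cycled for p > 6); and a response that is linear in a small active subset
plus Gaussian noise. Planted coefficients live on the standardised latent
scale so every active descriptor contributes comparably regardless of its
printed range; `true_coefficients` converts them to raw-scale slopes for
recovery assertions. The noise stream is seeded independently of the
descriptor draw so one pool can carry several noise realisations.
`noise_sd_for_r2` inverts R² = β'Cβ/(β'Cβ + σ²) to target a true model
R²; the default validation regime uses n = 22, true R² ≈ 0.9, matching
the bundled study's scale. An equicorrelated pool was chosen over copying
the empirical correlation matrix of the bundled table: it is simpler,
parameterised by a single ρ, and sufficient to stress selection; the real
table remains available as a real-structure fixture.

What the synthetic data do not emulate: non-Gaussian descriptor
marginals, heteroscedastic assay noise, outlier compounds, and the
block-correlation structure of real descriptor software. Passing the
synthetic suite therefore demonstrates correctness of the estimators and
power of the selection machinery under the stated model, not robustness
to real-data pathologies.

## Validation problem sizes

The property suite checks LOO shortcut/refit equivalence on 100
randomised datasets (n between 8 and 30, p up to 5), GA-vs-enumeration
agreement on 20 seeded pools with p between 6 and 12 (GA at population
120, 400 generations, patience 60 — ample for pools of ≤ 800 candidate
subsets), and the recovery regime of 20 replicates at n = 22, p = 20,
4 active descriptors. At those sizes the whole suite runs in well under a
minute; the full bundled-data pipeline itself is deterministic (no RNG
anywhere) and completes in about a second, so reruns are byte-identical.

## Known limitations

- Single-response fitting only; no PLS/latent-variable models, no
  regularisation, no applicability-domain analysis.
- Q² and the selection fitness assume exchangeable compounds; no
  scaffold-aware or leave-class-out validation.
- The 3-decimal precision of the bundled descriptor table propagates into
  refitted coefficients; third-decimal differences from statistics quoted
  to more precision elsewhere are expected and absorbed by the declared
  tolerances.
- The GA mutation-rate semantics (per-individual, see above) is a design
  decision; software quoting a per-bit rate will not be numerically
  comparable generation-by-generation, though both reach the same optima
  on enumerable pools.
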
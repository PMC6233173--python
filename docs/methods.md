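# Methods

## Model

`spectralsar` fits a linear latent-variable regression between spectral
features of protein sequences and a scalar activity.

**Encoding.** A sequence of length N over the 20 canonical amino acids
is mapped to a numeric signal s(0..N−1) through an encoding index (one
real value per residue, AAindex1 format). Sequence position 1
corresponds to signal index 0. The protein spectrum is the squared
magnitude of the discrete Fourier transform of that signal, restricted
to the non-redundant half-spectrum k = 0..⌊M/2⌋ (the input is real, so
the upper half is the mirror image). The DC bin (k = 0) is kept: it
carries amino-acid-composition information, its energy being the squared
sum of the signal.

Two definitions of "energy" are plausible — |S(k)|² or |S(k)| — and both
are exposed (`energy="squared"` is the default, as energy conventionally
means squared magnitude). Both are nonlinear in the signal, which is the
property that matters: spectrum features of a multi-point variant are
not the sum of the single-variant features, so a linear model on spectra
can represent pairwise interactions between mutations. Conversely, the
`no_fft` mode uses the raw encoded signal as the feature vector, which
is exactly linear in substitutions; any model that interpolates the wild
type and the single mutants in this mode makes exactly additive
predictions for every combination (see "Additivity" below).

Zero-padding before the transform is off by default: the method is
defined for substitution-only variant sets, whose equal lengths already
give comparable frequency bins. `pad_to` (e.g. the next power of two) is
available for users who want a denser frequency grid.

No detrending or signal-level standardization is applied before the
transform; centering happens inside the regression.

**Regression.** Single-response PLS via NIPALS on column-centred
features and centred response. For one response the weight vector per
component is Xᵀy normalised — no inner iteration — followed by score
projection and rank-one deflation, so the fit is deterministic.
Unit-variance feature scaling is available behind a flag but off by
default: centring-only is the minimal standard choice and keeps the
additivity property exact. If the response is fully deflated before the
requested component count (exact fit at lower rank), extraction stops
early and the model records the count actually used. At full components
the fitted values coincide with the minimum-norm least-squares solution;
the test suite asserts this against a pseudo-inverse oracle and against
an independent NIPALS implementation (scikit-learn).

**Validation.** Leave-one-out cross-validation by default: each variant
is predicted by a model trained on all others, and the pooled held-out
predictions are scored. k-fold with a seeded shuffle is available for
larger datasets. Two R² variants are reported because they genuinely
differ: the squared Pearson correlation (the headline metric) is
invariant under affine maps of the predictions and scores 1 even for
perfectly *anti*-correlated predictions, while 1 − SSE/SST penalises any
departure from the identity line. Both appear in `summary()` and the run
logs. RMSE uses divisor n (no degrees-of-freedom correction). The
component count is chosen to minimise LOOCV RMSE (overfitting control is
the stated purpose of the cross-validation stage), ties broken toward
fewer components; the cap defaults to min(n − 1, n_features, 10) since
typical training sets here hold 10–40 variants. When a full-component
model is requested explicitly, cross-validation runs at the largest
count feasible in every fold (fold training sets are one sample smaller)
while the final full-set fit uses the requested count.

**Index screening.** Each usable encoding index (complete, non-constant)
gets its own model; indices are ranked by LOOCV R² (ties: lower LOOCV
RMSE, then input order). Indices whose feature matrix is constant across
the variants — e.g. an index assigning equal values to the only residues
that distinguish them — are skipped with a logged warning.

## Landscape analysis

**Additive baseline.** The theoretical activity of a combination is the
wild-type value plus the sum of wild-type-relative single-mutation
effects: ΔΔG‡_add(g) = ΔΔG‡_WT + Σ_{m∈g}(ΔΔG‡_m − ΔΔG‡_WT). This is the
only formulation under which a single-mutant genotype reproduces its own
measured value, which fixes the ambiguity in "adding the values of the
single mutations".

**Epistasis.** On the ΔΔG‡ scale lower means more selective, so an
observed value below the additive baseline (beyond a tolerance, default
0) is positive epistasis and above it negative. In model-vs-additive
comparisons a genotype is credited to the model (flag I) only when its
absolute error is strictly smaller than the additive baseline's; ties go
to the simpler additive model (flag A).

**Enumeration and ranking.** The 2ⁿ recombinants of n position-distinct
single mutations are generated in binary-counter order (wild type first,
full combination last), with a configurable cap at n = 30. Rankings sort
by predicted enantioselectivity (E descending ⇔ ΔΔG‡ ascending), stable
under ties, and flag training-set members.

**Units.** E-values convert to differential activation free energies by
ΔΔG‡ = −RT ln E with R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and T = 298.15 K by
default (room-temperature kinetics); T is configurable, and conversions
are reported alongside the training-unit predictions rather than used in
the fit.

## Synthetic landscapes

The generator emulates a directed-evolution study: a random wild type,
n distinct point mutations, and activities

a(g) = β₀ + Σ_{m∈g} β_m + Σ_{{m₁,m₂}⊆g} γ_{m₁m₂} + ε,  ε ~ N(0, σ²),

on a ΔΔG‡-like scale (lower = better). Defaults are sized after an
enantioselective-hydrolase campaign: 9 mutations on a 60-residue wild
type, baseline β₀ = −0.9 kcal/mol (an E-value near 4.6 at 298 K),
improving single-mutation effects β ~ U(−1, 0) kcal/mol, pairwise
epistasis γ ~ U(−0.5, 0.5) on 25 % of the mutation pairs, and
measurement noise σ = 0.1 kcal/mol. Pairwise terms are the smallest
structure that defeats an additive predictor, so they are the default
family; a hook accepts an arbitrary genotype→activity callable for
higher-order landscapes. All randomness flows from the single config
seed through one generator.

Two numerical choices make strict (tol = 0) epistasis classification
meaningful on noiseless synthetic data: coefficients are snapped to a
dyadic grid (multiples of 2⁻²⁰ ≈ 10⁻⁶ kcal/mol) so sums of effects incur
no floating-point rounding and additive identities hold machine-exactly;
and variant CSVs are read with round-trip float parsing so the identities
survive the I/O path.

What the generator does **not** emulate: real biophysics. Effects are
position-independent draws, epistasis is pairwise and sparse by
construction, noise is homoscedastic Gaussian, and sequences are random
rather than structured. Passing tests therefore demonstrate the
machinery — exact additivity of the linear ablation, recovery of
constructed epistasis, the spectral model's advantage on pairwise
interactions — not predictive accuracy on any particular real enzyme.

## Problem sizes and determinism

The test and acceptance runs use exhaustive landscapes of 2⁶–2⁹
genotypes and seed ensembles of 10–20 landscapes, enough to make the
statistical assertions (FFT-vs-no-FFT medians, noise monotonicity)
stable while the whole suite completes in seconds. LOOCV is
deterministic; k-fold shuffling, landscape generation and fixture
indices are seeded, and model serialization is canonical (sorted keys,
no timestamps), so repeated runs are byte-identical.

## Known limitations

- The squared-Pearson R² rewards anti-correlated predictions; the
  residual-based variant is always reported alongside it for diagnosis.
- Single-response PLS only; no multi-task models, no kernel/nonlinear
  regression, and no uncertainty quantification — predictions are point
  estimates.
- Substitution-only variant sets: insertions and deletions change the
  sequence length and are rejected at encoding time.
- Non-canonical residues (B, Z, X, U, O) have no index values and are
  encoding errors rather than silently imputed.
- The FFT model's epistasis capture is representational, not causal: it
  can express interaction terms that a linear-in-mutations model cannot,
  but whether it learns the right ones depends entirely on the training
  coverage of the mutation combinations.
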
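# Methods

## Clinical scoring

**MASI.** The face is divided into forehead (F), right malar (MR), left
malar (ML) and chin (C). Each region contributes an area grade A ∈ 0–6 and
darkness/homogeneity grades D, H ∈ 0–4, combined as

    MASI = 0.3·A_F(D_F+H_F) + 0.3·A_MR(D_MR+H_MR)
         + 0.3·A_ML(D_ML+H_ML) + 0.1·A_C(D_C+H_C),

which spans [0, 48]. Component ranges follow the international MASI
convention. Treatment response is the decline rate (V_b − V_a)/V_b, where
V_b and V_a are the MASI scores before and after treatment. Dividing by
the baseline bounds the rate above by 1 and makes the published grade
bands attainable; an alternative denominator (post-treatment score) is
available via the `denominator` switch but is not used anywhere. The
four outcome grades are half-open bands on the rate — below 10% invalid,
[10%, 50%) get better, [50%, 90%) effective, ≥ 90% basically healed — so
every finite rate maps to exactly one grade (published integer bands leave
the 49–50 and 89–90 gaps ambiguous; half-open intervals resolve them).

**RCM grading.** Five parameters are graded 1–4: epidermal pigmentation by
quartile bands of the pigmented-field fraction (half-open above each lower
edge), dendritic cells by count bands 0 / 1–5 / 6–15 / >15, melanophages
by 0 / 1–5 / 6–10 / >10, and solar elastosis and vascularity on a
normal/mild/moderate/serious scale. These five ordinals are the network's
feature vector.

**Target encoding.** For network training each grade maps to the midpoint
of its decline-rate band: 0.05, 0.30, 0.70, 0.95. The encoding is strictly
monotone and round-trips through the classifier; the synthetic cohorts use
a continuous target directly, so the encoding matters only when real
graded outcomes are supplied.

## The BP network

A three-layer perceptron with unipolar sigmoid activations throughout.
Biases are fixed-unit inputs (x₀ = y₀ = 1), so the trainable parameters
are V ∈ R^{(m+1)×H} and W ∈ R^{(H+1)×l}; for the default 5-input,
1-output network with sizing constant a = 4 the width is
H = m + n + a = 10 and the parameter count is 71.

The global error is the **mean** over samples of ½ Σ_k (b_k − O_k)².
Averaging (rather than summing) keeps the error goal meaningful across
cohort sizes; the 0.001 goal then corresponds to a root-mean-square output
error of about 0.045. Updates are plain full-batch gradient descent with
learning rate μ = 0.2 and no momentum or regularization; an online
(per-sample) mode exists mainly for the convergence tests, where
stochastic updates escape the slow full-batch transient on tiny datasets.
Weights initialize uniformly in [−0.5, 0.5] from a seeded generator.
Training stops at the error goal or at `max_epochs` (default 1000);
a non-finite error raises a divergence error carrying the epoch index.

The sigmoid is computed branch-stably (separate forms for positive and
negative arguments) so |x| up to the overflow limit is safe. Analytic
gradients are audited against central finite differences (step 1e-5) in
the test suite and the acceptance script; agreement is ~1e-9 relative.

## The GA initializer

Individuals are full weight sets flattened V-then-W (row-major); the
genome length is (m+1)H + (H+1)l, determined by the architecture. Fitness
is f = 1/(E + ε) with ε = 1e-12 guarding the perfect-fit case. Each
generation: score everyone on the training set, copy the best individual
unchanged (elitism count 1), then fill the population by roulette-wheel
selection, whole-arithmetic crossover (probability P_c = 0.3; children
are complementary convex mixes of the parents) and sparse Gaussian
mutation (per-gene probability P_m = 0.01, σ = 0.1). The defaults are
20 individuals and 40 generations. Operator forms are this package's
choice — the scheme only fixes real coding — and were chosen as the
standard real-coded operators. An adaptive-rate mode sets
P_c = c·(f_max − f_mean) and P_m = d·(f_max − f_mean) (defaults c = 0.5,
d = 0.05), clamped into [0.01, 0.99] so a converged population keeps a
floor of variation; fixed rates are the default.

GA individuals are scored by the network's forward error only — no BP
refinement inside the GA — so the search is purely over initializations;
`ga_bp_train` then decodes the best genome ever seen and runs ordinary BP
from it. The elitist best fitness is non-decreasing by construction,
checked on every run.

## Synthetic cohorts

Each patient has five ordinal scores drawn uniformly over {1..4} through a
Gaussian copula that correlates epidermal pigmentation with melanophage
burden (ρ = 0.4, the two pigment-load markers; other pairs independent).
The ground-truth treatment effect is linear and decreasing in the scores,

    g(s) = clip(1 − Σ_k w_k (s_k − 1)/3, 0, 1),  w_k = 0.2,

so an all-1 (normal) profile yields 1.0 and an all-4 (severe) profile 0.0;
an optional interaction term between the dendritic and melanophage scores
adds curvature when a nonlinear target is wanted. The observed target adds
N(0, σ) noise (default σ = 0.05) and clips back to [0, 1]. Defaults are
240 patients, split at random into 200 training and 40 test samples, all
seeded.

What the generator does **not** emulate: measurement disagreement between
RCM readers, cohort-level class imbalance, longitudinal structure
(repeated visits), or any real joint distribution of the five parameters —
the copula correlation is an assumption, exposed in `CohortSpec`. Passing
tests therefore demonstrate that the estimator machinery is correct and
that GA initialization helps *under this generative model*, not that the
clinical effect sizes transfer to real patients.

## Experiment design

The comparison is paired: within a repeat, BP and GA-BP share the cohort,
the split and the fitted normalizer, and differ only in initialization.
Per-repeat seeds derive deterministically from the experiment seed (kept
below 2³¹). Headline outputs are per-repeat test MAEs, their means and
variances, and the GA-BP win fraction; the runner also writes the
per-sample evaluation tables, the BP training-error trajectory and the GA
fitness trace as CSV. Default: 20 repeats, ~1 s each on one CPU.

Parameter-recovery runs ask a different question — how much of the
generator's map the model can recover — so they train deeper than the
routine protocol: error goal 1e-4 with a 30 000-epoch cap (full-batch
descent at μ = 0.2 is slow near convergence; the routine 1000-epoch budget
measures the comparison, not the model's capacity). Under this budget
GA-BP reaches test MAE ≈ 0.01 on noiseless cohorts and ≈ 0.04 at σ = 0.05,
against the noise-imposed floor of σ·√(2/π) ≈ 0.04.

## Numerical and degenerate-input choices

- Min–max normalization round-trips to 1e-12; constant features map to
  0.5 and are flagged rather than rejected.
- Selection probabilities require strictly positive fitness and sum to 1
  within 1e-12; they are scale-invariant.
- Cohort CSVs store targets with 17 significant digits and are read back
  with round-trip float parsing, so write/read is lossless.
- Ties in the paired comparison count as GA-BP wins (≤), consistent with
  "at least as good"; with continuous errors ties have probability ~0.
- Zero GA generations degrade gracefully to the best-of-initial-pool
  initialization, making plain BP a strict special case.

## Known limitations

- A single scalar sigmoid output regresses the continuous effect; grades
  come from thresholding it. Multi-output one-hot classification is out of
  scope.
- Full-batch descent at fixed μ converges slowly near the optimum; no
  momentum or adaptive step is provided by design.
- The GA searches connection weights only, not topology or learning
  rules.
- All empirical claims in this note are the quantities the test suite and
  `scripts/acceptance.py` themselves compute on synthetic cohorts.
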
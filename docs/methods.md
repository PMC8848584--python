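# Methods

## The problem

Neurons transmit information through the timing of their action potentials.
Four canonical discharge rhythms recur in single-unit recordings and in
conductance-based model simulations: periodic discharge (PD), random
discharge alternating between two periodic cluster patterns (RD), chaotic
discharge (CD), and integer-multiple discharge (IMD), in which interspike
intervals (ISIs) cluster at integer multiples of a base period.  Classifying
an unlabeled ISI sequence into one of these rhythms traditionally requires a
battery of hand-picked statistics and expert judgment.  `spikerhythm`
implements an automatic alternative: a stacked sparse auto-encoder (SAE)
learns a compact code from the raw normalized ISI vector, two classical
time-series statistics are fused with that code, and a softmax head assigns
the class.

## Mechanistic simulators

The Chay model describes an excitable cell with three state variables —
membrane potential `V` (mV), potassium activation `n`, and dimensionless
intracellular calcium `C`:

    dV/dt = g_I·m∞³h∞·(V_I − V) + g_KV·n⁴·(V_K − V)
          + g_KC·C/(1+C)·(V_K − V) + g_L·(V_L − V)
    dn/dt = w_K·(n∞ − n)/τ_n
    dC/dt = ρ·(m∞³h∞·(V_C − V) − K_C·C)

The gating steady states m∞, h∞, n∞ and the relaxation time τ_n use the
classical Hodgkin–Huxley rate functions with the canonical voltage shifts of
this model family; the shipped defaults are the canonical set (g_I = 1800,
g_KV = 1700, g_L = 7, V_I = V_C = 100 mV, V_K = −75 mV, V_L = −40 mV,
K_C = 3.3/18, ρ = 0.27, λ_n = 230), with the calcium-gated potassium
conductance g_KC as the main rhythm dial and `w_K = 1` recovering the
original model.  `w_K ≠ 1` rescales the potassium gating speed — the
"improved" variant motivated by the near-instantaneous opening of K⁺
channels at the spike peak — and produces irregular rhythm alternation with
no noise source at all.

Stochastic variants add, by Euler–Maruyama with √dt scaling:

* **global white noise** ξ(t) with ⟨ξ(t)ξ(t′)⟩ = 2D·δ(t−t′) on dV/dt;
* **global colored noise**: a stationary Ornstein–Uhlenbeck process with
  correlation time τ and stationary variance D/τ, integrated by its exact
  discretization σ_{k+1} = e^{−dt/τ}σ_k + √((D/τ)(1−e^{−2dt/τ}))·z_k so the
  stationary-variance test is sharp rather than O(dt)-biased;
* **channel noise** η_n = ξ_n(t)·(1/√N_K)·√(2n(1−n)/τ_n(V)) on dn/dt,
  the diffusion approximation of a finite population of N_K potassium
  channels (variance ∝ 1/N_K), with white or colored ξ_n.

Numerical choices: fixed-step integration at dt = 0.001 model-time units
(RK4 available for deterministic runs; Euler–Maruyama for stochastic ones);
`n` is clamped to [0, 1] and `C` floored at 0 after every step because noise
can push a probability out of range; a |V| ≤ 500 mV guard converts blow-ups
into errors carrying the failure time.  With D = 0 every stochastic variant
reproduces the deterministic Euler trajectory bitwise, which the tests
assert.  Time is treated as dimensionless model time throughout.

### Rhythm regimes

`configs/chay_regimes.json` maps classes to regimes, found by scanning the
model (all are overridable):

| class | mechanism | key settings | behaviour |
|---|---|---|---|
| PD | deterministic | g_KC = 10.0 | tonic spiking, ISI CV ≈ 4·10⁻⁴ |
| RD | improved deterministic | g_KC = 11.5, w_K = 1.1 | irregular alternation of burst clusters |
| CD | deterministic | g_KC = 11.12 | chaotic bursting (continuum of ISIs) |
| IMD | K⁺ channel noise | g_KC = 27.6, N_K = 3000, D = 1 | spike skipping near the firing boundary; ISIs near multiples of the slow-wave period |

The IMD regime sits just past the boundary (g_KC ≈ 27.9) where tonic firing
ceases; weak channel noise then triggers spikes on some cycles of the
underlying slow wave and skips others.  The multiple structure is broader
than the textbook picture of subthreshold-oscillation-driven integer-multiple
firing; it is the qualitatively correct mechanism available in this model
family without adding external pacing.

## From trace to classifier input

Spikes are upward threshold crossings followed by the next local maximum,
with crossings inside a refractory window suppressed (defaults: 0 mV and 2
time units for generic traces; the Chay regimes configure −30 mV and 0.05
because their spikes peak near −19 mV and intra-burst ISIs reach 0.1).  ISIs
are consecutive spike-time differences.  Preprocessing truncates each
sequence to its first 1024 intervals and min–max scales it to [0, 1] per
sequence (a constant sequence maps to zeros by a guarded division; z-score
is available as an alternative).  Truncate-then-normalize order is fixed;
min–max matches the sigmoid auto-encoder's input range.

## The synthetic dataset

The default experiment uses 60 sequences per class (40 train / 20 test) of
length 1024.  Generating that mechanistically needs > 10⁹ integrator steps,
so dataset-scale work uses **archetype mode**: statistical surrogates with
the phenomenology of each rhythm, decoupling classifier verification from
dynamical-systems tuning.  Defaults (all in `ARCHETYPE_DEFAULTS`):

* **PD** — base period 1.0 modulated by a slow sinusoid (period ≈ 128 ISIs,
  random phase, per-sequence period jitter) plus 2% white jitter; total
  CV ≈ 0.01.  The modulation is deliberately smooth: regular firing drifts
  slowly in rate, and a purely white jitter would score as high-complexity
  under approximate entropy, which is blind to scale.
* **RD** — stochastic alternation (p = 0.5) between two periodic cluster
  motifs: 3 spikes at intra-burst ISI 0.3 then a 2.0 gap, or 7 spikes then a
  1.2 gap, each with 2% jitter.
* **CD** — logistic-map iterates (r = 3.9, random initial condition, 100-step
  burn-in) rescaled to ISIs in [0.3, 1.7].
* **IMD** — base period times an integer k ≥ 1 with geometric weights
  (p = 0.55, k ≤ 6) and 2% jitter, so every raw ISI rounds back to its
  multiple.

These surrogates reproduce the feature structure that makes the real
problem interesting: RD and CD have nearly identical approximate entropy
(≈ 0.49 both) — the confusable pair — while the coefficient of variation
separates them (≈ 2.2 vs ≈ 0.6), and PD scores lowest in ApEn (≈ 0.17).
What passing tests on archetype data do **not** show is performance on
mechanistic Chay ISI sequences at full scale, whose within-class variability
(shared attractor geometry across sequences) is narrower than the
surrogates'; the surrogate classes are, in practice, more cleanly separable
than the published experiment's simulated data (see Limitations).

## Features

* **Dispersion** — default: coefficient of variation SD/mean of the
  sequence, the standard ISI dispersion statistic; lag-1 autocovariance is
  available as an alternative reading of "covariance" for a univariate
  series.  Both are implemented because the term is ambiguous for a single
  sequence.
* **Approximate entropy** — Pincus ApEn(m, r) with Chebyshev distance,
  self-matches included, natural log; defaults m = 2, r = 0.2·SD (the
  dominant convention of the ApEn literature; the original experiment's
  m and r are unreported).  r relative to SD makes ApEn invariant to the
  affine min–max normalization, so computing it on the normalized vector
  (the default, for pipeline coherence) equals computing it on raw ISIs.
* **Fusion** — the two scalars are min–max scaled using training-set
  statistics only and concatenated to the 824-wide code: widths
  824/825/825/826 across the four ablation configurations.

## The classifier

Two sigmoid auto-encoder layers, 1024 → 1224 → 1024 and 1224 → 824 → 1224,
are pretrained greedily full-batch on

    J = (1/m)Σ ½‖x − x̂‖² + λ·½‖W‖² + β·Σ_j KL(ρ̂ ‖ ρ̄_j)

with λ = 0.01, β = 0.1 and sparsity target ρ̂ = 0.05 (ρ̂ is unreported in
the source experiment; 0.05 is the classic toolbox default, configurable).
The KL penalty against the batch-mean activation ρ̄_j is the standard sparse
restriction consistent with a "sparsity regularization" weight.  The
optimizer is Møller's scaled conjugate gradient ("trainscg"), full batch —
160 rows is tiny, so mini-batching would only add variance; bold-driver
gradient descent is provided as the alternative.  Both only accept
cost-reducing steps, so recorded trajectories are non-increasing.

Fine-tuning attaches a softmax head (with intercept) to the fused feature
vector and minimizes the multinomial cross-entropy for `sup_epochs`
iterations.  Default scope is head + second-layer encoder ("top"); a
head-only mode freezes the stack bitwise.  A small L2 on the head
(10⁻⁴) keeps the separable-case parameters finite; at θ = 0 the cost is
exactly ln 4.  Weight initialization is symmetric uniform with
±√(6/(fan_in + fan_out)) bounds, from a single seeded generator per fit, so
identical seeds give bitwise-identical models.

Budgets: the published setting trains 1000 unsupervised and 1000 supervised
epochs.  The test suite and the reproduction script run 100/150 as their
problem size — the cost curves are deep into their flat tail there, and the
ablation conclusions are unchanged across seeds.

## Evaluation

Confusion matrices use rows = true class, columns = predicted (the
convention of the published tables); overall accuracy is 100·trace/total.
`run_ablation` pretrains once per seed and fine-tunes the four fusion
configurations — code-only, +dispersion, +ApEn, +both — reporting
per-configuration matrices, accuracies and their dispersion across seeds,
plus KNN (k = 5, Euclidean) and RBF-SVM (C = 1) baselines on the raw
normalized vectors.  Baseline hyper-parameters are unreported in the source
experiment; these defaults are exposed as options.

## Known limitations

* The mapping from model variants to rhythm classes is an implementation
  choice (the source experiment does not state which variant produced which
  class, nor its per-class parameter values); all regime parameters live in
  an overridable config file.
* Archetype surrogates are *more* separable than mechanistically simulated
  ISI data: the fused pipeline reaches high-90s accuracy where the published
  experiment reports 87.5% on its own (unavailable) simulated dataset, and
  the baselines score correspondingly higher.  The ablation *direction*
  (fused ≥ code-only) is the transferable conclusion.
* Full-scale chay-mode dataset generation is supported but computationally
  heavy; it is exercised at small scale in the tests.
* ApEn is O(n²) in sequence length — acceptable at n = 1024, not intended
  for much longer sequences.
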
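# Methods

## The inference problem

A trajectory is a 1-D position series x_0, …, x_{T−1} sampled at unit time
steps from one of five anomalous-diffusion processes, each with ensemble
mean squared displacement ⟨x²(t)⟩ ≃ 2K_α t^α. Two tasks are supported:
regressing the anomalous exponent α ∈ (0, 2] and classifying the generating
model among ATTM, CTRW, FBM, LW, SBM (this canonical alphabetical order is
used for every probability vector and confusion matrix). Both tasks return
calibrated uncertainties: a predictive standard deviation (aleatoric +
epistemic) for regression, class probabilities for classification.

## Simulators

All processes start at the origin, are sampled at integer times, and treat
events between samples exactly (no Euler discretisation):

* **CTRW** (0 < α ≤ 1): waiting times are Pareto, τ = τ_min·u^(−1/α) with
  u ~ U(0,1) and τ_min = 1; jump displacements are N(0, 2K_α). Positions
  are piecewise constant between jumps.
* **FBM** (0 < α < 2): increments are exact discrete fractional Gaussian
  noise with autocovariance c(k) = K_α((k+1)^α − 2k^α + |k−1|^α), generated
  by Davies–Harte circulant embedding with a Cholesky factorisation of the
  Toeplitz covariance as fallback when the embedding is not nonnegative
  definite. α = 2 is excluded (degenerate straight line).
* **LW** (1 < α ≤ 2): constant-speed flights (v = 1) with Pareto durations
  of tail exponent σ = 3 − α; at α = 2 the entire ballistic band is covered
  by drawing σ ~ U(0, 1) per trajectory. Direction ±1 is redrawn each
  flight; positions are linear inside flights, so integer-time sampling is
  exact interpolation.
* **SBM** (0 < α ≤ 2): the increment over [t, t+1] is Gaussian with
  variance 2K_α((t+1)^α − t^α), the exact integral of 2K(t) = 2αK_α t^(α−1).
* **ATTM** (0 < α ≤ 1): per trajectory γ ~ U(1, min(3, 1/(1−α))) (γ = 1 at
  α = 1), σ = αγ, enforcing the σ < γ < σ + 1 regime; epochs draw
  D = D_max·u^(1/σ) (inverse CDF of P(D) ∝ D^(σ−1) on (0, 1]) and last
  τ = D^(−γ). Positions follow a time-changed Brownian motion: increments
  are Gaussian with variance equal to the integrated diffusivity
  2∫D(s)ds over the sampling interval, exact across epoch boundaries.

Waiting/flight times are capped just beyond the observation window; beyond
it they are statistically indistinguishable, and the cap prevents float
overflow of u^(−1/exponent) at very small tail exponents.

**Noise.** The noisy trajectory is x̃(t) = x(t) + ξ(t) with ξ i.i.d.
N(0, (σ_Δx/snr)²), where σ_Δx is the population standard deviation of this
trajectory's clean increments and snr ∈ {1, 2, 10}. A constant (jump-free)
trajectory gets no noise and a warning. When shorter trajectories are cut
from longer ones, noise is added after truncation — the snr refers to the
increment statistics at the final length, which matters for processes with
time-varying diffusivity such as SBM.

**Priors / dataset assembly.** Exponents live on the grid
{0.05, 0.10, …, 1.95, 2}. Admissibility: CTRW and ATTM are sub- or
normal-diffusive (α ≤ 1), LW superdiffusive (α > 1), FBM excludes α = 2,
SBM covers everything. Regression datasets stratify exponent counts exactly
over the grid with the model uniform over those admissible at each
exponent (so FBM/SBM are overrepresented); classification datasets stratify
model counts exactly with the exponent uniform over the model's admissible
grid (so subdiffusion is overrepresented). A `models` restriction in the
prior supports single-model studies. Every trajectory gets an independent
seed-sequence substream of the master seed, so datasets are bit-reproducible.

### What the generator does and does not emulate

It reproduces the labelled-trajectory study conditions: the five processes,
the exponent grid and admissibility rules, the snr set and the
noise-after-truncation rule. It does not emulate experimental artefacts —
drift, blur/motion averaging, missing frames, non-Gaussian localisation
errors, model switching within a trajectory, or 2-D/3-D motion. Passing
tests therefore demonstrate correctness of the method on data drawn from
the stated generative family, not robustness to real microscopy data.

### Validating the MSD scaling

The scaling validator fits the log-log slope of the ensemble MSD of 10⁴
clean trajectories. FBM and SBM satisfy ⟨x²(t)⟩ = 2K_α t^α exactly, so the
unit grid to T = 100 suffices. The renewal-type processes converge to their
power law slowly when the minimum waiting time equals the sampling step:
the CTRW/ATTM MSD is measured on a log-spaced grid out to t = 10⁵ and
fitted over the last two decades, and LW uses T = 1000. At the marginal
renewal point α = 1 the CTRW/ATTM MSD carries an intrinsic logarithmic
correction (⟨x²⟩ ∼ t/ln t), so fitted slopes approach 1 only as 1 − 1/ln t;
at these horizons they measure ≈ 0.89. These horizons are statements about
where the asymptotic exponent is measurable, not about the training data,
which uses the short lengths of the study (T = 10–500).

## Network

Inputs are the normalised increment series: Δx_t = x_{t+1} − x_t divided by
max(std(Δx), 10⁻¹⁰), per trajectory, population convention, mean not
subtracted. The network stacks LSTM layers (default sizes 128, 128, 64;
scaled-down studies use smaller stacks via the same config field) and feeds
the final hidden state to the head. The regression head is a direct linear
map to (μ, log σ²), with the log-variance clamped to [−10, 10] before
exponentiation — the Gaussian NLL degenerates as σ → 0 and the
parameterisation must keep σ > 0; μ is not clipped to (0, 2]. The
classification head inserts a fully connected ReLU layer of width 20 before
the 5-way softmax (computed with max subtraction). Losses are the
heteroscedastic Gaussian negative log-likelihood ½(log σ² + (μ−ŷ)²/σ²)
(additive constant dropped) and the cross entropy −log p_true with
probabilities clamped at 10⁻¹² before the log; both are reduced by the
batch mean so learning rates keep their meaning across batch sizes.
Everything runs on float64 numpy arrays with hand-written backpropagation
through time, verified against central finite differences to 10⁻⁵ relative.

## SWAG weight posterior

After Adam pretraining, the model trains further with plain constant-rate
SGD, and every c-th iterate (default: once per epoch) is folded into
running moments following the collection rule n = i/c:

    θ̄ ← (nθ̄ + θ_i)/(n+1),  θ²bar ← (nθ²bar + θ_i²)/(n+1),

initialised at the pretrained weights. The deviation matrix D̂ keeps the
last K columns θ_i − θ̄_i, centred on the *running* mean at collection time
(the running-mean and final-mean formulations differ; the collection
algorithm is taken as normative). Sampling draws

    θ̃ = θ̄ + √(½Σ_diag)⊙z₁ + D̂z₂/√(2(K_used−1)),

with Σ_diag = θ²bar − θ̄² clamped elementwise at zero (running moments can
go marginally negative in floating point) and K_used the current column
count (≥ 2 required). Multi-SWAG trains several SWAG models from
independent seeds, ranks them by the validation loss of their SWA mean
weights, keeps the best n_keep, and averages M Monte-Carlo predictive
distributions split equally across members: probability vectors are
averaged directly; regression collapses the Gaussian mixture to its
moments, μ* = mean(μ_m) and σ*² = mean(σ_m²) + mean(μ_m²) − μ*².

## Training protocol and defaults

| parameter | default | notes |
|---|---|---|
| epochs_total | 75 | full-scale protocol; scaled-down studies use ~13 |
| epochs_swag | 12 | trailing constant-rate SGD epochs |
| lr_pretrain | 1e−3 | Adam |
| swag.eta | 1e−4 | constant SGD rate in the SWAG phase |
| weight_decay | 1e−5 | L2, added to the gradient |
| batch_size | 128 | |
| n_models / n_keep | 20 / 5 | Multi-SWAG ensemble size / kept members |
| samples_per_model | 10 | so M = n_keep × 10 Monte-Carlo samples |
| swag.K_cols | 20 | deviation-matrix columns (FIFO) |

The optimiser split is deliberate: pretraining uses Adam, while the SWAG
phase uses plain SGD, whose iterates around a minimum are what the Gaussian
posterior construction models. Learning-rate and batch defaults are
pragmatic CPU-scale choices exposed in the config; one network is trained
per trajectory length.

### Scaled-down study sizes

The full-scale protocol (10⁶ trajectories, 20-member ensembles, lengths to
500) is a GPU-scale undertaking. The package's own end-to-end checks use a
scaled-down configuration chosen once: 3×10³ FBM-only trajectories of
length 50, an LSTM stack (32, 32), 13 total epochs with 4 SWAG epochs,
3 ensemble members keeping 2, and 10 weight samples per kept member. Under
these conditions the ensemble reaches a test MAE of ≈ 0.19 — well below
the 0.5 analytic baseline of predicting the prior mean of a uniform
exponent — with ENCE ≈ 0.03–0.15 depending on the seed. Full-scale
calibration figures are not expected at this scale.

## Calibration metrics

* **Reliability diagram (regression)**: predictions are binned by predicted
  standard deviation in fixed-width bins of 0.02 from zero; each non-empty
  bin reports RMV = √(mean σ²) and RMSE = √(mean (μ−α)²).
* **ENCE** = mean over non-empty bins of |RMV − RMSE|/RMV (bins with
  RMV = 0 excluded); **ECE (regression)** = mean |RMV − RMSE|. Both are
  unweighted over fixed-width bins — whether the original bins were
  count-weighted is not recoverable, so the standard normalised-calibration
  definition is adopted and documented here.
* **ECE (classification)**: for rank k, take each trajectory's k-th most
  probable class and its confidence, bin confidences into 10 equal-width
  bins on [0, 1], and compute Σ_b (n_b/n)|accuracy_b − confidence_b|
  (count-weighted, the standard definition).
* **Confusion matrix**: argmax class (ties broken toward the lower class
  index — a measure-zero event for continuous outputs) against ground
  truth, columns normalised to 1.
* **Mean-confidence table**: the mean predicted probability vector per
  (ground-truth model, ground-truth exponent) cell.

All metrics are validated on calibrated-by-construction synthetic sets
(truths sampled from the predicted distributions), where they must vanish
as n → ∞, and on hand-computed examples.

## Numerical choices and degenerate inputs

* fGn spectra and Cholesky factors are cached per (α, T); the circulant
  eigenvalues are clamped at zero when within 10⁻⁹ relative of it.
* Normalisation floors the increment standard deviation at 10⁻¹⁰; all-zero
  series map to all-zero inputs, never NaN.
* The mixture predictive variance is floored at 10⁻¹⁶ so reported standard
  deviations stay positive.
* Training aborts with a diagnostic on a non-finite loss; the SWAG phase
  requires at least two moment collections.
* Dataset CSV round trips are exact: floats are written with 17 significant
  digits and parsed with round-trip precision.

## Known limitations

* The marginal renewal point α = 1 for CTRW/ATTM has ⟨x²⟩ ∼ t/ln t; no
  finite-horizon slope fit recovers exactly 1.
* Calibration at toy training scale is noisy; ENCE at the scaled-down
  conditions fluctuates by several percentage points across seeds.
* Only 1-D trajectories are generated and consumed.
* The SWA-averaging advantage (mean weights beating the last iterate on
  validation) emerges only once the SGD phase bounces around a converged
  minimum; in under-trained smoke runs the last iterate wins.
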
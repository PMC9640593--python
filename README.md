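# diffuq

Uncertainty-quantified inference of anomalous diffusion from single-particle
trajectories.

Single-particle tracking experiments produce short, noisy position time
series whose mean squared displacement grows as ⟨x²(t)⟩ ≃ 2K_α t^α. Knowing
the anomalous exponent α and the generating stochastic process (the
"diffusion model") is how biophysicists characterise transport in cells,
membranes and crowded fluids — but a point estimate alone is of limited use
when trajectories are 10–500 points long and heavily corrupted by
localisation noise. `diffuq` infers α (regression) or the diffusion model
class (classification) *together with a calibrated uncertainty*: a
predictive standard deviation for α, or a full probability vector over the
five model classes.

## What is inside

* **Simulators** for the five canonical anomalous-diffusion processes used
  by the AnDi-Challenge conventions, all in 1-D at unit sampling:
  - CTRW — Gaussian jumps separated by heavy-tailed waits Ψ(τ) ∝ τ^(−1−α);
  - FBM — exact fractional Gaussian noise increments (Davies–Harte circulant
    embedding, Cholesky fallback), Hurst H = α/2;
  - LW — constant-speed Lévy walks, flight exponent σ = 3 − α;
  - SBM — Brownian motion with diffusivity K(t) = αK_α t^(α−1), integrated
    exactly over each sampling step;
  - ATTM — Brownian epochs of random diffusivity D ∼ D^(σ−1) held for
    τ = D^(−γ), α = σ/γ.
  Trajectories carry ground-truth labels and are corrupted with white
  Gaussian localisation noise of standard deviation σ_Δx/snr,
  snr ∈ {1, 2, 10}.
* **Preprocessing**: increments Δx_t = x_{t+1} − x_t, normalised to unit
  standard deviation per trajectory (the diffusion coefficient is
  deliberately discarded).
* **A recurrent network** (stacked LSTM layers, default sizes 128–128–64)
  with either a heteroscedastic Gaussian head (μ, σ) trained with the
  Gaussian negative log-likelihood ½(log σ² + (μ−α)²/σ²), or a softmax
  classification head trained with cross entropy. Forward pass and
  backpropagation through time are implemented directly on numpy arrays so
  the flat weight vector θ is a first-class object.
* **SWAG / Multi-SWAG**: the weight posterior is approximated by
  N(θ̄, ½Σ_diag + D̂D̂ᵀ/(2(K−1))) from the running first and second moments
  of constant-rate SGD iterates and a FIFO deviation matrix D̂; several
  independently trained SWAG models are combined by Bayesian model
  averaging over an equal number of Monte-Carlo weight samples each.
* **Calibration diagnostics**: MAE/accuracy, reliability diagrams binned by
  predicted standard deviation (width 0.02), ENCE and ECE for regression,
  count-weighted rank-k ECE for classification, column-normalised confusion
  matrices, mean-confidence tables and predicted-error histograms.

## Worked example

Train a scaled-down Multi-SWAG ensemble (3 members, keep the best 2 by
validation loss) to regress α on FBM trajectories of length 50, and check
its calibration — about two minutes on one CPU:

```python
import numpy as np
from diffuq import (PriorSpec, generate_dataset, NetworkSpec, TrainConfig,
                    SwagConfig, build_multiswag, multiswag_predict,
                    dataset_to_arrays)
from diffuq.evaluate import RegressionEvalRecord, regression_report

prior = PriorSpec(task="regression", models=("FBM",))
train = dataset_to_arrays(generate_dataset("regression", 2000, 50, prior, master_seed=1))
val   = dataset_to_arrays(generate_dataset("regression", 400, 50, prior, master_seed=2))
X_test, alpha_test = dataset_to_arrays(
    generate_dataset("regression", 800, 50, prior, master_seed=3))

spec = NetworkSpec(head="regression", lstm_sizes=(32, 32))
cfg = TrainConfig(epochs_total=13, epochs_swag=4, batch_size=64,
                  swag=SwagConfig(eta=1e-4, K_cols=4),
                  n_models=3, n_keep=2, samples_per_model=10, master_seed=0)
states = build_multiswag(spec, train, val, cfg)
pred = multiswag_predict(states, X_test, cfg.swag, np.random.default_rng(0))

records = [RegressionEvalRecord(m, s, a)
           for m, s, a in zip(pred.mu, pred.sigma, alpha_test)]
report = regression_report(records)
print(f"MAE  = {report.mae:.3f}")
print(f"ENCE = {report.ence:.3f}")
print(f"ECE  = {report.ece:.4f}")
print(f"first prediction: mu = {pred.mu[0]:.2f} +/- {pred.sigma[0]:.2f} "
      f"(truth {alpha_test[0]:.2f})")
```

Output:

```
MAE  = 0.195
ENCE = 0.205
ECE  = 0.0536
first prediction: mu = 1.41 +/- 0.24 (truth 1.80)
```

The MAE of 0.195 beats the analytic baseline of 0.5 obtained by always
predicting the prior mean of a uniform exponent on (0, 2); the ENCE says
the predicted standard deviations track the observed errors to about 20%
relative at this toy scale, and each prediction comes with its own error
bar (here the truth lies within two predicted standard deviations).

The same workflow is available from the shell:

```bash
diffuq simulate --task regression --n 2000 --length 50 --seed 1 --out data/train
diffuq train --task regression --train data/train --val data/val \
       --config cfg.yaml --seed 0 --out model/
diffuq predict --model-dir model/ --data data/test --out pred.csv
diffuq evaluate --task regression --pred pred.csv --data data/test --out report.json
```

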
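# vitalfuse

Fully-Bayesian fusion of continuous-valued labels from multiple imperfect
annotators, with a respiratory-rate-from-PPG front end.

## The problem

Automated algorithms that label physiological time series (for example,
respiratory-rate estimators running on wearable photoplethysmography) are
individually unreliable: each carries its own systematic bias and noise
level, different algorithms are best for different patients, and any of them
can drop out for stretches of a recording. Without gold-standard reference
labels, which algorithm should be trusted — and how should their outputs be
merged into one estimate per sample, with honest uncertainty?

`vitalfuse` answers this with two unsupervised graphical models fitted by
Gibbs sampling. Both treat the N observed labels per annotator as noisy,
biased views of a latent ground truth and infer everything jointly:

**Independent Annotator Model (IAM).** For sample *i* and annotator *j*,

```
z_i  ~ N(x_i'w, 1/b)                  latent truth, linear-regression mean
y_ij ~ N(z_i + phi_j, 1/lambda_j)     label = truth + bias + noise
phi_j ~ N(mu_phi, 1/alpha_phi)        annotator bias
lambda_j, alpha_phi, b ~ Gamma(k, theta)
```

Annotator errors are conditionally independent given the truth. Every full
conditional is conjugate (Gaussian or gamma), and all sums run over the
observed entries only, so arbitrarily missing labels are handled natively.

**Correlated Annotator Model (CAM).** Real annotators are often variants of
the same underlying algorithm, so their errors correlate. CAM replaces the
per-annotator noise with a joint multivariate normal,

```
y_i ~ N(z_i 1 + phi, Sigma),   phi ~ N(mu_phi, Sigma/k0),   Sigma ~ IW(nu, S)
```

and reports `Sigma = Q rho Q`, separating per-annotator error standard
deviations (Q) from the latent error-correlation matrix (rho). A clique of
mutually correlated, high-variance annotators is automatically
down-weighted; an independent precise annotator dominates the fused
estimate. Missing labels are handled by data augmentation inside the
sampler.

The fused output per sample is the posterior mean of `z_i` with an
empirical 95% credible interval.

**RR front end.** For the respiratory-rate use case the package also
converts a PPG waveform into its "annotators": pulse-peak detection, three
respiratory modulation series (amplitude modulation, baseline wander,
frequency modulation) resampled at 4 Hz, 32-s windows with 29-s overlap,
and two spectral estimators per series (periodogram peak and Burg
autoregressive spectrum) — six RR estimates per window, gated by spectral
quality, ready for fusion.

## Worked example

```
vitalfuse simulate --kind ppg --duration-s 480 --seed 0 --out demo/
vitalfuse rr-extract --ppg demo/record.csv --out demo/labels.csv
vitalfuse fuse --model iam --labels demo/labels.csv --seed 0 --out demo/fused/
```

which prints

```
wrote demo/record.csv (480s)
wrote demo/labels.csv (150 windows x 6 estimators)
wrote demo/fused/fused_estimates.csv (150 rows)
```

The simulated 8-minute record breathes at 15 breaths/min. The first fused
windows (`demo/fused/fused_estimates.csv`):

```
sample_id,posterior_mean,ci_low,ci_high
t0s,15.0362149,15.0089695,15.0579195
t3s,15.0481836,15.0233666,15.0708222
t6s,15.0457343,15.0221436,15.0689476
```

Each row is one 32-s window: the posterior-mean respiratory rate in
breaths/min and its 95% credible interval — all within a twentieth of a
breath of the true rate (the six synthetic estimators agree closely here;
noisier records give proportionally wider intervals). `demo/fused/annotator_report.csv` gives each of the six
estimators' inferred bias and precision with intervals; with
`--model cam` the run also writes `sigma.csv` and `rho.csv`, the posterior
error covariance and correlation between estimators.

In library form the same is three calls:

```python
import vitalfuse as vf

rec, rr = vf.simulate_ppg(duration_s=480, seed=0)
data = vf.build_annotation_set(vf.extract_rr_estimates(rec))
chain = vf.run_chain(data, config=vf.GibbsConfig(model="iam", seed=0))
print(chain.summary["z"].head())
```

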
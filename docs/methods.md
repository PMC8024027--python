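# Methods

This note documents the models, the sampler, the synthetic-data generators
and the numerical choices behind `vitalfuse`, in the order a reader needs
them to judge what the tests do and do not establish.

## Models and assumptions

Both models assume each of N samples has a scalar latent ground truth
`z_i`, Gaussian around a linear-regression mean `x_i'w` with precision `b`
(the design matrix always carries a leading intercept column; with no
features supplied it is intercept-only). Each of R annotators reports a
label equal to the truth plus a fixed additive bias and zero-mean noise.
Samples are treated as exchangeable: no temporal correlation between
windows is modelled, so the models apply equally to time-series windows and
to unordered crowd-labelled items.

**IAM** takes annotator noises conditionally independent given the truth,
`y_ij ~ N(z_i + phi_j, 1/lambda_j)`, with conjugate priors: Gaussian on
biases (`N(mu_phi, 1/alpha_phi)`) and gammas on all precisions. **CAM**
replaces the noise model with a joint multivariate normal
`y_i ~ N(z_i 1 + phi, Sigma)`, a normal-inverse-Wishart prior on
`(phi, Sigma)` (`phi ~ N(mu_phi, Sigma/k0)`, `Sigma ~ IW(nu, S)`), and the
same truth prior. For reporting, `Sigma` is separated as `Q rho Q` with
`Q = diag(sqrt(Sigma_jj))`; the separation is a deterministic
post-processing step, not a prior placed on `rho` and `Q` themselves.

## Gibbs sweeps

All full conditionals are standard distributions; one sweep visits

* IAM: `z`, `phi`, `lambda`, `alpha_phi`, `b`, `w`;
* CAM: impute missing labels, `z`, `Sigma`, `phi`, `b`, `w`.

`w` is not sampled but set to the least-squares fit of the current `z`
on `X` (the zero-gradient of the expected complete-data log-likelihood);
rank-deficient designs fall back to the pseudoinverse with a warning.

Two printed-form choices are kept configurable because the conventional
update and the model-consistent one differ:

* `b_update_mode`: `as_printed` (default) rates the gamma update by the
  dispersion of `z` around its own mean; `regression_residual` uses
  `(z_i - x_i'w)^2`, the residual the regression prior implies. The two
  coincide for an intercept-only design with `w` at its least-squares
  value.
* `alpha_phi` is rated by the dispersion of the biases around their
  current mean (not around `mu_phi`); with the default `mu_phi = 0` and
  centred biases the difference is negligible.

**CAM missing labels — data augmentation.** Unobserved entries of `y_i`
are redrawn each sweep from their conditional normal given the observed
entries of the same row (rows grouped by missingness pattern). The `phi`
and `Sigma` conditionals then take their exact complete-data
normal-inverse-Wishart form: residual means `ybar_b = mean_i(y_i - z_i)`
over all N completed rows, `phi | Sigma ~ N((k0 mu + N ybar_b)/(k0+N),
Sigma/(k0+N))`, and `Sigma` drawn *before* `phi` from its bias-marginalized
inverse-Wishart conditional with `nu* = nu + N` and
`S* = S + sum_i r_i r_i' + k0 N/(k0+N)(ybar_b - mu)(ybar_b - mu)'`,
`r_i = y_i - z_i 1 - ybar_b`. Drawing `Sigma` marginally and then
`phi | Sigma` is a blocked draw of the joint conditional, so the sweep is a
valid Gibbs sampler. We verified this with successive-conditional
("getting it right") testing: alternating the transition kernel with fresh
data regenerated from the current parameters reproduces the prior moments
of `Sigma` to three decimals, whereas variants that mix observed-only
residual means (normalized by per-annotator counts `U_j`) into the
complete-data updates fail the same test by ~15% — those forms are kept
only behind `phi_update_mode="as_printed"` for comparability, and are not
exact conditionals under augmentation.

**Identifiability and the `w` update.** With an intercept in `X` and `w`
re-fit every sweep, the posterior is invariant to the common shift
`(z - c, phi + c)`: the intercept absorbs any shift of `z`, and only the
(learned, weak) bias prior pins the split, so posterior means of `phi` can
drift by a few tenths of a label unit over a desk-scale chain. The chain
default follows the model as stated (`update_w_every_sweep=True`), but the
recovery and consistency experiments freeze `w` at its initialization fit
(`update_w_every_sweep=False`), which anchors the latent location at the
data scale; this is the configuration we recommend whenever the absolute
level of the biases matters. An equivalent alternative is a fixed, strongly
informative regression prior.

## Defaults and hyperparameters (label units throughout)

| Parameter | Default | Why |
|---|---|---|
| `mu_phi` | 0 | no prior preference for positive or negative bias |
| `k_lambda, k_alpha, k_b` / `theta_*` | 1e-3 / 1e3 | diffuse gammas, prior mean 1 for every precision |
| CAM `k0` | 1 | one pseudo-observation of prior belief in `mu_phi` |
| CAM `nu` | R + 2 | smallest integer giving a finite IW mean |
| CAM `S` | identity | IW prior mean is then exactly the identity |
| `n_iter` / `burn_in` / `thin` | 3000 / 1000 / 1 | conjugate conditionals mix fast; 2000 retained draws give per-quantity MC error well under posterior spread |
| credible level | 0.95 | empirical 2.5/97.5 percentiles, no normality assumption |

Convergence is monitored by a single-chain Geweke-style score (first 10%
vs last 50% of retained draws, independent-segment variance); |z| > 3 logs
a warning. No multi-chain R-hat is provided.

## Respiratory-rate front end

* **Beat detection**: local maxima above an adaptive threshold (median +
  quarter of the median-to-max range), prominence at least 10% of the
  signal range, refractory period 60/220 s. Records with fewer than 8
  beats are rejected.
* **Modulation series**: per beat, amplitude = peak minus preceding
  trough (AM), baseline = trough level (BW), instantaneous rate = 60/IBI
  (FM); linearly interpolated to a uniform 4 Hz grid spanning the record
  and mean-detrended. 4 Hz is Nyquist-safe for the 4–60 breaths/min band.
* **Windows**: 32 s with 29 s overlap (3-s stride), fully contained in the
  record: a T-second record yields floor((T−32)/3)+1 windows; 8 minutes
  gives exactly 150.
* **Spectral RR**: per window, linear detrend; (a) Hann-tapered,
  zero-padded periodogram peak; (b) Burg AR(10) spectral peak (the
  innovation variance cancels in the quality ratio and is dropped, which
  also makes noiseless windows well-defined). Both search 4–60
  breaths/min only.
* **Quality gate**: an estimate is kept when the in-band peak of the
  0.45-Hz-moving-average-smoothed spectrum exceeds twice its in-band
  median. The smoothing is what makes the gate meaningful: raw periodogram
  bins of pure noise always contain a few outliers several times the
  median, while a genuine respiratory peak concentrates enough power to
  survive averaging. Gated-out estimates become missing labels, which the
  fusion models absorb natively.
* AR order (10) and the gate bandwidth are configurable/constants chosen
  once for 32-s respiratory windows; the paper trail for all front-end
  settings is in this section because the upstream experiment description
  fixes only the windowing and the six-estimator design.

## Synthetic data: what it emulates, what it does not

`simulate_iam` / `simulate_cam` draw exactly from the corresponding model:
standard-normal features (when requested), truth around the regression
mean, labels = truth + bias + (independent or jointly normal) noise, and a
missing-completely-at-random mask re-drawn per row until every sample keeps
at least one label. Moment tests at N=5000 confirm the generators match
their models within 3 sampling standard errors, so recovery failures
indict the sampler rather than the data.

`simulate_ppg` builds a raised-cosine pulse train `((1-cos phase)/2)^3` at
the requested heart rate and modulates it multiplicatively (AM), additively
(BW) and in instantaneous frequency (FM) at the respiratory frequency,
plus white noise. It does not model pulse morphology (no dicrotic notch),
motion artefacts, arrhythmia, or drifting respiratory rate — so passing
end-to-end tests demonstrates the pipeline's correctness on clean
modulation structure, not clinical-grade robustness. Default depths
(0.15/0.15/0.05, noise sd 0.02 at unit pulse amplitude) give six
estimators that all succeed on most windows; real recordings will populate
the missing-label machinery far more heavily.

## Degenerate inputs and numerical choices

* Samples with no labels fall back to their prior conditional (the grand
  mean at initialization); annotators with no labels revert to their
  priors exactly.
* `Sigma` draws are symmetrized and Cholesky-checked every sweep; a
  non-positive-definite conditional scale raises a structured error naming
  the sweep.
* Conditional imputation adds 1e-12 to the conditional covariance diagonal
  before factorization to absorb rounding at near-singular `Sigma`.
* All output floats are written with 9 significant digits; runs write no
  timestamps, so identical seed and config reproduce every output file
  byte for byte.

## Known limitations

* Single chain only; no cross-chain convergence diagnostics.
* The common-shift mode above means per-annotator biases are weakly
  identified when `w` tracks `z` each sweep; use the frozen-`w`
  configuration (or informative `mu_phi`/`alpha_phi`) when biases are the
  quantity of interest.
* CAM sampling cost grows with the number of distinct missingness
  patterns (conditional imputation per pattern) and as O(R^3) per sweep.
* The front end reads single-channel plain-text records (CSV with a
  sampling-rate header); multi-channel waveform-database formats are out
  of scope.
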
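"""Gibbs-chain orchestration, posterior summaries and baselines.

Runs full chains for either annotator model with a fixed sweep order
(IAM: z, phi, lambda, alpha_phi, b, w; CAM: impute, z, Sigma, phi, b, w —
Sigma is drawn from its bias-marginalized conditional, then the bias given
Sigma, a valid blocked draw of the joint),
retains post-burn-in thinned draws, and summarizes each quantity with a
posterior mean and central credible interval (empirical percentiles, 95%
by default).  Also provides the naive mean/median fusion baselines and the
per-subject MAE/SEM evaluation used to compare fused estimates against a
reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np
import pandas as pd

from . import cam_model, iam_model
from .cam_model import CAMHyperparams, CAMState
from .errors import ConfigurationError, InputError, NumericalStateError
from .iam_model import AnnotationSet, FeatureMatrix, IAMHyperparams, IAMState

__all__ = [
    "GibbsConfig",
    "PosteriorChain",
    "initialize_state",
    "run_chain",
    "summarize_posterior",
    "geweke_diagnostic",
    "naive_fusion",
    "evaluate_mae",
]

Hyperparams = Union[IAMHyperparams, CAMHyperparams]


@dataclass
class GibbsConfig:
    """Run configuration for a single Gibbs chain.

    Defaults give a desk-scale chain (3000 sweeps, 1000 burn-in) that is
    long enough for the conjugate conditionals here to mix well.
    """

    model: str = "iam"
    n_iter: int = 3000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    b_update_mode: str = "as_printed"
    phi_update_mode: str = "conjugate"
    update_w_every_sweep: bool = True

    def __post_init__(self) -> None:
        if self.model not in ("iam", "cam"):
            raise ConfigurationError(f"model must be 'iam' or 'cam', got {self.model!r}")
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be a positive integer")
        if not 0 <= self.burn_in < self.n_iter:
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PosteriorChain:
    """Retained post-burn-in draws, keyed by quantity name.

    ``draws`` maps names ("z", "phi", "lam" or "Sigma", "b", "alpha_phi",
    "w") to arrays whose first axis indexes retained sweeps.
    """

    draws: dict[str, np.ndarray]
    config: GibbsConfig
    annotator_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def mean(self, name: str) -> np.ndarray:
        return self.draws[name].mean(axis=0)

    @property
    def summary(self) -> dict[str, pd.DataFrame]:
        return summarize_posterior(self)


def initialize_state(
    data: AnnotationSet, X: FeatureMatrix, config: GibbsConfig
) -> IAMState | CAMState:
    """Deterministic starting point for a chain.

    z starts at the per-sample mean of observed labels (grand mean for rows
    with no labels); phi = 0; unit precisions / identity covariance; w at
    the least-squares fit of the initial z; missing labels imputed at
    z_i + phi_j.
    """
    if not data.mask.any():
        raise InputError("annotation set contains no observed labels")
    counts = data.labels_per_sample
    sums = data.observed_or(0.0).sum(axis=1)
    grand_mean = float(data.labels[data.mask].mean())
    z0 = np.where(counts > 0, sums / np.maximum(counts, 1), grand_mean)
    w0 = iam_model.update_w(z0, X)
    r = data.n_annotators
    if config.model == "iam":
        return IAMState(
            z=z0, phi=np.zeros(r), lam=np.ones(r), b=1.0, alpha_phi=1.0, w=w0
        )
    y0 = np.where(data.mask, data.labels, z0[:, None] + 0.0)
    return CAMState(
        z=z0, phi=np.zeros(r), Sigma=np.eye(r), b=1.0, w=w0, y_imputed=y0
    )


def _run_iam(
    data: AnnotationSet,
    X: FeatureMatrix,
    hyp: IAMHyperparams,
    config: GibbsConfig,
    rng: np.random.Generator,
    state: IAMState,
) -> dict[str, list]:
    kept: dict[str, list] = {k: [] for k in ("z", "phi", "lam", "alpha_phi", "b", "w")}
    for sweep in range(config.n_iter):
        try:
            state.z = iam_model.sample_z(state, data, X, rng)
            state.phi = iam_model.sample_phi(state, data, hyp, rng)
            state.lam = iam_model.sample_lambda(state, data, hyp, rng)
            state.alpha_phi = iam_model.sample_alpha_phi(state, hyp, rng)
            state.b = iam_model.sample_b(state, X, hyp, config.b_update_mode, rng)
            if config.update_w_every_sweep:
                state.w = iam_model.update_w(state.z, X)
        except NumericalStateError as exc:
            raise NumericalStateError(f"sweep {sweep}: {exc}") from exc
        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            kept["z"].append(state.z.copy())
            kept["phi"].append(state.phi.copy())
            kept["lam"].append(state.lam.copy())
            kept["alpha_phi"].append(state.alpha_phi)
            kept["b"].append(state.b)
            kept["w"].append(state.w.copy())
    return kept


def _run_cam(
    data: AnnotationSet,
    X: FeatureMatrix,
    hyp: CAMHyperparams,
    config: GibbsConfig,
    rng: np.random.Generator,
    state: CAMState,
) -> dict[str, list]:
    kept: dict[str, list] = {k: [] for k in ("z", "phi", "Sigma", "b", "w")}
    # b and w reuse the IAM updates (identical priors in both models)
    iam_hyp = IAMHyperparams(k_b=hyp.k_b, theta_b=hyp.theta_b)
    for sweep in range(config.n_iter):
        try:
            state.y_imputed = cam_model.impute_missing_labels(state, data, rng)
            state.z = cam_model.sample_z_cam(state, data, X, rng)
            # blocked (phi, Sigma) draw: Sigma from its phi-marginalized
            # conditional first, then phi | Sigma (valid collapsed order)
            state.Sigma = cam_model.sample_sigma_cam(
                state, data, hyp, rng, mode=config.phi_update_mode
            )
            state.phi = cam_model.sample_phi_cam(
                state, data, hyp, rng, mode=config.phi_update_mode
            )
            iam_view = IAMState(
                z=state.z,
                phi=state.phi,
                lam=np.ones(data.n_annotators),
                b=state.b,
                alpha_phi=1.0,
                w=state.w,
            )
            state.b = iam_model.sample_b(iam_view, X, iam_hyp, config.b_update_mode, rng)
            if config.update_w_every_sweep:
                state.w = iam_model.update_w(state.z, X)
        except NumericalStateError as exc:
            raise NumericalStateError(f"sweep {sweep}: {exc}") from exc
        if sweep >= config.burn_in and (sweep - config.burn_in) % config.thin == 0:
            kept["z"].append(state.z.copy())
            kept["phi"].append(state.phi.copy())
            kept["Sigma"].append(state.Sigma.copy())
            kept["b"].append(state.b)
            kept["w"].append(state.w.copy())
    return kept


def run_chain(
    data: AnnotationSet,
    X: FeatureMatrix | None = None,
    hyp: Hyperparams | None = None,
    config: GibbsConfig | None = None,
) -> PosteriorChain:
    """Run one full Gibbs chain and return the retained draws.

    Fully reproducible under a fixed ``config.seed``.  Number of retained
    draws is floor((n_iter - burn_in)/thin) (plus one when the division is
    exact at the first kept sweep).
    """
    config = config or GibbsConfig()
    if X is None:
        X = FeatureMatrix.from_features(None, data.n_samples)
    if hyp is None:
        hyp = (
            IAMHyperparams()
            if config.model == "iam"
            else CAMHyperparams.default(data.n_annotators)
        )
    rng = np.random.default_rng(config.seed)
    state = initialize_state(data, X, config)
    if config.model == "iam":
        if not isinstance(hyp, IAMHyperparams):
            raise ConfigurationError("IAM chain needs IAMHyperparams")
        kept = _run_iam(data, X, hyp, config, rng, state)
    else:
        if not isinstance(hyp, CAMHyperparams):
            raise ConfigurationError("CAM chain needs CAMHyperparams")
        kept = _run_cam(data, X, hyp, config, rng, state)
    draws = {k: np.asarray(v) for k, v in kept.items()}
    return PosteriorChain(
        draws=draws,
        config=config,
        annotator_ids=list(data.annotator_ids),
        sample_ids=list(data.sample_ids),
    )


def summarize_posterior(
    chain: PosteriorChain, level: float = 0.95
) -> dict[str, pd.DataFrame]:
    """Per-quantity posterior mean and central credible interval.

    Interval bounds are the empirical (1-level)/2 and (1+level)/2
    percentiles of the retained draws, matching the dashed-interval style
    of per-window fused-estimate plots.
    """
    if not 0 < level < 1:
        raise ConfigurationError("level must lie in (0, 1)")
    if chain.n_draws < 2:
        raise InputError("need at least 2 retained draws to summarize")
    lo_q, hi_q = 50 * (1 - level), 50 * (1 + level)
    out: dict[str, pd.DataFrame] = {}
    for name, arr in chain.draws.items():
        flat = arr.reshape(arr.shape[0], -1)
        df = pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "ci_low": np.percentile(flat, lo_q, axis=0),
                "ci_high": np.percentile(flat, hi_q, axis=0),
            }
        )
        if name == "z" and chain.sample_ids and len(chain.sample_ids) == df.shape[0]:
            df.index = pd.Index(chain.sample_ids, name="sample_id")
        elif (
            name in ("phi", "lam")
            and chain.annotator_ids
            and len(chain.annotator_ids) == df.shape[0]
        ):
            df.index = pd.Index(chain.annotator_ids, name="annotator_id")
        out[name] = df
    return out


def geweke_diagnostic(
    chain: PosteriorChain, quantity: str, index: int | tuple = 0
) -> float:
    """Geweke-style convergence z-score for one scalar chain quantity.

    Compares the mean of the first 10% of retained draws with the mean of
    the last 50%, standardized by the independent-segment standard error.
    |z| > 3 indicates the two chain segments disagree (a warning sign, not
    an error).
    """
    if quantity not in chain.draws:
        raise InputError(
            f"unknown quantity {quantity!r}; have {sorted(chain.draws)}"
        )
    arr = chain.draws[quantity]
    series = arr if arr.ndim == 1 else arr[(slice(None), *np.atleast_1d(index))]
    series = np.asarray(series, dtype=float).ravel()
    n = series.size
    if n < 100:
        raise InputError(f"need >= 100 retained draws for the diagnostic, have {n}")
    a = series[: max(1, n // 10)]
    b = series[n - n // 2:]
    var = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


def naive_fusion(data: AnnotationSet, method: str = "mean") -> np.ndarray:
    """Per-sample mean or median of the observed labels (baseline fusion)."""
    if method not in ("mean", "median"):
        raise ConfigurationError(f"method must be 'mean' or 'median', got {method!r}")
    counts = data.labels_per_sample
    if np.any(counts == 0):
        bad = int(np.flatnonzero(counts == 0)[0])
        raise InputError(f"sample {data.sample_ids[bad]!r} has no observed labels")
    masked = np.ma.masked_array(data.labels, mask=~data.mask)
    if method == "mean":
        return np.asarray(masked.mean(axis=1))
    return np.asarray(np.ma.median(masked, axis=1))


def evaluate_mae(
    estimates: np.ndarray, truth: np.ndarray, subject_ids: np.ndarray | list
) -> tuple[pd.Series, float, float]:
    """Per-subject MAE plus the across-subject mean MAE and its SEM.

    Each subject's MAE is averaged over that subject's windows; SEM is the
    sample standard deviation of the per-subject MAEs divided by
    sqrt(number of subjects) (0 for a single subject).
    """
    estimates = np.asarray(estimates, dtype=float)
    truth = np.asarray(truth, dtype=float)
    subject_ids = np.asarray(subject_ids)
    if not estimates.shape == truth.shape == subject_ids.shape:
        raise InputError(
            f"length mismatch: estimates {estimates.shape}, truth {truth.shape}, "
            f"subjects {subject_ids.shape}"
        )
    err = pd.Series(np.abs(estimates - truth))
    per_subject = err.groupby(pd.Series(subject_ids)).mean()
    per_subject.index.name = "subject_id"
    per_subject.name = "mae"
    n_subj = per_subject.size
    mean_mae = float(per_subject.mean())
    sem = float(per_subject.std(ddof=1) / np.sqrt(n_subj)) if n_subj > 1 else 0.0
    return per_subject, mean_mae, sem
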
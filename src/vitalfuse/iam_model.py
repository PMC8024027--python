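"""Independent Annotator Model (IAM).

Each of R annotators produces a continuous label for some subset of N
samples.  Labels are modelled as the latent ground truth plus an
annotator-specific additive bias and Gaussian noise with annotator-specific
precision:

    z_i   ~ N(x_i'w, 1/b)                latent truth, linear-regression mean
    y_ij  ~ N(z_i + phi_j, 1/lambda_j)   observed label
    phi_j ~ N(mu_phi, 1/alpha_phi)       annotator bias
    lambda_j, alpha_phi, b ~ Gamma(shape, scale)

All full conditionals are conjugate; this module provides the domain types
and one Gibbs draw per latent block.  Every sampler also exposes its
conditional parameters (`*_conditional` functions) so they can be checked
against brute-force oracles without Monte-Carlo noise.

Missing labels are first-class: the boolean ``mask`` restricts every sum to
the observed entries, so an annotator with no labels (or a sample with no
annotators) reverts to its prior conditional.

Gamma conventions: hyperparameters are stored as shape/scale (matching the
usual Gamma(k, theta) notation); the conditional updates are additive in the
rate 1/theta, so the conditional helpers return (shape, rate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DimensionError

__all__ = [
    "AnnotationSet",
    "FeatureMatrix",
    "IAMHyperparams",
    "IAMState",
    "sample_z",
    "sample_phi",
    "sample_lambda",
    "sample_alpha_phi",
    "sample_b",
    "update_w",
    "z_conditional",
    "phi_conditional",
    "lambda_conditional",
    "alpha_phi_conditional",
    "b_conditional",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """N x R continuous label matrix with an observation mask.

    ``labels[i, j]`` is annotator j's label for sample i, in the measured
    quantity's units (breaths/min for respiratory rate).  Entries where
    ``mask`` is false are never read and may hold any sentinel (NaN in CSV).
    """

    labels: np.ndarray
    mask: np.ndarray
    annotator_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.ndim != 2:
            raise DimensionError(f"labels must be 2-D, got shape {self.labels.shape}")
        if self.mask.shape != self.labels.shape:
            raise DimensionError(
                f"mask shape {self.mask.shape} != labels shape {self.labels.shape}"
            )
        n, r = self.labels.shape
        if n < 1 or r < 1:
            raise DimensionError(f"need N >= 1 and R >= 1, got N={n}, R={r}")
        if not np.all(np.isfinite(self.labels[self.mask])):
            raise ValueError("labels must be finite wherever mask is true")
        if not self.annotator_ids:
            self.annotator_ids = [f"A{j + 1}" for j in range(r)]
        if not self.sample_ids:
            self.sample_ids = [str(i) for i in range(n)]
        if len(self.annotator_ids) != r:
            raise DimensionError("annotator_ids length must equal R")
        if len(self.sample_ids) != n:
            raise DimensionError("sample_ids length must equal N")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def n_annotators(self) -> int:
        return self.labels.shape[1]

    @property
    def labels_per_annotator(self) -> np.ndarray:
        """N_j: number of samples labelled by each annotator (length R)."""
        return self.mask.sum(axis=0)

    @property
    def labels_per_sample(self) -> np.ndarray:
        """|V_i|: number of annotators that labelled each sample (length N)."""
        return self.mask.sum(axis=1)

    def observed_or(self, fill: float = 0.0) -> np.ndarray:
        """Labels with masked-out entries replaced by ``fill`` (safe for sums)."""
        return np.where(self.mask, self.labels, fill)


@dataclass
class FeatureMatrix:
    """Design matrix with a leading intercept column.

    ``X`` is N x (d+1); the first column is identically one so the
    regression prior on the latent truth always carries an intercept.
    """

    X: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(self.X[:, 0] == 1.0):
            raise DimensionError("first column of X must be identically 1 (intercept)")

    @classmethod
    def from_features(cls, features: np.ndarray | None, n_samples: int) -> "FeatureMatrix":
        """Prepend the intercept column to raw features (or build intercept-only)."""
        if features is None:
            return cls(np.ones((n_samples, 1)))
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[0] != n_samples:
            raise DimensionError(
                f"feature rows {features.shape[0]} != number of samples {n_samples}"
            )
        return cls(np.column_stack([np.ones(n_samples), features]))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        """Number of supplied (non-intercept) features."""
        return self.X.shape[1] - 1


@dataclass
class IAMHyperparams:
    """Fixed prior constants for the IAM.

    Defaults are weakly informative: zero prior bias mean and diffuse
    Gamma(1e-3, 1e3) priors (prior mean 1, prior variance 1e3) on all
    precisions.
    """

    mu_phi: float = 0.0
    k_lambda: float = 1e-3
    theta_lambda: float = 1e3
    k_alpha: float = 1e-3
    theta_alpha: float = 1e3
    k_b: float = 1e-3
    theta_b: float = 1e3

    def __post_init__(self) -> None:
        for name in ("k_lambda", "theta_lambda", "k_alpha", "theta_alpha", "k_b", "theta_b"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"hyperparameter {name} must be > 0")


@dataclass
class IAMState:
    """One Gibbs iterate of all IAM latent variables."""

    z: np.ndarray          # (N,) latent ground truth
    phi: np.ndarray        # (R,) annotator biases
    lam: np.ndarray        # (R,) annotator precisions, > 0
    b: float               # ground-truth precision, > 0
    alpha_phi: float       # bias-population precision, > 0
    w: np.ndarray          # (d+1,) regression coefficients

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.lam <= 0) or self.b <= 0 or self.alpha_phi <= 0:
            raise ValueError("precisions lam, b, alpha_phi must be strictly positive")

    @property
    def phi_bar(self) -> float:
        return float(np.mean(self.phi))

    @property
    def z_bar(self) -> float:
        return float(np.mean(self.z))


def _check_dims(state: IAMState, data: AnnotationSet, X: FeatureMatrix | None = None) -> None:
    n, r = data.labels.shape
    if state.z.shape != (n,):
        raise DimensionError(f"state.z has shape {state.z.shape}, expected ({n},)")
    if state.phi.shape != (r,):
        raise DimensionError(f"state.phi has shape {state.phi.shape}, expected ({r},)")
    if state.lam.shape != (r,):
        raise DimensionError(f"state.lam has shape {state.lam.shape}, expected ({r},)")
    if X is not None:
        if X.n_samples != n:
            raise DimensionError(f"X has {X.n_samples} rows, expected {n}")
        if state.w.shape != (X.X.shape[1],):
            raise DimensionError(
                f"state.w has shape {state.w.shape}, expected ({X.X.shape[1]},)"
            )


# ---------------------------------------------------------------------------
# conditional parameters (deterministic) and Gibbs draws
# ---------------------------------------------------------------------------


def z_conditional(
    state: IAMState, data: AnnotationSet, X: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian full-conditional parameters (mean a_i*, precision b_i*) for z.

    b_i* = b + sum_{j in V_i} lambda_j and
    a_i* = (b x_i'w + sum_{j in V_i} lambda_j (y_ij - phi_j)) / b_i*.
    A sample with no observed labels reverts to the prior N(x_i'w, 1/b).
    """
    _check_dims(state, data, X)
    prior_mean = X.X @ state.w
    prec = state.b + data.mask @ state.lam
    resid = np.where(data.mask, data.labels - state.phi[None, :], 0.0)
    mean = (state.b * prior_mean + resid @ state.lam) / prec
    return mean, prec


def sample_z(
    state: IAMState, data: AnnotationSet, X: FeatureMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Draw the latent truth vector z from its Gaussian full conditional."""
    mean, prec = z_conditional(state, data, X)
    return rng.normal(mean, 1.0 / np.sqrt(prec))


def phi_conditional(
    state: IAMState, data: AnnotationSet, hyp: IAMHyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian full-conditional (mean mu_phi_j*, precision alpha_phi_j*) for phi.

    alpha_phi_j* = alpha_phi + N_j lambda_j and
    mu_phi_j* = (mu_phi alpha_phi + lambda_j sum_{i in U_j}(y_ij - z_i)) / alpha_phi_j*.
    An annotator with no labels reverts to the prior N(mu_phi, 1/alpha_phi).
    """
    _check_dims(state, data)
    n_j = data.labels_per_annotator
    prec = state.alpha_phi + n_j * state.lam
    resid_sum = np.where(data.mask, data.labels - state.z[:, None], 0.0).sum(axis=0)
    mean = (hyp.mu_phi * state.alpha_phi + state.lam * resid_sum) / prec
    return mean, prec


def sample_phi(
    state: IAMState, data: AnnotationSet, hyp: IAMHyperparams, rng: np.random.Generator
) -> np.ndarray:
    """Draw the annotator bias vector phi from its Gaussian full conditional."""
    mean, prec = phi_conditional(state, data, hyp)
    return rng.normal(mean, 1.0 / np.sqrt(prec))


def lambda_conditional(
    state: IAMState, data: AnnotationSet, hyp: IAMHyperparams
) -> tuple[np.ndarray, np.ndarray]:
    """Gamma full-conditional (shape, rate) per annotator precision lambda_j.

    shape = k_lambda + N_j/2, rate = 1/theta_lambda + (1/2) sum of squared
    residuals (y_ij - phi_j - z_i) over the annotator's observed labels.
    """
    _check_dims(state, data)
    n_j = data.labels_per_annotator
    resid = np.where(
        data.mask, data.labels - state.phi[None, :] - state.z[:, None], 0.0
    )
    shape = hyp.k_lambda + 0.5 * n_j
    rate = 1.0 / hyp.theta_lambda + 0.5 * (resid**2).sum(axis=0)
    return shape, rate


def sample_lambda(
    state: IAMState, data: AnnotationSet, hyp: IAMHyperparams, rng: np.random.Generator
) -> np.ndarray:
    """Draw annotator precisions from their gamma full conditionals."""
    shape, rate = lambda_conditional(state, data, hyp)
    return rng.gamma(shape, 1.0 / rate)


def alpha_phi_conditional(state: IAMState, hyp: IAMHyperparams) -> tuple[float, float]:
    """Gamma full-conditional (shape, rate) for the bias-population precision.

    Centred at the current bias mean phi_bar:
    shape = k_alpha + R/2, rate = 1/theta_alpha + (1/2) sum_j (phi_j - phi_bar)^2.
    """
    r = state.phi.shape[0]
    shape = hyp.k_alpha + 0.5 * r
    rate = 1.0 / hyp.theta_alpha + 0.5 * float(np.sum((state.phi - state.phi_bar) ** 2))
    return shape, rate


def sample_alpha_phi(
    state: IAMState, hyp: IAMHyperparams, rng: np.random.Generator
) -> float:
    """Draw alpha_phi from its gamma full conditional."""
    shape, rate = alpha_phi_conditional(state, hyp)
    return float(rng.gamma(shape, 1.0 / rate))


_B_MODES = ("as_printed", "regression_residual")


def b_conditional(
    state: IAMState, X: FeatureMatrix, hyp: IAMHyperparams, mode: str = "as_printed"
) -> tuple[float, float]:
    """Gamma full-conditional (shape, rate) for the ground-truth precision b.

    shape = k_b + N/2.  In ``as_printed`` mode the rate sums (z_i - z_bar)^2;
    in ``regression_residual`` mode it sums (z_i - x_i'w)^2, the residual
    implied by the regression prior on z.  The two coincide for an
    intercept-only design with w at its least-squares value.
    """
    if mode not in _B_MODES:
        raise ConfigurationError(f"unknown b update mode {mode!r}; expected one of {_B_MODES}")
    n = state.z.shape[0]
    if mode == "as_printed":
        ss = float(np.sum((state.z - state.z_bar) ** 2))
    else:
        if X.n_samples != n:
            raise DimensionError(f"X has {X.n_samples} rows, expected {n}")
        ss = float(np.sum((state.z - X.X @ state.w) ** 2))
    return hyp.k_b + 0.5 * n, 1.0 / hyp.theta_b + 0.5 * ss


def sample_b(
    state: IAMState,
    X: FeatureMatrix,
    hyp: IAMHyperparams,
    mode: str = "as_printed",
    rng: np.random.Generator | None = None,
) -> float:
    """Draw b from its gamma full conditional (see :func:`b_conditional`)."""
    shape, rate = b_conditional(state, X, hyp, mode)
    if rng is None:
        rng = np.random.default_rng()
    return float(rng.gamma(shape, 1.0 / rate))


def update_w(z: np.ndarray, X: FeatureMatrix) -> np.ndarray:
    """Closed-form regression update: ordinary least squares of z on X.

    w = (sum_i x_i x_i')^{-1} sum_i x_i z_i.  Deterministic.  A
    rank-deficient design is solved by pseudoinverse with a warning rather
    than a hard failure.
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] != X.n_samples:
        raise DimensionError(f"z has {z.shape[0]} entries, X has {X.n_samples} rows")
    w, _, rank, _ = np.linalg.lstsq(X.X, z, rcond=None)
    if rank < X.X.shape[1]:
        warnings.warn(
            "rank-deficient design matrix; regression coefficients solved by "
            "pseudoinverse (minimum-norm solution)",
            RuntimeWarning,
            stacklevel=2,
        )
    return w
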
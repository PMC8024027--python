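"""Correlated Annotator Model (CAM).

Relaxes the IAM's conditional-independence assumption: the R annotators'
error vector for a sample is jointly multivariate normal with a full
covariance Sigma,

    y_i ~ N(z_i 1 + phi, Sigma),
    phi ~ N(mu_phi_Sigma, Sigma / k0),
    Sigma ~ InverseWishart(nu, S),

with the same regression prior N(x_i'w, 1/b) on the latent truth z_i as the
IAM.  An annotator that tracks the others closely but with large variance
and bias is effectively down-weighted by the Sigma-aware conditional for z.

For reporting, Sigma separates as Sigma = Q rho Q with Q = diag(sigma_j)
(per-annotator error standard deviations, i.e. 1/sqrt(lambda_j)) and rho the
latent error-correlation matrix.

Missing labels are handled by within-sweep data augmentation
(:func:`impute_missing_labels`): unobserved entries are drawn from their
conditional normal given the observed entries of the same sample, after
which the complete-data conjugate updates for phi and Sigma apply exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DimensionError, NumericalStateError
from .iam_model import AnnotationSet, FeatureMatrix

__all__ = [
    "CAMHyperparams",
    "CAMState",
    "CorrelationDecomposition",
    "sample_phi_cam",
    "sample_sigma_cam",
    "sample_z_cam",
    "impute_missing_labels",
    "decompose_sigma",
    "phi_cam_conditional",
    "sigma_cam_conditional",
    "z_cam_conditional",
    "bias_residual_means",
]

_SYM_TOL = 1e-10


def _require_spd(mat: np.ndarray, what: str) -> np.ndarray:
    """Cholesky factor of ``mat``; raises NumericalStateError if not SPD."""
    if not np.allclose(mat, mat.T, atol=_SYM_TOL * max(1.0, float(np.abs(mat).max()))):
        raise NumericalStateError(f"{what} is not symmetric")
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise NumericalStateError(
            f"{what} is not positive definite; consider a stronger prior "
            "(larger nu or S) or rescaled labels"
        ) from exc


@dataclass
class CAMHyperparams:
    """Prior constants for the CAM.

    mu_phi_sigma is the prior mean of the bias vector; k0 scales the prior
    confidence in it (the bias prior covariance is Sigma/k0).  The
    inverse-Wishart prior IW(nu, S) on Sigma needs nu > R - 1; the default
    builder uses nu = R + 2, the smallest integer giving a finite IW mean,
    with S = I so that prior mean equals the identity.
    """

    mu_phi_sigma: np.ndarray
    k0: float = 1.0
    nu: float = 0.0
    S: np.ndarray = field(default_factory=lambda: np.eye(1))
    k_b: float = 1e-3
    theta_b: float = 1e3

    def __post_init__(self) -> None:
        self.mu_phi_sigma = np.atleast_1d(np.asarray(self.mu_phi_sigma, dtype=float))
        self.S = np.asarray(self.S, dtype=float)
        r = self.mu_phi_sigma.shape[0]
        if self.S.shape != (r, r):
            raise DimensionError(f"S must be {r}x{r}, got {self.S.shape}")
        if self.k0 <= 0:
            raise ConfigurationError("k0 must be > 0")
        if self.nu <= r - 1:
            raise ConfigurationError(f"nu must exceed R - 1 = {r - 1}, got {self.nu}")
        if self.k_b <= 0 or self.theta_b <= 0:
            raise ConfigurationError("k_b and theta_b must be > 0")
        try:
            _require_spd(self.S, "prior scale matrix S")
        except NumericalStateError as exc:
            raise ConfigurationError(str(exc)) from exc

    @classmethod
    def default(cls, n_annotators: int) -> "CAMHyperparams":
        return cls(
            mu_phi_sigma=np.zeros(n_annotators),
            k0=1.0,
            nu=n_annotators + 2,
            S=np.eye(n_annotators),
        )


@dataclass
class CAMState:
    """One Gibbs iterate of all CAM latent variables.

    ``y_imputed`` carries the complete label matrix: observed entries copied
    from the data, unobserved entries at their current augmented values.
    """

    z: np.ndarray          # (N,)
    phi: np.ndarray        # (R,)
    Sigma: np.ndarray      # (R, R) SPD
    b: float
    w: np.ndarray          # (d+1,)
    y_imputed: np.ndarray  # (N, R)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.y_imputed = np.asarray(self.y_imputed, dtype=float)
        if self.b <= 0:
            raise ValueError("b must be strictly positive")
        _require_spd(self.Sigma, "Sigma")


@dataclass
class CorrelationDecomposition:
    """Separation Sigma = Q rho Q into scales and correlations.

    Q is diagonal with the per-annotator error standard deviations (the CAM
    reading of 1/sqrt(lambda_j)); rho is the correlation matrix.
    """

    Q: np.ndarray
    rho: np.ndarray


def _check_cam_dims(state: CAMState, data: AnnotationSet) -> None:
    n, r = data.labels.shape
    if state.z.shape != (n,):
        raise DimensionError(f"state.z has shape {state.z.shape}, expected ({n},)")
    if state.phi.shape != (r,):
        raise DimensionError(f"state.phi has shape {state.phi.shape}, expected ({r},)")
    if state.Sigma.shape != (r, r):
        raise DimensionError(f"Sigma has shape {state.Sigma.shape}, expected ({r},{r})")
    if state.y_imputed.shape != (n, r):
        raise DimensionError(
            f"y_imputed has shape {state.y_imputed.shape}, expected ({n},{r})"
        )


def bias_residual_means(
    state: CAMState, data: AnnotationSet, complete: bool = True
) -> np.ndarray:
    """Per-annotator mean label-minus-truth residual ybar_b.

    With ``complete=True`` (the default used by the augmented Gibbs sweep)
    the mean runs over all N rows of the completed label matrix,
    ybar_b,j = (1/N) sum_i (y_ij - z_i), which is the exact sufficient
    statistic for the complete-data conjugate updates.  With
    ``complete=False`` it is restricted to observed entries,
    (1/N_j) sum_{i in U_j}(y_ij - z_i); an annotator with no labels gets 0.
    """
    if complete:
        return (state.y_imputed - state.z[:, None]).mean(axis=0)
    n_j = data.labels_per_annotator
    resid = np.where(data.mask, data.labels - state.z[:, None], 0.0)
    return resid.sum(axis=0) / np.maximum(n_j, 1)


_PHI_MODES = ("conjugate", "as_printed")


def phi_cam_conditional(
    state: CAMState, data: AnnotationSet, hyp: CAMHyperparams, mode: str = "conjugate"
) -> tuple[np.ndarray, np.ndarray]:
    """MVN full-conditional (mean, covariance) for the bias vector phi.

    Covariance is Sigma/(k0 + N).  In ``conjugate`` mode (default) the mean
    is the exact complete-data normal-inverse-Wishart shrinkage
    (k0 mu + N ybar_b)/(k0 + N) with ybar_b over the completed label
    matrix — the correct full conditional once missing labels have been
    imputed (verified by successive-conditional prior-recovery testing).
    ``as_printed`` retains the mixed-denominator observed-count form
    k0 mu/(k0+N) + U ybar_b/(k0+U) for compatibility; it is not an exact
    conditional when counts differ.
    """
    if mode not in _PHI_MODES:
        raise ConfigurationError(
            f"unknown phi update mode {mode!r}; expected one of {_PHI_MODES}"
        )
    _check_cam_dims(state, data)
    n = data.n_samples
    if mode == "conjugate":
        ybar = bias_residual_means(state, data, complete=True)
        mean = (hyp.k0 * hyp.mu_phi_sigma + n * ybar) / (hyp.k0 + n)
    else:
        u = data.labels_per_annotator.astype(float)
        ybar = bias_residual_means(state, data, complete=False)
        mean = hyp.k0 * hyp.mu_phi_sigma / (hyp.k0 + n) + u * ybar / (hyp.k0 + u)
    cov = state.Sigma / (hyp.k0 + n)
    return mean, cov


def sample_phi_cam(
    state: CAMState,
    data: AnnotationSet,
    hyp: CAMHyperparams,
    rng: np.random.Generator,
    mode: str = "conjugate",
) -> np.ndarray:
    """Draw the bias vector from its multivariate-normal full conditional."""
    mean, cov = phi_cam_conditional(state, data, hyp, mode)
    chol = _require_spd(cov, "phi conditional covariance")
    return mean + chol @ rng.standard_normal(mean.shape[0])


def sigma_cam_conditional(
    state: CAMState, data: AnnotationSet, hyp: CAMHyperparams, mode: str = "conjugate"
) -> tuple[float, np.ndarray]:
    """Inverse-Wishart full-conditional (dof nu*, scale S*) for Sigma.

    nu* = nu + N and
    S* = S + sum_i r_i r_i' + k0 N/(k0+N) (ybar_b - mu)(ybar_b - mu)'
    with residual rows r_i = y_i - z_i 1 - ybar_b over the complete
    (observed + imputed) label matrix.  This is the phi-marginalized
    conditional of the normal-inverse-Wishart block; in ``conjugate`` mode
    ybar_b is the complete-data residual mean (the exact conditional under
    augmentation), in ``as_printed`` mode the observed-only per-annotator
    mean.
    """
    if mode not in _PHI_MODES:
        raise ConfigurationError(
            f"unknown sigma update mode {mode!r}; expected one of {_PHI_MODES}"
        )
    _check_cam_dims(state, data)
    n = data.n_samples
    ybar = bias_residual_means(state, data, complete=(mode == "conjugate"))
    resid = state.y_imputed - state.z[:, None] - ybar[None, :]
    dev = ybar - hyp.mu_phi_sigma
    s_star = (
        hyp.S
        + resid.T @ resid
        + (hyp.k0 * n / (hyp.k0 + n)) * np.outer(dev, dev)
    )
    s_star = 0.5 * (s_star + s_star.T)  # enforce exact symmetry
    return hyp.nu + n, s_star


def sample_sigma_cam(
    state: CAMState,
    data: AnnotationSet,
    hyp: CAMHyperparams,
    rng: np.random.Generator,
    mode: str = "conjugate",
) -> np.ndarray:
    """Draw Sigma from its inverse-Wishart full conditional."""
    nu_star, s_star = sigma_cam_conditional(state, data, hyp, mode)
    _require_spd(s_star, "inverse-Wishart scale S*")
    draw = stats.invwishart.rvs(df=nu_star, scale=s_star, random_state=rng)
    draw = np.atleast_2d(draw)
    return 0.5 * (draw + draw.T)


def z_cam_conditional(
    state: CAMState, data: AnnotationSet, X: FeatureMatrix
) -> tuple[np.ndarray, float]:
    """Gaussian full-conditional (mean vector, common precision) for z.

    Derived by conjugacy from the regression prior and the MVN likelihood:
    precision p = b + 1'Sigma^{-1}1 (identical for all samples) and
    mean_i = (b x_i'w + 1'Sigma^{-1}(y_i - phi)) / p using the complete row
    y_i.
    """
    _check_cam_dims(state, data)
    if X.n_samples != data.n_samples:
        raise DimensionError(f"X has {X.n_samples} rows, expected {data.n_samples}")
    chol = _require_spd(state.Sigma, "Sigma")
    ones = np.ones(state.Sigma.shape[0])
    # s = Sigma^{-1} 1 via the Cholesky factor
    s = np.linalg.solve(chol.T, np.linalg.solve(chol, ones))
    prec = state.b + float(ones @ s)
    mean = (state.b * (X.X @ state.w) + (state.y_imputed - state.phi[None, :]) @ s) / prec
    return mean, prec


def sample_z_cam(
    state: CAMState, data: AnnotationSet, X: FeatureMatrix, rng: np.random.Generator
) -> np.ndarray:
    """Draw the latent truth vector from its Gaussian full conditional."""
    mean, prec = z_cam_conditional(state, data, X)
    return rng.normal(mean, 1.0 / np.sqrt(prec))


def impute_missing_labels(
    state: CAMState, data: AnnotationSet, rng: np.random.Generator
) -> np.ndarray:
    """Data augmentation: redraw unobserved labels given the observed ones.

    For each sample the unobserved entries of y_i are drawn from the
    conditional multivariate normal of N(z_i 1 + phi, Sigma) given the
    sample's observed entries; observed entries pass through unchanged.
    Rows sharing a missingness pattern are drawn together.
    """
    _check_cam_dims(state, data)
    _require_spd(state.Sigma, "Sigma")
    out = np.where(data.mask, data.labels, 0.0).astype(float)
    full_mean = state.z[:, None] + state.phi[None, :]

    # group rows by missingness pattern so each conditional is solved once
    patterns, inverse = np.unique(data.mask, axis=0, return_inverse=True)
    for p_idx, obs in enumerate(patterns):
        rows = np.flatnonzero(inverse == p_idx)
        mis = ~obs
        if not mis.any():
            # fully observed rows pass through bitwise
            out[rows] = data.labels[rows]
            continue
        if not obs.any():
            chol = np.linalg.cholesky(state.Sigma)
            eps = rng.standard_normal((rows.size, mis.sum()))
            out[np.ix_(rows, np.flatnonzero(mis))] = full_mean[rows] + eps @ chol.T
            continue
        s_oo = state.Sigma[np.ix_(obs, obs)]
        s_mo = state.Sigma[np.ix_(mis, obs)]
        s_mm = state.Sigma[np.ix_(mis, mis)]
        gain = np.linalg.solve(s_oo, s_mo.T).T           # Sigma_mo Sigma_oo^{-1}
        cond_cov = s_mm - gain @ s_mo.T
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        chol = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(cond_cov.shape[0]))
        y_obs = data.labels[np.ix_(rows, np.flatnonzero(obs))]
        cond_mean = full_mean[np.ix_(rows, np.flatnonzero(mis))] + (
            y_obs - full_mean[np.ix_(rows, np.flatnonzero(obs))]
        ) @ gain.T
        eps = rng.standard_normal(cond_mean.shape)
        out[np.ix_(rows, np.flatnonzero(mis))] = cond_mean + eps @ chol.T
        out[np.ix_(rows, np.flatnonzero(obs))] = y_obs
    return out


def decompose_sigma(Sigma: np.ndarray) -> CorrelationDecomposition:
    """Separate Sigma = Q rho Q into scales Q = diag(sqrt(Sigma_jj)) and rho."""
    Sigma = np.asarray(Sigma, dtype=float)
    diag = np.diag(Sigma)
    if np.any(diag <= 0):
        raise NumericalStateError("covariance has a non-positive diagonal entry")
    sd = np.sqrt(diag)
    rho = Sigma / np.outer(sd, sd)
    np.fill_diagonal(rho, 1.0)
    return CorrelationDecomposition(Q=np.diag(sd), rho=rho)
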
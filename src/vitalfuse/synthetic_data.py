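"""Generators with known ground truth for every other module.

Two families:

* annotator-label datasets drawn exactly from the IAM or CAM generative
  model (Gaussian truth around a linear-regression mean; labels = truth +
  bias + noise, independent or with a full error covariance; MCAR masks),
  so that parameter-recovery failures indict the sampler, not the data;
* PPG-like waveforms: a raised-cosine pulse train whose amplitude, baseline
  and instantaneous frequency are modulated at a known respiratory rate,
  so the RR pipeline can be tested end to end without any recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .iam_model import AnnotationSet, FeatureMatrix

__all__ = ["SimulationTruth", "simulate_iam", "simulate_cam", "simulate_ppg", "PPGRecord"]


@dataclass
class SimulationTruth:
    """Generating parameters stored alongside a simulated dataset."""

    z_true: np.ndarray
    phi_true: np.ndarray
    w_true: np.ndarray
    b_true: float
    mask: np.ndarray
    seed: int
    lambda_true: np.ndarray | None = None
    Sigma_true: np.ndarray | None = None


@dataclass
class PPGRecord:
    """Single-channel PPG waveform with its sampling rate."""

    samples: np.ndarray
    fs_hz: float
    record_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise InputError("fs_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz


def _simulate_common(n, r, d, w_true, b_true, phi_true, missing_rate, rng):
    if not 0 <= missing_rate < 1:
        raise InputError(f"missing_rate must lie in [0, 1), got {missing_rate}")
    if n < 1 or r < 1 or d < 0:
        raise InputError(f"invalid dimensions N={n}, R={r}, d={d}")
    w_true = np.atleast_1d(np.asarray(w_true, dtype=float))
    phi_true = np.atleast_1d(np.asarray(phi_true, dtype=float))
    if w_true.shape != (d + 1,):
        raise InputError(f"w_true must have length d+1={d + 1}, got {w_true.shape}")
    if phi_true.shape != (r,):
        raise InputError(f"phi_true must have length R={r}, got {phi_true.shape}")
    if b_true <= 0:
        raise InputError("b_true must be positive")
    features = rng.standard_normal((n, d)) if d > 0 else None
    X = FeatureMatrix.from_features(features, n)
    z = rng.normal(X.X @ w_true, 1.0 / np.sqrt(b_true))
    # MCAR mask; rows left with no observed label are resampled
    mask = rng.random((n, r)) >= missing_rate
    while True:
        empty = ~mask.any(axis=1)
        if not empty.any():
            break
        mask[empty] = rng.random((int(empty.sum()), r)) >= missing_rate
    return X, z, mask, w_true, phi_true


def simulate_iam(
    N: int,
    R: int,
    d: int = 0,
    w_true=(15.0,),
    b_true: float = 1.0,
    phi_true=None,
    lambda_true=None,
    missing_rate: float = 0.2,
    seed: int = 0,
) -> tuple[AnnotationSet, FeatureMatrix, SimulationTruth]:
    """Simulate labels from the independent-annotator generative model.

    y_ij = z_i + phi_j + eps_ij with eps_ij ~ N(0, 1/lambda_j), z_i drawn
    around the regression mean x_i'w_true with precision b_true, and an
    MCAR mask at the given missing rate (every sample keeps >= 1 label).
    """
    rng = np.random.default_rng(seed)
    if phi_true is None:
        phi_true = np.linspace(-2.0, 2.0, R)
    if lambda_true is None:
        lambda_true = np.linspace(0.5, 4.0, R)
    lambda_true = np.atleast_1d(np.asarray(lambda_true, dtype=float))
    if lambda_true.shape != (R,) or np.any(lambda_true <= 0):
        raise InputError("lambda_true must be R positive precisions")
    X, z, mask, w_true, phi_true = _simulate_common(
        N, R, d, w_true, b_true, phi_true, missing_rate, rng
    )
    noise = rng.standard_normal((N, R)) / np.sqrt(lambda_true)[None, :]
    labels = z[:, None] + phi_true[None, :] + noise
    labels = np.where(mask, labels, np.nan)
    data = AnnotationSet(labels=labels, mask=mask)
    truth = SimulationTruth(
        z_true=z, phi_true=phi_true, w_true=w_true, b_true=b_true,
        mask=mask, seed=seed, lambda_true=lambda_true,
    )
    return data, X, truth


def simulate_cam(
    N: int,
    R: int,
    d: int = 0,
    w_true=(15.0,),
    b_true: float = 1.0,
    phi_true=None,
    Sigma_true=None,
    missing_rate: float = 0.2,
    seed: int = 0,
) -> tuple[AnnotationSet, FeatureMatrix, SimulationTruth]:
    """Simulate labels with a full annotator error covariance.

    Error rows are drawn jointly from N(0, Sigma_true), so annotator noise
    can be correlated; otherwise identical to :func:`simulate_iam`.
    """
    rng = np.random.default_rng(seed)
    if phi_true is None:
        phi_true = np.linspace(-2.0, 2.0, R)
    if Sigma_true is None:
        Sigma_true = np.eye(R)
    Sigma_true = np.asarray(Sigma_true, dtype=float)
    if Sigma_true.shape != (R, R):
        raise InputError(f"Sigma_true must be {R}x{R}, got {Sigma_true.shape}")
    try:
        chol = np.linalg.cholesky(0.5 * (Sigma_true + Sigma_true.T))
    except np.linalg.LinAlgError as exc:
        raise InputError("Sigma_true must be symmetric positive definite") from exc
    X, z, mask, w_true, phi_true = _simulate_common(
        N, R, d, w_true, b_true, phi_true, missing_rate, rng
    )
    errors = rng.standard_normal((N, R)) @ chol.T
    labels = z[:, None] + phi_true[None, :] + errors
    labels = np.where(mask, labels, np.nan)
    data = AnnotationSet(labels=labels, mask=mask)
    truth = SimulationTruth(
        z_true=z, phi_true=phi_true, w_true=w_true, b_true=b_true,
        mask=mask, seed=seed, Sigma_true=Sigma_true,
    )
    return data, X, truth


def simulate_ppg(
    duration_s: float = 480.0,
    fs_hz: float = 125.0,
    heart_rate_bpm: float = 80.0,
    rr_bpm: float = 15.0,
    am_depth: float = 0.15,
    bw_depth: float = 0.15,
    fm_depth: float = 0.05,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[PPGRecord, float]:
    """Synthetic PPG: raised-cosine pulse train with respiratory modulation.

    The pulse shape is ((1 - cos(theta))/2)^3 over the beat phase theta; the
    respiratory rate imprints itself as multiplicative amplitude modulation
    (depth ``am_depth``), an additive baseline oscillation (``bw_depth``),
    and modulation of the instantaneous beat frequency (``fm_depth``), all
    at rr_bpm/60 Hz, plus white measurement noise.  Returns the record and
    the (constant) true RR in breaths/min.
    """
    if not 4 <= rr_bpm <= 60:
        raise InputError(f"rr_bpm must lie in [4, 60], got {rr_bpm}")
    if heart_rate_bpm <= 2 * rr_bpm:
        raise InputError("heart_rate_bpm must exceed twice rr_bpm")
    if fs_hz < 25:
        raise InputError("fs_hz must be >= 25")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    f_resp = rr_bpm / 60.0
    resp = np.sin(2 * np.pi * f_resp * t)
    # instantaneous heart frequency, integrated to a beat phase
    f_heart = (heart_rate_bpm / 60.0) * (1.0 + fm_depth * resp)
    phase = 2 * np.pi * np.cumsum(f_heart) / fs_hz
    pulse = ((1.0 - np.cos(phase)) / 2.0) ** 3
    waveform = (
        (1.0 + am_depth * resp) * pulse
        + bw_depth * resp
        + noise_sd * rng.standard_normal(n)
    )
    return PPGRecord(samples=waveform, fs_hz=fs_hz), float(rr_bpm)
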
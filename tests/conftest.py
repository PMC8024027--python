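import numpy as np
import pytest

from vitalfuse.iam_model import AnnotationSet, FeatureMatrix, IAMHyperparams, IAMState


@pytest.fixture
def tiny_instance():
    """Fixed N=4, R=2 instance used by the conditional grid-oracle checks."""
    labels = np.array(
        [
            [14.0, 15.5],
            [12.0, np.nan],
            [np.nan, 16.5],
            [13.0, 14.0],
        ]
    )
    mask = ~np.isnan(labels)
    data = AnnotationSet(labels=labels, mask=mask)
    X = FeatureMatrix.from_features(None, 4)
    state = IAMState(
        z=np.array([14.5, 12.5, 15.5, 13.5]),
        phi=np.array([-0.5, 0.8]),
        lam=np.array([2.0, 1.5]),
        b=0.7,
        alpha_phi=1.2,
        w=np.array([14.0]),
    )
    hyp = IAMHyperparams(
        mu_phi=0.0, k_lambda=2.0, theta_lambda=0.5,
        k_alpha=1.5, theta_alpha=1.0, k_b=1.0, theta_b=2.0,
    )
    return data, X, state, hyp


def grid_normalize(log_density, grid):
    """Normalize an unnormalized log-density evaluated on a uniform grid."""
    log_density = log_density - log_density.max()
    dens = np.exp(log_density)
    dens /= np.trapezoid(dens, grid)
    return dens
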
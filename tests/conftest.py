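import numpy as np
import pytest

from scdpaf.survey import SurveyDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20150945)


def srs_design(n: int, weights=None) -> SurveyDesign:
    """Degenerate design: one stratum, one PSU per respondent (classical SRS)."""
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    return SurveyDesign(np.zeros(n, dtype=int), np.arange(n), w)


@pytest.fixture
def make_srs_design():
    return srs_design


def bivariate_binary_sample(rng, n, rho, px, py):
    """Latent-normal dichotomized pair with known tetrachoric correlation."""
    L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
    z = rng.standard_normal((n, 2)) @ L.T
    from scipy.stats import norm

    x = (z[:, 0] > norm.ppf(1 - px)).astype(float)
    y = (z[:, 1] > norm.ppf(1 - py)).astype(float)
    return x, y
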
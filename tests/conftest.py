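import numpy as np
import pandas as pd
import pytest

from nfpredict import neurophys
from nfpredict.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The trial-sized cohort: 24 EEG + 23 fNIRS participants, seed 42."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def hrf10():
    return neurophys.two_gamma_hrf(fs=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_gaussian_design(n=200, coefs=(0.5, -0.3, 0.0), sigma=1.0, seed=0):
    """Linear-model test data with z-scored columns; returns (design, spec
    terms, generating coefficients on the standardized scale)."""
    from nfpredict.bayes import standardize

    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(coefs)))
    y = X @ np.asarray(coefs) + rng.normal(0, sigma, n)
    names = [f"x{i+1}" for i in range(len(coefs))]
    tab = pd.DataFrame(X, columns=names)
    tab["y"] = y
    roles = {"y": "metric", **{c: "metric" for c in names}}
    return standardize(tab, roles), names
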
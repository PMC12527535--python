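import numpy as np
import pandas as pd
import pytest

from causalmeta import (
    AnalysisSpec,
    ExternalCovariates,
    MultiSourceDataset,
    SyntheticDGP,
    generate,
)


@pytest.fixture(scope="session")
def small_dgp():
    """Three sources, five-subgroup effect modifier, three covariates."""
    return SyntheticDGP(sizes=(600, 400, 300), n_external=800, p=3)


@pytest.fixture(scope="session")
def small_study(small_dgp):
    data, external, po = generate(small_dgp, seed=7)
    return data, external, po


@pytest.fixture()
def tiny_data():
    """A hand-built, well-formed 3-source dataset with 12 rows."""
    rng = np.random.default_rng(0)
    n = 12
    return MultiSourceDataset(
        Y=rng.normal(size=n),
        S=np.repeat(["A", "B", "C"], 4),
        A=np.tile([0, 1], 6),
        X=pd.DataFrame({"x1": rng.normal(size=n),
                        "x2": np.tile(["u", "v"], 6)}),
        EM=np.tile(["g1", "g2"], 6),
    )


@pytest.fixture()
def default_spec():
    return AnalysisSpec()


def make_discrete_data(seed=0, n=400, n_ext=120):
    """Discrete study: one binary covariate, two sources, binary treatment.

    Used by the exhaustive-enumeration oracle tests; every stratum
    (x, s, a) is guaranteed non-empty.
    """
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n)
    s = np.where(rng.uniform(size=n) < 0.4 + 0.2 * x, "s1", "s2")
    p_a = 0.3 + 0.3 * x + 0.1 * (s == "s1")
    a = (rng.uniform(size=n) < p_a).astype(int)
    y = 1.0 + 2.0 * x + 1.5 * a + 0.5 * a * x + rng.normal(size=n)
    data = MultiSourceDataset(Y=y, S=s, A=a, X=pd.DataFrame({"x": x.astype(float)}))
    x_ext = rng.integers(0, 2, size=n_ext)
    external = ExternalCovariates(X=pd.DataFrame({"x": x_ext.astype(float)}))
    return data, external
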
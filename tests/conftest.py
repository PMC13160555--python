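import numpy as np
import pytest

from regimeshift import PopulationSpec, parameter_recovery


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def recovery_hom():
    """Full-design homoscedastic parameter recovery (30 subjects, 11
    blocks, all five noise levels); shared across tests for speed."""
    return parameter_recovery(PopulationSpec(), seed=0)


@pytest.fixture(scope="session")
def recovery_het(recovery_hom):
    """Heteroscedastic companion run: the binned-SD profile rescaled to
    each noise level's mean sigma, same seed as the homoscedastic run."""
    return parameter_recovery(PopulationSpec(), seed=0, heteroscedastic=True)


def _meng_z_vectorized(r1, r2, rx, N):
    """Vectorized, independently coded evaluation of the
    dependent-correlation z statistic (used as an oracle)."""
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    r2bar = (r1**2 + r2**2) / 2.0
    f = np.minimum((1.0 - rx) / (2.0 * (1.0 - r2bar)), 1.0)
    h = 1.0 + r2bar / (1.0 - r2bar) * (1.0 - f)
    return (z1 - z2) * np.sqrt((N - 3) / (2.0 * (1.0 - rx) * h))


@pytest.fixture(scope="session")
def meng_null_cohorts():
    """10^4 simulated N=30 cohorts under the null of equal dependent
    correlations, with their (r1, r2, rx) triples and oracle z values."""
    rng = np.random.default_rng(12345)
    N, n_sim = 30, 10_000
    # x correlates 0.4 with both y1 and y2; corr(y1, y2) = 0.5
    cov = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.5], [0.4, 0.5, 1.0]])
    L = np.linalg.cholesky(cov)
    data = rng.standard_normal((n_sim, N, 3)) @ L.T
    xc = data - data.mean(axis=1, keepdims=True)
    ss = np.sqrt((xc**2).sum(axis=1))

    def corr(i, j):
        return (xc[:, :, i] * xc[:, :, j]).sum(axis=1) / (ss[:, i] * ss[:, j])

    r1, r2, rx = corr(0, 1), corr(0, 2), corr(1, 2)
    z = _meng_z_vectorized(r1, r2, rx, N)
    return {"r1": r1, "r2": r2, "rx": rx, "N": N, "z_oracle": z}
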
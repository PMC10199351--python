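import numpy as np
import pytest

from riskmag.cohort import CohortConfig, TruthParameters, simulate_cohort
from riskmag.coxnet import PenaltySpec
from riskmag.modified import fit_modified_model


def two_arm_exponential(n, rate, hr, seed, censor=(3.5, 5.88), p_treat=0.5):
    """Minimal two-arm exponential trial: returns (times, events, intensive)."""
    rng = np.random.default_rng(seed)
    z = rng.random(n) < p_treat
    lam = rate * np.where(z, hr, 1.0)
    t_event = rng.exponential(1.0 / lam)
    c = rng.uniform(*censor, size=n)
    return np.minimum(t_event, c), (t_event <= c).astype(int), z


def efron_loglik_reference(beta, X, times, events):
    """Brute-force Efron log partial likelihood (independent test oracle)."""
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        D = np.flatnonzero((times == t) & (events == 1))
        R = np.flatnonzero(times >= t)
        d = len(D)
        sD = np.exp(eta[D]).sum()
        sR = np.exp(eta[R]).sum()
        ll += eta[D].sum()
        for l in range(d):
            ll -= np.log(sR - (l / d) * sD)
    return ll


@pytest.fixture(scope="session")
def default_truth():
    return TruthParameters()


@pytest.fixture(scope="session")
def midsize_cohort(default_truth):
    """4000-subject cohort under the default constant-HR truth."""
    return simulate_cohort(CohortConfig(n_subjects=4000, seed=11), default_truth)


@pytest.fixture(scope="session")
def midsize_fit(midsize_cohort):
    return fit_modified_model(
        midsize_cohort, "full", "pd_amci", penalty=PenaltySpec(alpha=0.5, lam=0.01)
    )
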
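import numpy as np
import pytest

from noctograph.fingerprint import N_BINS, RelativeProfile
from noctograph.ingest import localize
from noctograph.fingerprint import compute_fingerprint
from noctograph.model import UnifiedModel, flat_height, reference_model
from noctograph.synthetic import SyntheticSpec, simulate_cohort


def random_valid_model(rng: np.random.Generator) -> UnifiedModel:
    """Sample a valid model: upward parabola with interior minimum, d >= 0.

    Parametrized via vertex location and nonnegative nadir value so the
    section is nonnegative by construction; resampled until the implied
    flat height is nonnegative.
    """
    while True:
        S = 0.25 * rng.integers(0, 25)
        E = 0.25 * rng.integers(1, 48)
        k = int(round((S + E) / 0.25)) + 1
        if k < 3 or k >= 96:
            continue
        a = rng.uniform(1e-4, 1.2e-3)
        xv = rng.uniform(-S, E)
        m0 = rng.uniform(0.0, 5e-3)
        b = -2.0 * a * xv
        c = m0 + a * xv * xv
        d = flat_height(S, E, a, b, c)
        if d < 0:
            continue
        return UnifiedModel(S=S, E=E, a=a, b=b, c=c, d=d)


def cohort_labeled(n_users, posts_per_user, seed, noise=0.0):
    """Simulate a cohort and return (fingerprint, true bedtime) pairs."""
    spec = SyntheticSpec(n_users=n_users, posts_per_user=posts_per_user,
                         seed=seed, noise=noise)
    out = []
    for u in simulate_cohort(spec):
        lp = localize(u.epochs, u.tz_name, u.author_id)
        out.append((u.author_id, compute_fingerprint(lp), u.true_bedtime))
    return out


@pytest.fixture(scope="session")
def ref_model():
    return reference_model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231114)


@pytest.fixture(scope="session")
def small_cohort():
    """30 users x 500 posts: enough signal for pipeline-level checks."""
    return cohort_labeled(30, 500, seed=3)


def random_profile(rng: np.random.Generator) -> RelativeProfile:
    """A realistic noisy profile: model curve blended with Dirichlet noise."""
    m = random_valid_model(rng)
    from noctograph.model import eval_model

    vals = eval_model(m)
    w = rng.uniform(0.0, 0.3)
    vals = (1 - w) * vals + w * rng.dirichlet(np.ones(N_BINS))
    return RelativeProfile(values=vals / vals.sum())
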
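import numpy as np
import pytest

from forage import GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def tuned_session():
    """Small distance-tuned session used by decoder/geometry tests."""
    cfg = GeneratorConfig(n_units=12, n_trials=14, duration=600.0, seed=1)
    session, gt = generate_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def event_session():
    """Balanced-outcome session with planted AW-selective units."""
    cfg = GeneratorConfig(
        n_units=12,
        n_trials=30,
        duration=900.0,
        seed=2,
        aw_probability=0.5,
        balanced_outcomes=True,
    )
    session, gt = generate_session(cfg)
    return session, gt


@pytest.fixture(scope="session")
def tuned_dataset(tuned_session):
    from forage import build_distance_dataset

    session, _ = tuned_session
    return build_distance_dataset(session)


def two_template_population(n_units, noise_sd, rng):
    """Planted clustering problem: two orthogonal 80-bin response motifs."""
    t = np.linspace(-2, 2, 80)
    templates = np.vstack(
        [np.exp(-((t + 0.5) ** 2) / 0.08), -np.exp(-((t - 0.5) ** 2) / 0.18)]
    )
    truth = rng.integers(0, 2, size=n_units)
    V = templates[truth] * 2.0 + rng.normal(0, noise_sd, size=(n_units, 80))
    return V, truth
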
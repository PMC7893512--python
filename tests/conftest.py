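import numpy as np
import pandas as pd
import pytest

from paikit.synthetic_trial import GeneratorConfig, generate


@pytest.fixture(scope="session")
def default_trial():
    """Default study conditions: n=151, 38 covariates, 1 planted predictor
    + 2 planted moderators, missingness injected."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def complete_trial():
    """Same structure with no missingness and no visit noise (clean AUC)."""
    cfg = GeneratorConfig(
        seed=42,
        missing_rate_covariates=0.0,
        missing_rate_outcomes=0.0,
        visit_noise_sd=0.0,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def null_trial():
    """No planted effects at all: outcome unrelated to covariates and arm."""
    cfg = GeneratorConfig(
        seed=99,
        true_predictor_ids=(),
        predictor_effect_sizes=(),
        true_moderator_ids=(),
        moderator_effect_sizes=(),
        baseline_effect=0.0,
        missing_rate_covariates=0.0,
        missing_rate_outcomes=0.0,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def small_regression(rng):
    """Tiny two-arm regression fixture used by oracle tests."""
    n = 12
    arm = np.array([0, 1] * (n // 2), dtype=float)
    x = pd.DataFrame(
        {
            "a": rng.normal(size=n),
            "b": rng.poisson(1.5, size=n).astype(float),
        }
    )
    y = 2.0 + 1.5 * x["a"].to_numpy() - 0.8 * x["b"].to_numpy() * arm + rng.normal(
        0, 0.5, n
    )
    return x, y, arm
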
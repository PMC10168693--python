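import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metacontrast as mc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("metacontrast").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_corpus():
    """Six-comparison synthetic corpus with the default design bias."""
    comps, truth = mc.simulate_corpus(mc.SimConfig(n_comparisons=6, seed=42))
    return comps, truth


@pytest.fixture
def arm_pair():
    treat = mc.ArmSummary(mean=1.0, dispersion=1.0, n=12)
    control = mc.ArmSummary(mean=0.2, dispersion=1.1, n=10)
    return treat, control


def random_estimates(rng, k):
    """Random EffectEstimate-like inputs for pooling tests."""
    pts = rng.normal(0, 1, size=k)
    vs = rng.uniform(0.02, 0.5, size=k)
    return [
        mc.EffectEstimate(
            point=float(p), variance=float(v),
            ci_low=float(p - 1.96 * np.sqrt(v)),
            ci_high=float(p + 1.96 * np.sqrt(v)),
            metric=mc.Metric.g, n_treat=10, n_control=10,
        )
        for p, v in zip(pts, vs)
    ]
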
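import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hitsurv import SimulationConfig, SurvivalModel

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def xray_model() -> SurvivalModel:
    """Reference two-hit model for low-LET x-rays: z_F=1 Gy, s1=1, s2=0.35.

    Two sublethal hits are fully/partially survivable, a third is lethal;
    gives the classic shouldered curve turning into a straight line.
    """
    return SurvivalModel(z_f=1.0, s=(1.0, 0.35))


@pytest.fixture
def dose_grid() -> np.ndarray:
    return np.arange(1.0, 14.1, 1.0)


@pytest.fixture
def mc_config() -> SimulationConfig:
    return SimulationConfig(n_samples=10 ** 6, seed=20260928)


def random_valid_models(rng: np.random.Generator, n: int) -> list[SurvivalModel]:
    """Random truncated models with s2 <= s1^2 (physically valid)."""
    models = []
    while len(models) < n:
        z_f = float(rng.uniform(0.3, 3.0))
        k = int(rng.integers(1, 4))
        s = []
        for i in range(k):
            hi = 1.0 if i == 0 else min(s[0] ** 2, s[i - 1]) if i == 1 else s[i - 1]
            s.append(float(rng.uniform(0, hi)))
        models.append(SurvivalModel(z_f=z_f, s=tuple(s)))
    return models
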
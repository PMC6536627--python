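import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """Shared 400-transcript simulation with planted templates."""
    from stresspattern import SimulationConfig, simulate_expression

    cfg = SimulationConfig(n_transcripts=400, seed=11)
    matrix, samples, truth = simulate_expression(cfg)
    return cfg, matrix, samples, truth


@pytest.fixture(scope="session")
def small_calls(small_dataset):
    from stresspattern import call_stress_transcripts

    _, matrix, samples, _ = small_dataset
    return call_stress_transcripts(matrix, samples)


def make_calls_frame(entries):
    """Build a minimal passing-calls frame from (transcript, strain, direction)."""
    return pd.DataFrame(
        [
            {
                "transcript": t,
                "strain": s,
                "direction": d,
                "passes": True,
            }
            for t, s, d in entries
        ]
    )


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test (independent of scipy)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p
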
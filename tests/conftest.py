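import numpy as np
import pytest

from hiberphys import classify, simulate, trace


@pytest.fixture
def params():
    return classify.ClassifierParams()


@pytest.fixture
def torpor_week():
    """One week of nightly activity plus a 300-min daily torpor bout."""
    cfg = simulate.ScenarioConfig(
        seed=42, n_weeks=1,
        torpor_schedule=tuple((d, 480.0, 300.0, 5.0) for d in range(7)),
    )
    nest, ambient, truth = simulate.simulate_prehibernation_trace(cfg)
    aligned = trace.align_ambient(ambient, nest.timestamps)
    return cfg, nest, aligned, truth


def square_wave_traces(days=3, elevation=6.0, ambient_c=20.0,
                       outside_start=720, outside_len=720):
    """Noise-free square-wave nest trace: half the day in nest, half outside."""
    n = days * 1440
    t = np.arange(n, dtype=float)
    minute = t % 1440
    outside = (minute >= outside_start) & (minute < outside_start + outside_len)
    nest_vals = np.where(outside, ambient_c, ambient_c + elevation)
    nest = trace.TemperatureTrace(t, nest_vals, source="nest")
    amb = trace.TemperatureTrace(t, np.full(n, ambient_c), source="ambient")
    return nest, amb, outside
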
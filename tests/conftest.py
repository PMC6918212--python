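import numpy as np
import pytest

from wristacc.signal import AccelStream, PipelineConfig


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def causal_cfg() -> PipelineConfig:
    return PipelineConfig(zero_phase=False)


def make_stream(x, rate=50.0, y=None, z=None) -> AccelStream:
    x = np.asarray(x, dtype=float)
    return AccelStream(
        ax=x,
        ay=np.zeros_like(x) if y is None else np.asarray(y, float),
        az=np.zeros_like(x) if z is None else np.asarray(z, float),
        rate=rate,
    )
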
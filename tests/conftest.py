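import numpy as np
import pytest

from cardiotrace import DeviceSpec, EventStream

# canonical tiny stream used by the committed fixture files
MINI_T_MS = [0, 8, 16, 24, 32]
MINI_DY = [3, -1, 2, 0, -4]
MINI_CREATED_UTC = "2023-03-17T00:00:00+00:00"


def make_mini_stream() -> EventStream:
    n = len(MINI_T_MS)
    return EventStream(
        device=DeviceSpec(dpi=1600, pinned_axis="y", sample_interval_ms=8.0),
        t_ms=np.array(MINI_T_MS, dtype=np.int64),
        dx=np.zeros(n, dtype=np.int64),
        dy=np.array(MINI_DY, dtype=np.int64),
    )


def make_random_stream(rng: np.random.Generator, n: int = 100,
                       device: DeviceSpec | None = None) -> EventStream:
    if device is None:
        device = DeviceSpec()
    t_ms = np.cumsum(rng.integers(1, 20, size=n))
    return EventStream(
        device=device,
        t_ms=t_ms.astype(np.int64),
        dx=rng.integers(-50, 51, size=n).astype(np.int64),
        dy=rng.integers(-50, 51, size=n).astype(np.int64),
    )


@pytest.fixture
def device() -> DeviceSpec:
    return DeviceSpec()


@pytest.fixture
def mini_stream() -> EventStream:
    return make_mini_stream()
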
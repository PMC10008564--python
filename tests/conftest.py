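import numpy as np
import pytest

from inteinctrl import (
    PRESET_IDS,
    RegulatedNetwork,
    build_preset,
    build_regulated,
)

#: circuits realized with transcription factors (the experimentally built set)
TF_CIRCUITS = ("zf", "intradd", "tetr", "gal4", "inactive_intein")


@pytest.fixture(scope="session")
def presets():
    """Default-parameter networks for every built-in circuit."""
    return {pid: build_preset(pid).network for pid in PRESET_IDS}


@pytest.fixture(scope="session")
def plant1():
    """Single-stage plant: the actuated output itself is the regulated species."""
    return build_regulated(1)


@pytest.fixture(scope="session")
def plant2():
    """Two-stage plant with a fast conversion stage and unit dc gain."""
    return RegulatedNetwork(L=2, k=(10.0,), gamma=(0.0, 1.0))
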
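import numpy as np
import pytest

from consafety import datasets


@pytest.fixture(scope="session")
def deaths_series() -> np.ndarray:
    """The bundled 10-year annual deaths series as a float array."""
    return datasets.load_deaths_series().to_numpy(float)


@pytest.fixture(scope="session")
def panel():
    """The bundled 31-region province panel."""
    return datasets.load_province_panel()


@pytest.fixture(scope="session")
def severe_records():
    """The seven severe accidents of the study decade."""
    return datasets.load_severe_accidents()
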
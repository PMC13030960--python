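import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

JASPAR_TWO_RECORDS = """\
>MA0001.1 ALPHA
A [ 9  0  0  9 ]
C [ 0  9  0  0 ]
G [ 0  0  9  0 ]
T [ 0  0  0  0 ]
>MA0002.1 BETA
A [ 1  8  0 ]
C [ 7  0  1 ]
G [ 0  1  8 ]
T [ 1  0  0 ]
"""


@pytest.fixture
def jaspar_file(tmp_path):
    path = tmp_path / "matrices.jaspar"
    path.write_text(JASPAR_TWO_RECORDS)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)
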
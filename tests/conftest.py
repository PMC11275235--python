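import numpy as np
import pytest

from hrvrel import RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240835)


@pytest.fixture
def rr_file(tmp_path):
    """Factory writing an R-R text file and returning its path."""

    def _write(lines, name="rr.txt"):
        p = tmp_path / name
        p.write_text("\n".join(str(x) for x in lines) + "\n")
        return p

    return _write


@pytest.fixture
def clean_series(rng):
    """A realistic artefact-free resting series (~5 min, ~700 ms mean)."""
    iv = 700.0 + 30.0 * np.sin(2 * np.pi * 0.1 * np.arange(430) * 0.7) + rng.normal(0, 8, 430)
    return RRSeries(iv, label="clean")
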
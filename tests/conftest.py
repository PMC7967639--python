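import numpy as np
import pytest

from pahrisk.profiles import CongenerProfile
from pahrisk.registry import CONGENERS


@pytest.fixture
def make_profile():
    """Factory: profile with given concentrations, zeros elsewhere."""

    def _make(conc=None, mdl=0.1, **kwargs):
        full = {c: 0.0 for c in CONGENERS}
        full.update(conc or {})
        return CongenerProfile(
            sample_id=kwargs.pop("sample_id", "s1"),
            conc=full, mdl={c: mdl for c in CONGENERS}, **kwargs)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
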
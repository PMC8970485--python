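"""Shared fixtures: reference monoculture parameter triples and small helpers."""

import numpy as np
import pytest

# Monoculture (K, r, tau, duration_h) triples at the small and large droplet
# sizes, used for round-trip identifiability checks of the fitter.
MONO_55UM = (73.0, 0.79, 1.3, 24.0)
MONO_150UM = (598.9, 0.63, 3.1, 48.0)


@pytest.fixture
def ten_minute_grid():
    """Time grid factory matching the plate-reader cadence (10-min reads)."""

    def make(duration_h: float) -> np.ndarray:
        return np.arange(0.0, duration_h + 1.0 / 12.0, 1.0 / 6.0)

    return make
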
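"""Shared fixtures: expensive model sweeps computed once per session."""

import pytest

from paedyn import (
    DEFAULT_MOTIF_PARAMS,
    DEFAULT_PARAMS,
    efflux_sensitivity,
    make_motif,
    run_exposure_collapse,
)
from paedyn.motifs import MOTIF_KINDS


@pytest.fixture(scope="session")
def default_sweep():
    """The reference 6 x 4 concentration-by-duration rectangular sweep."""
    return run_exposure_collapse(DEFAULT_PARAMS)


@pytest.fixture(scope="session")
def motif_sensitivities():
    """Efflux-inhibition sensitivity of the three motifs on the default grid."""
    return {
        kind: efflux_sensitivity(make_motif(kind, DEFAULT_MOTIF_PARAMS))
        for kind in MOTIF_KINDS
    }
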
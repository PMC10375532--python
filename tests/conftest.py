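import numpy as np
import pytest

from acylseq import LibraryDesign, make_truth, simulate_selection_reads


@pytest.fixture(scope="session")
def stem_design():
    """Three randomized stem positions flanked by fixed stem/overhang sequence."""
    return LibraryDesign("GAUUC", 3, "UUCCA", name="stem3")


@pytest.fixture(scope="session")
def overhang_design():
    """Fully randomized five-base 3'-overhang downstream of a fixed flank."""
    return LibraryDesign("UCGCU", 5, "", name="overhang5")


@pytest.fixture(scope="session")
def small_screen(stem_design):
    """A modest simulated screen (k=3, depth 2e4) reused across tests."""
    truth = make_truth(3, bias_sd=0.5, seed=11)
    sel, blank = simulate_selection_reads(truth, stem_design, depth=20_000,
                                          error_rate=0.0, seed=12)
    return truth, sel, blank
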
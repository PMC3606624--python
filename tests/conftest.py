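import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20130316)


@pytest.fixture
def toy_alignment():
    """Four-column toy alignment used across fixed-difference tests."""
    from barcodeflora.specimen_io import AlignmentSet

    return AlignmentSet(
        marker="COI-5P",
        records={
            "atl1": "AATA",
            "atl2": "AATA",
            "pac1": "AACA",
            "pac2": "AACA",
            "chu1": "AATA",
        },
        length=4,
    )
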
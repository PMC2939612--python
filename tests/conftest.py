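import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dnlscreen import Peak, Spectrum


@pytest.fixture
def worked_example() -> Spectrum:
    """Five-peak spectrum whose scan can be stepped through by hand.

    Sorted abundances [10, 12, 14, 16, 100]: the four low peaks lie on
    the line 2i + 8, so every noise prediction is exact, and the 100
    peak is the only one whose SNR (100/18) clears the default
    threshold of 2.
    """
    return Spectrum(
        identifier="worked",
        precursor_mz=500.25,
        precursor_charge=[2],
        peaks=[
            Peak(300.0, 100.0),
            Peak(150.0, 10.0),
            Peak(450.0, 14.0),
            Peak(250.0, 12.0),
            Peak(500.0, 16.0),
        ],
    )


@pytest.fixture
def mgf_text() -> str:
    return (
        "BEGIN IONS\n"
        "TITLE=s1\n"
        "PEPMASS=500.2 12345.6\n"
        "CHARGE=2+\n"
        "RTINSECONDS=83.2\n"
        "100.5 10\n"
        "200.25 20.5\n"
        "300.75 5\n"
        "END IONS\n"
        "\n"
        "BEGIN IONS\n"
        "PEPMASS=612.3\n"
        "CHARGE=2+ and 3+\n"
        "150.1 7.25\n"
        "END IONS\n"
    )
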
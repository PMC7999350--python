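import numpy as np
import pytest

from phenoleaf import (
    CO2Level,
    LightRegime,
    TreatmentLabel,
    Variety,
    render_section,
)


def make_section(pixels, meta=None):
    """RgbSection from a raw (H, W, 3) array."""
    from phenoleaf import RgbSection

    return RgbSection(pixels=np.asarray(pixels, dtype=np.uint8), meta=meta)


@pytest.fixture(scope="session")
def hl_section():
    """One rendered high-light low-CO2 section at default noise."""
    label = TreatmentLabel(Variety.BARKE, CO2Level.LC, LightRegime.HL, 1, 1)
    return render_section(label, seed=42)


@pytest.fixture(scope="session")
def ll_section():
    """One rendered low-light ambient-CO2 section (deep-accumulation pattern)."""
    label = TreatmentLabel(Variety.BOJOS, CO2Level.AC, LightRegime.LL, 1, 1)
    return render_section(label, seed=7)
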
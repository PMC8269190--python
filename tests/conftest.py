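import numpy as np
import pandas as pd
import pytest

from caslice.io import CellGeometry, PacingProtocol, Recording


@pytest.fixture
def protocol_1hz():
    return PacingProtocol(stimulus_times=(1.0, 2.0, 3.0), rate_hz=1.0)


@pytest.fixture
def small_recording(protocol_1hz):
    """3 cells x 401 frames at 10 ms with clean 1 Hz transients."""
    times = np.arange(401) * 0.01
    fluor = np.full((3, 401), 100.0)
    for s in protocol_1hz.stimulus_times:
        mask = times >= s
        tt = times[mask] - s
        bump = 100.0 * (np.exp(-tt / 0.25) - np.exp(-tt / 0.02))
        for i in range(3):
            fluor[i, mask] += (1.0 + 0.2 * i) * bump / bump.max()
    return Recording(
        cells=["a", "b", "c"], times=times, fluor=fluor, protocol=protocol_1hz
    )


@pytest.fixture
def grid_geometry():
    rows = []
    for r in range(2):
        for c in range(2):
            rows.append(
                {"cell": f"g{r}{c}", "x_um": 20.0 * c, "y_um": 20.0 * r,
                 "row": r, "col": c, "diameter_um": 20.0}
            )
    return CellGeometry(table=pd.DataFrame(rows).set_index("cell"))
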
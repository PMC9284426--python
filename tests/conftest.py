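import numpy as np
import pytest

from copiiscreen.plate import PlateLayout, SpotAssignment


def grid_layout(
    n_rows: int = 8,
    n_cols: int = 10,
    chamber_id: str = "T1",
    background: str = "control",
    control_cycle=None,
) -> PlateLayout:
    """A small fully-populated test chamber with interleaved controls."""
    if control_cycle is None:
        control_cycle = [
            ("Scramble", None, "negative"),
            ("si_COPB1", "COPB1", "positive"),
            ("si_INCENP", "INCENP", "transfection_qc"),
        ]
    spots = []
    ci = 0
    for i in range(n_rows * n_cols):
        r, c = divmod(i, n_cols)
        if i % 7 == 3:
            sirna, gene, role = control_cycle[ci % len(control_cycle)]
            ci += 1
        else:
            sirna, gene, role = f"si{i:03d}", f"G{i:03d}", "sample"
        spots.append(SpotAssignment(r, c, sirna, gene, role, background))
    return PlateLayout.from_spots(
        chamber_id, spots, background=background, n_rows=n_rows, n_cols=n_cols
    )


@pytest.fixture
def small_layout():
    return grid_layout()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
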
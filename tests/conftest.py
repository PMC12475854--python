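import numpy as np
import pandas as pd
import pytest

from proxidiff.matrix_io import GroupDesign, IntensityMatrix


@pytest.fixture
def tiny_matrix() -> IntensityMatrix:
    """3 proteins x 6 samples, raw scale, one missing cell."""
    data = pd.DataFrame(
        {
            "bait_1": [8.0, 16.0, 4.0],
            "bait_2": [8.0, 32.0, 4.0],
            "bait_3": [8.0, 16.0, 4.0],
            "ctrl_1": [2.0, np.nan, 4.0],
            "ctrl_2": [2.0, 16.0, 4.0],
            "ctrl_3": [2.0, 16.0, 4.0],
        },
        index=pd.Index(["P1", "P2", "P3"], name="protein_id"),
    )
    genes = pd.Series(["Bin1", "Amph", "Synj1"], index=data.index)
    return IntensityMatrix(data, genes)


@pytest.fixture
def tiny_design() -> GroupDesign:
    return GroupDesign(
        {
            "bait_1": "bait",
            "bait_2": "bait",
            "bait_3": "bait",
            "ctrl_1": "ctrl",
            "ctrl_2": "ctrl",
            "ctrl_3": "ctrl",
        },
        bait_group="bait",
        control_group="ctrl",
    )
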
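import numpy as np
import pandas as pd
import pytest

from mnprof.io import FeatureTable, classify_measurement


def make_table(values, names, sample_ids, conditions, scaled=False):
    """Assemble a FeatureTable from raw arrays (test helper)."""
    values = np.asarray(values, dtype=float)
    cell_ids = [f"cell{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=cell_ids, columns=names)
    cells = pd.DataFrame(
        {"sample_id": sample_ids, "condition": conditions, "stain_panel": None},
        index=cell_ids,
    )
    return FeatureTable(df, [classify_measurement(n) for n in names], cells, scaled)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_table():
    """3 cells x 4 measurements across the three categories."""
    names = [
        "AreaShape_Zernike_4_2",
        "Texture_Contrast_DAPI_3",
        "Intensity_MeanIntensity_FUS",
        "Intensity_NCRatio_SFPQ",
    ]
    values = [
        [1.0, 0.5, 10.0, 1.2],
        [2.0, 0.7, 12.0, 0.9],
        [3.0, 0.2, 11.0, 1.1],
    ]
    return make_table(
        values,
        names,
        ["m1", "m1", "m2"],
        ["control", "control", "vcp"],
    )
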
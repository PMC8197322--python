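import numpy as np
import pandas as pd
import pytest

from mirpipe import (
    CtMatrix,
    GroupDesign,
    default_panel_truth,
    generate_ct_matrix,
)


@pytest.fixture()
def toy_matrix() -> CtMatrix:
    """3 assays x 2 samples, fully detected."""
    ct = pd.DataFrame(
        [[20.0, 21.0], [25.5, 24.5], [30.25, 31.75]],
        index=["miR-a", "miR-b", "miR-c"],
        columns=["s1", "s2"],
    )
    meta = pd.DataFrame(
        {"condition": ["ctrl", "ko"], "cell_line": ["l1", "l2"],
         "batch": ["b1", "b1"], "pooled": [0, 0]},
        index=["s1", "s2"],
    )
    return CtMatrix(ct, meta=meta)


@pytest.fixture()
def panel():
    """Default synthetic 111-assay panel (seed 1) with its ground truth."""
    truth = default_panel_truth(seed=1)
    m, truth = generate_ct_matrix(truth)
    return m, truth


@pytest.fixture()
def design(panel) -> GroupDesign:
    return panel[1].design()


def make_matrix(ct: np.ndarray, conditions, prefix="s") -> CtMatrix:
    """Build a fully detected CtMatrix with given per-sample conditions."""
    ct = np.asarray(ct, dtype=float)
    samples = [f"{prefix}{j+1}" for j in range(ct.shape[1])]
    assays = [f"a{i+1}" for i in range(ct.shape[0])]
    meta = pd.DataFrame(
        {"condition": list(conditions), "cell_line": samples,
         "batch": "b1", "pooled": 0},
        index=samples,
    )
    return CtMatrix(pd.DataFrame(ct, index=assays, columns=samples), meta=meta)
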
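import numpy as np
import pandas as pd
import pytest

from preservstat import FeatureTable, StudyTable


@pytest.fixture
def two_material_study() -> StudyTable:
    """Tiny 2-material x (2 dried + 2 frozen) design with a strong effect."""
    rows = []
    for m in ("mat_A", "mat_B"):
        for t, vals in (("dried", (10.0, 10.0)), ("frozen", (1.0, 1.0))):
            for i, v in enumerate(vals):
                rows.append(
                    {"sample_id": f"{m}.{t}.{i}", "material": m,
                     "treatment": t, "yield": v}
                )
    return StudyTable(pd.DataFrame(rows), ("yield",))


@pytest.fixture
def small_proportions() -> FeatureTable:
    values = np.array(
        [
            [0.50, 0.20, 0.10, 0.30],
            [0.30, 0.30, 0.60, 0.30],
            [0.20, 0.50, 0.30, 0.40],
        ]
    )
    return FeatureTable(("f1", "f2", "f3"), ("s1", "s2", "s3", "s4"), values,
                        "proportions")


def make_study(materials, treatments, values, metric="metric") -> StudyTable:
    """Build a StudyTable from parallel label/value lists."""
    df = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(values))],
            "material": materials,
            "treatment": treatments,
            metric: values,
        }
    )
    return StudyTable(df, (metric,))
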
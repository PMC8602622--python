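import numpy as np
import pandas as pd
import pytest

from aerometab import (
    MetaboliteMatrix,
    SimulationConfig,
    StudyDesign,
    align,
    preprocess_matrix,
    simulate_study,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: 34 samples (10/10/6/8), 89/71/71 metabolites."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def serum_processed(study):
    """Aligned and preprocessed serum matrix with its design."""
    matrices, design, _ = study
    matrix, design = align(matrices["serum"], design)
    processed, spec = preprocess_matrix(matrix, design)
    return processed, design, spec


@pytest.fixture()
def small_design():
    """Tiny full-factorial design: 2 samples per capacity x age cell."""
    rows = []
    i = 0
    for cap in ("HCR", "LCR"):
        for age in ("Y", "O"):
            for _ in range(2):
                i += 1
                rows.append((f"s{i}", cap, age))
    table = pd.DataFrame(rows, columns=["sample_id", "capacity", "age"])
    return StudyDesign(table.set_index("sample_id"))


def make_design(n_per_group, speed=None, seed=0):
    """Design with given (HCR-Y, LCR-Y, HCR-O, LCR-O) counts."""
    from aerometab.datatypes import GROUP_ORDER

    groups = [g for g, n in zip(GROUP_ORDER, n_per_group) for _ in range(n)]
    table = pd.DataFrame(
        {
            "capacity": [g.split("-")[0] for g in groups],
            "age": [g.split("-")[1] for g in groups],
        },
        index=pd.Index([f"s{i + 1}" for i in range(len(groups))], name="sample_id"),
    )
    if speed is not None:
        table["speed"] = speed
    return StudyDesign(table)


def random_matrix(n, J, seed=0, tissue="serum", positive=True):
    rng = np.random.default_rng(seed)
    values = rng.lognormal(2.0, 0.4, size=(n, J)) if positive \
        else rng.standard_normal((n, J))
    return MetaboliteMatrix(
        pd.DataFrame(
            values,
            index=[f"s{i + 1}" for i in range(n)],
            columns=[f"m{j + 1}" for j in range(J)],
        ),
        tissue=tissue,
    )
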
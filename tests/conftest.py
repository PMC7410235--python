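import numpy as np
import pandas as pd
import pytest

from stablasso.preprocess import CohortTable, DesignMatrix, VariableSpec


def _make_design(X, y, names=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(names) if names is not None else [f"x{j + 1}" for j in range(X.shape[1])]
    return DesignMatrix(
        X=X, y=y, column_names=names, scaling={n: (0.0, 1.0) for n in names}
    )


def _make_table(values: dict, censored: dict | None = None, llods: dict | None = None,
                roles: dict | None = None, kinds: dict | None = None,
                outcome: str = "group"):
    """Small cohort table from plain dicts; cytokines inferred from llods."""
    llods = llods or {}
    roles = roles or {}
    kinds = kinds or {}
    data = pd.DataFrame(values)
    data.index = pd.Index([f"s{i + 1}" for i in range(len(data))], name="subject_id")
    cens = pd.DataFrame(False, index=data.index, columns=data.columns)
    for col, mask in (censored or {}).items():
        cens[col] = list(mask)
        data.loc[cens[col], col] = np.nan
    meta = {}
    for col in data.columns:
        if col == outcome:
            meta[col] = VariableSpec(col, "outcome", kind="binary")
        elif col in llods:
            meta[col] = VariableSpec(col, "cytokine", units="pg/ml", llod=llods[col])
        else:
            meta[col] = VariableSpec(
                col, roles.get(col, "pup"), kind=kinds.get(col, "numeric")
            )
    return CohortTable(data, cens, meta, outcome)


@pytest.fixture
def make_design():
    return _make_design


@pytest.fixture
def make_table():
    return _make_table


@pytest.fixture(scope="session")
def logistic_xy():
    """Well-conditioned synthetic logistic data, n=60, p=3, standardized."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((60, 3))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.array([1.0, -0.5, 0.25])
    eta = 0.3 + X @ beta
    y = (rng.random(60) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y
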
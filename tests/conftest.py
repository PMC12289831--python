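import warnings

import numpy as np
import pandas as pd
import pytest

from soilpte import SyntheticScenario, generate_survey, make_survey

warnings.filterwarnings(
    "ignore", message="singular correlation matrix"
)


@pytest.fixture(scope="session")
def default_survey():
    """Default 44-site synthetic survey plus its ground truth (seed 1)."""
    return generate_survey(SyntheticScenario(seed=1))


@pytest.fixture(scope="session")
def clr_default(default_survey):
    from soilpte import clr_transform, impute_censored

    survey, _ = default_survey
    matrix, _ = impute_censored(survey)
    return clr_transform(matrix)


@pytest.fixture(scope="session")
def pca_default(clr_default):
    from soilpte import CompositionalPCA

    return CompositionalPCA(clr_default).fit()


def toy_table(conc: dict, censored: dict | None = None, land_use=None):
    """Small hand-built survey: conc maps element -> list of values."""
    n = len(next(iter(conc.values())))
    rng = np.random.default_rng(0)
    coords = np.column_stack(
        [np.arange(n) * 300.0, rng.uniform(0, 1000, n)]
    )
    cens = None
    if censored is not None:
        cens = pd.DataFrame(
            {el: censored.get(el, [False] * n) for el in conc}
        )
    return make_survey(
        [f"T{i}" for i in range(n)],
        coords,
        np.full(n, 10.0),
        land_use or ["agricultural"] * n,
        pd.DataFrame(conc),
        cens,
    )


@pytest.fixture
def four_site_as():
    """Four sites with As = 10, 21, 55, 19 (screening toy example)."""
    return toy_table({"As": [10.0, 21.0, 55.0, 19.0]})
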
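import numpy as np
import pandas as pd
import pytest

from biomon.survey import ElementPanel, ElementalSurvey, Site

SMALL_PANEL = ElementPanel(("Al", "Fe", "Cr", "Zn"),
                           {"Al": "micro", "Fe": "micro", "Cr": "trace", "Zn": "micro"})


def build_survey(values, sites=None, panel=SMALL_PANEL, censored=None, dls=None,
                 label="strawberry_leaf"):
    """Assemble a survey from a plain array (last row = background by default)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if sites is None:
        sites = [Site(f"S{i}", -9.0 + 0.01 * i, 38.6, "exposure") for i in range(n - 1)]
        sites.append(Site("BG", -9.2, 38.6, "background"))
    ids = [s.site_id for s in sites]
    cens = (np.zeros_like(values, dtype=bool) if censored is None
            else np.asarray(censored, dtype=bool))
    conc = pd.DataFrame(np.where(cens, np.nan, values), index=ids,
                        columns=list(panel.elements))
    mask = pd.DataFrame(cens, index=ids, columns=list(panel.elements))
    return ElementalSurvey(tuple(sites), panel, conc, mask, dls or {}, label)


@pytest.fixture
def small_survey():
    # 3 exposure sites + background; strictly positive, no censoring
    vals = [
        [100.0, 500.0, 10.0, 30.0],
        [200.0, 900.0, 8.0, 45.0],
        [150.0, 300.0, 12.0, 20.0],
        [120.0, 400.0, 6.0, 25.0],
    ]
    return build_survey(vals)


@pytest.fixture(scope="session")
def synth_pair():
    """One default synthetic paired survey, shared across tests."""
    from biomon.synth import generate
    return generate(seed=11)


@pytest.fixture(scope="session")
def leaf_survey(synth_pair):
    from biomon.survey import impute_censored
    return impute_censored(synth_pair[0])
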
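import numpy as np
import pytest

import ncaaprop as ncp


@pytest.fixture(scope="session")
def canonical_table():
    return ncp.canonical_table()


@pytest.fixture(scope="session")
def design_matrix(canonical_table):
    return ncp.build_design_matrix(canonical_table)


@pytest.fixture(scope="session")
def ncaa_table():
    return ncp.ncaa_table()


@pytest.fixture(scope="session")
def published_model_dict():
    return ncp.published_eisd_model()


@pytest.fixture(scope="session")
def published_model(published_model_dict):
    ref = published_model_dict
    return ncp.TrainedModel(
        accession=ref["accession"],
        selected=tuple(ref["selected"]),
        b={k: ref["coefficients"][k] for k in ref["selected"]},
        constant=ref["constant"],
        f_star=ref["f_star"],
        r_jn=ref["r_jn"],
        r_insample=ref["r_insample"],
        p_num=ref["p_num"],
        rmse=ref["rmse"],
        n_used=20,
        description=ref["description"],
    )


@pytest.fixture(scope="session")
def eisd_record():
    return ncp.eisd_values_synthetic()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
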
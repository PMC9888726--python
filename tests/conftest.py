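import numpy as np
import pandas as pd
import pytest

import vaxineq as vq


@pytest.fixture(scope="session")
def small_config():
    return vq.SynthConfig(
        n_countries=2,
        regions_per_country=9,
        psus_per_region=3,
        children_per_psu=12,
        seed=17,
    )


@pytest.fixture(scope="session")
def small_survey(small_config):
    """A small two-country survey shared across read-only tests."""
    children, geojson, truth = vq.generate_survey(small_config)
    return children, geojson, truth


@pytest.fixture(scope="session")
def small_status(small_survey):
    children, _, _ = small_survey
    return vq.complete_course(children)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_children(doses_rows, weights=None, **extra):
    """Minimal child table from explicit dose tuples (bcg, dtp1..3, opv1..3, mcv)."""
    n = len(doses_rows)
    cols = ["bcg", "dtp1", "dtp2", "dtp3", "opv1", "opv2", "opv3", "mcv"]
    df = pd.DataFrame(doses_rows, columns=cols)
    df.insert(0, "child_id", [f"k{i}" for i in range(n)])
    df.insert(1, "country", extra.get("country", ["X"] * n))
    df.insert(2, "region_id", extra.get("region_id", ["X-R0"] * n))
    df.insert(3, "psu_id", extra.get("psu_id", [f"p{i % 2}" for i in range(n)]))
    df.insert(4, "weight", weights if weights is not None else np.ones(n))
    df.insert(5, "age_months", extra.get("age_months", [24] * n))
    df.insert(6, "wealth_score", extra.get("wealth_score", np.arange(n, dtype=float)))
    df["source"] = "card"
    return df
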
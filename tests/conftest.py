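import numpy as np
import pandas as pd
import pytest

from rfrelate import FeatureTable
from rfrelate.synthetic import InformativeGroup, SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def two_class_block_dataset():
    """120 samples, 40 metabolites x 3 adducts, one informative triplet group."""
    spec = SyntheticSpec(
        n_samples=120,
        class_schemes={"origin": {"A": 60, "B": 60}},
        n_batches=3,
        n_metabolites=40,
        adduct_multiplicity=3,
        within_metabolite_corr=0.98,
        informative_groups=(
            InformativeGroup((0, 1), "origin", ("A",), 3.0),
        ),
        missing_base_rate=0.0,
        seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture()
def small_table():
    """Tiny complete table with batches and two label schemes."""
    rng = np.random.default_rng(0)
    n = 12
    intens = pd.DataFrame(
        rng.uniform(10, 50, size=(n, 4)),
        index=[f"s{i}" for i in range(n)],
        columns=["f1", "f2", "f3", "f4"],
    )
    smeta = pd.DataFrame(
        {
            "origin": ["A"] * 6 + ["B"] * 6,
            "variety": ["X", "Y"] * 3 + [pd.NA] * 6,
            "batch": [0, 1, 2] * 4,
        },
        index=intens.index,
    )
    fmeta = pd.DataFrame(
        {
            "mz": [100.0, 122.0, 300.0, 322.0],
            "rt": [1.0, 1.0, 2.0, 2.0],
            "adduct_label": ["[M+Na]+", "[M+NH4]+", "[M+Na]+", "fragment"],
            "adduct_group_id": [pd.NA] * 4,
        },
        index=intens.columns,
    )
    return FeatureTable(intens, smeta, fmeta)
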
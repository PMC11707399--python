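import numpy as np
import pandas as pd
import pytest

from benthos.core_io import (
    EnvironmentTable,
    SampleTable,
    TrawlRecord,
    tree_from_newick,
)

#: ((A:1,B:1):1,C:2); patristic: AB=2, AC=BC=4; depths all 2
TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return tree_from_newick(TOY_NEWICK)


@pytest.fixture
def toy_table():
    data = pd.DataFrame(
        [[10.0, 20.0, 70.0], [5.0, 0.0, 3.0], [0.0, 1.0, 4.0]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return SampleTable(data)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def star_tree(k: int, branch: float = 1.0):
    tips = ",".join(f"t{i}:{branch}" for i in range(k))
    return tree_from_newick(f"({tips});")


def random_table(rng, n_sites=8, n_species=5, scale=100.0) -> SampleTable:
    vals = rng.gamma(1.0, scale, (n_sites, n_species))
    vals[rng.random(vals.shape) < 0.2] = 0.0
    return SampleTable(
        pd.DataFrame(
            vals,
            index=[f"s{i}" for i in range(n_sites)],
            columns=[f"sp{j}" for j in range(n_species)],
        )
    )


def make_records():
    """Trawl fixture: two sites, one with a double tow."""
    return [
        TrawlRecord("st1", "crab", 100, 2.0, 1000.0, tow_id="T1"),
        TrawlRecord("st2", "crab", 50, 2.0, 1000.0, tow_id="T1"),
        TrawlRecord("st2", "shrimp", 50, 2.0, 1000.0, tow_id="T2"),
    ]
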
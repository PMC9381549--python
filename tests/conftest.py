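import numpy as np
import pandas as pd
import pytest

from ecoassembly import CountTable, RelAbundanceTable, parse_tree

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def toy_tree():
    """Balanced 4-tip tree, all branch lengths 1 (total branch length 6)."""
    return parse_tree(TOY_NEWICK)


@pytest.fixture
def toy_counts():
    return CountTable(
        pd.DataFrame(
            [[10, 10, 0, 0], [0, 0, 5, 15], [4, 4, 4, 4]],
            index=["s1", "s2", "s3"],
            columns=list("ABCD"),
        )
    )


def random_table(rng, n_samples, n_taxa, depth=500):
    """Multinomial table from a log-normal pool (helper for property tests)."""
    a = rng.lognormal(0, 1, n_taxa)
    counts = rng.multinomial(depth, a / a.sum(), size=n_samples)
    # ensure no empty sample / taxon labels are well formed
    return CountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )


def random_rel_table(rng, n_samples, n_taxa):
    x = rng.dirichlet(np.ones(n_taxa), size=n_samples)
    return RelAbundanceTable(
        pd.DataFrame(
            x,
            index=[f"s{i}" for i in range(n_samples)],
            columns=[f"t{j}" for j in range(n_taxa)],
        )
    )
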
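from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from glycograph.chaingraph import Box, Variable, VariableOrdering


def make_ordering(response="y", covars=("x1", "x2", "x3"), categorical=()):
    """Two-box ordering: one response on the left, covariates on the right."""
    variables = {response: Variable(response, role="response")}
    for c in covars:
        if c in categorical:
            variables[c] = Variable(
                c, vtype="categorical", reference=categorical[c], role="intrinsic"
            )
        else:
            variables[c] = Variable(c, role="intrinsic")
    return VariableOrdering([Box((response,)), Box(tuple(covars))], variables)


@pytest.fixture
def ordering3():
    return make_ordering()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_genotypes():
    """6 individuals x 3 SNPs with two sporadic missing calls."""
    from glycograph.genotyping import GenotypeMatrix

    counts = pd.DataFrame(
        {
            "rs1": [0, 1, 2, 1, np.nan, 1],
            "rs2": [2, 2, 1, 0, 1, np.nan],
            "rs3": [0, 0, 1, 1, 2, 2],
        },
        index=pd.Index([f"I{i}" for i in range(6)], name="id"),
    )
    return GenotypeMatrix(counts)
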
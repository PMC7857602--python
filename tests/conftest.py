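import numpy as np
import pytest

from dvpattern.gradients import make_canonical_gradient
from dvpattern.pipeline import quantify_cohort, simulate_cohort
from dvpattern.synthetic import CANONICAL_GENES, EmbryoSpec, GeneTruth, ReadoutModel

THREE_GENES = tuple(g for g in CANONICAL_GENES if g.gene_name != "ved")


@pytest.fixture(scope="session")
def wt_gradient():
    return make_canonical_gradient("wild_type")


@pytest.fixture(scope="session")
def chd_gradient():
    return make_canonical_gradient("chordin_mutant")


@pytest.fixture(scope="session")
def genes():
    return THREE_GENES


@pytest.fixture(scope="session")
def threshold_model():
    return ReadoutModel.from_truths(CANONICAL_GENES)


@pytest.fixture(scope="session")
def wt_cohort():
    """20 wild-type embryos at study conditions (seeds 1-20)."""
    return simulate_cohort("wild_type", 20, list(range(1, 21)), genes=THREE_GENES)


@pytest.fixture(scope="session")
def chd_cohort():
    """20 chordin-mutant embryos at study conditions (seeds 101-120)."""
    return simulate_cohort(
        "chordin_mutant", 20, list(range(101, 121)), genes=THREE_GENES
    )


@pytest.fixture(scope="session")
def wt_quantified(wt_cohort):
    return quantify_cohort(wt_cohort, genes=[g.gene_name for g in THREE_GENES])


@pytest.fixture(scope="session")
def chd_quantified(chd_cohort):
    return quantify_cohort(chd_cohort, genes=[g.gene_name for g in THREE_GENES])
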
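import warnings

import pytest

from cosbr.fixtures import FixtureSpec, make_end_to_end_fixture, make_locus
from cosbr.pipeline import run_pipeline


@pytest.fixture(scope="session")
def e2e():
    """One full end-to-end scenario (seed 1)."""
    return make_end_to_end_fixture(1)


@pytest.fixture(scope="session")
def pipeline_result(e2e):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            e2e.bac,
            e2e.puc_plasmid,
            e2e.selection_fragment,
            e2e.design.lox_oligo,
            e2e.retrieval_plasmid,
            e2e.params,
            screen_primers=e2e.design.screen_primers,
        )


@pytest.fixture(scope="session")
def locus_and_gene():
    """A plain plus-strand locus/gene pair for unit tests."""
    return make_locus(FixtureSpec(seed=11))


def small_gene(seed, **over):
    """A compact locus for bulk frame-arithmetic tests."""
    spec = FixtureSpec(
        seed=seed,
        locus_len=8000,
        n_exons=5,
        exon_len_range=(90, 150),
        critical_exon=2,
        **over,
    )
    return make_locus(spec)
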
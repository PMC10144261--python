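import pytest

from svatk.psm_io import make_config
from svatk.quant import quantify_variants
from svatk.simulate import synth_project


@pytest.fixture(scope="session")
def sva7():
    """Default spiked-variant project: 7 true SVs at 0.2%, 50 planted FPs."""
    return synth_project(seed=1)


@pytest.fixture(scope="session")
def sva7_proteins(sva7):
    return {p.id: p for p in sva7.proteins}


@pytest.fixture(scope="session")
def sva7_quants(sva7):
    return {name: q.rel_quant_pct
            for name, q in quantify_variants(sva7.psms).items()}


@pytest.fixture(scope="session")
def high_res_config():
    return make_config("high_res")
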
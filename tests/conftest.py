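import logging

import pytest

from rlea import FixtureSpec, IntervalSet, LocusSet, make_ocr_sets, make_toy_genome


@pytest.fixture
def toy_spec():
    """Default synthetic-data conditions: 2 x 10 Mb genome, 3 cell types,
    200 x 5 kb peaks each (5% coverage), 1000 SNV loci."""
    return FixtureSpec()


@pytest.fixture
def toy_genome(toy_spec):
    return make_toy_genome(toy_spec)


@pytest.fixture
def toy_ocr_sets(toy_spec):
    return make_ocr_sets(toy_spec)


def iset(name, *spans):
    return IntervalSet(name, list(spans))


@pytest.fixture
def quiet_logs(caplog):
    caplog.set_level(logging.INFO)
    return caplog
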
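import dataclasses

import pytest

from avipva.demography_io import load_fixtures


@pytest.fixture(scope="session")
def catalog():
    return load_fixtures()


@pytest.fixture(scope="session")
def starling1(catalog):
    return catalog.get("Common Starling", period="1960-1978")


@pytest.fixture(scope="session")
def starling2(catalog):
    return catalog.get("Common Starling", period="1978-1990")


@pytest.fixture(scope="session")
def starling3(catalog):
    return catalog.get("Common Starling", period="1990-2012")


@pytest.fixture(scope="session")
def godwit_coast(catalog):
    return catalog.get("Black-tailed Godwit", population="Kuststrook")


def strip_sds(v):
    """Copy of a record with every SD forced to zero (deterministic limit)."""
    return dataclasses.replace(
        v,
        fledglings_sd=0.0,
        survival=tuple(dataclasses.replace(s, sd=0.0) for s in v.survival),
    )


def scale_sds(v, factor):
    return dataclasses.replace(
        v,
        fledglings_sd=v.fledglings_sd * factor,
        survival=tuple(
            dataclasses.replace(s, sd=s.sd * factor) for s in v.survival
        ),
    )
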
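"""Shared fixtures: small synthetic proteomes generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from piscape import (
    CompartmentSpec,
    batch_pi,
    gen_proteome,
    load_scheme,
)
from piscape.sequence_io import attach_localizations


@pytest.fixture(scope="session")
def scheme():
    return load_scheme("bjellqvist")


@pytest.fixture(scope="session")
def small_specs():
    """Six-compartment mini design with clear acid/alkaline contrasts."""
    return [
        CompartmentSpec("cytoplasm", n=150, acid_weight=0.80),
        CompartmentSpec("lysosome", n=150, acid_weight=0.75),
        CompartmentSpec("er", n=150, acid_weight=0.70),
        CompartmentSpec("golgi", n=150, acid_weight=0.45),
        CompartmentSpec("nucleus", n=150, acid_weight=0.25),
        CompartmentSpec("mitochondria", n=150, acid_weight=0.20),
    ]


@pytest.fixture(scope="session")
def small_proteome(small_specs):
    """Raw records + localization map from the generator (seeded)."""
    return gen_proteome(small_specs, seed=11)


@pytest.fixture(scope="session")
def annotated_records(small_proteome, scheme):
    """Records with pI computed and localization attached."""
    records, loc_map = small_proteome
    labelled, missing = attach_localizations(records, loc_map)
    assert not missing
    return batch_pi(labelled, scheme)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))
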
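"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gametolog_div.seq_io import (
    FEMALE,
    MALE,
    NW_EUROPE,
    PANNONIAN,
    SE_REFUGIA,
    AlignedMarker,
    AlleleSequence,
    RegionMap,
    parse_label,
)
from gametolog_div.simulate import SimParams

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[
        HealthCheck.too_slow,
        HealthCheck.function_scoped_fixture,
    ],
    deadline=None,
)
settings.load_profile("suite")


def make_marker(records: list[tuple[str, str]], marker: str = "toy") -> AlignedMarker:
    """Build an AlignedMarker from (header, sequence) pairs."""
    alleles = tuple(parse_label(h, marker, s) for h, s in records)
    return AlignedMarker(marker=marker, length=len(records[0][1]), alleles=alleles)


@pytest.fixture
def regions() -> RegionMap:
    return RegionMap(
        {1: SE_REFUGIA, 2: SE_REFUGIA, 3: PANNONIAN, 4: NW_EUROPE, 5: NW_EUROPE}
    )


@pytest.fixture
def toy_marker() -> AlignedMarker:
    return make_marker(
        [
            ("1_F_1_a", "ACGTACGTAC"),
            ("1_F_1_b", "ACGAACGTAC"),
            ("2_M_1_a", "ACGTACGTAC"),
            ("2_M_1_b", "TCGAACGTAC"),
        ]
    )


#: Scaled-down simulation conditions for replicate-heavy property checks.
SMALL_SIM = dict(
    seq_len=300,
    deme_size={SE_REFUGIA: 16, PANNONIAN: 12, NW_EUROPE: 12},
    n_sample={
        (SE_REFUGIA, MALE): 4,
        (SE_REFUGIA, FEMALE): 4,
        (PANNONIAN, MALE): 3,
        (PANNONIAN, FEMALE): 3,
        (NW_EUROPE, MALE): 4,
        (NW_EUROPE, FEMALE): 4,
    },
    burn_in=80,
    t_split=60,
    t_pannonian=80,
    sub_rate=5e-5,
)


def small_params(**overrides) -> SimParams:
    kw = dict(SMALL_SIM)
    kw.update(overrides)
    return SimParams(**kw)


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test RNG (stable across processes)."""
    import zlib

    return np.random.default_rng(zlib.crc32(name.encode()) % (2**31))
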
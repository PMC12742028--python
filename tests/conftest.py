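"""Shared fixtures: compact protocols and cached synthetic sessions.

Expensive session-scoped fixtures are generated once; tests that only read
them must not mutate. Problem sizes are chosen so the whole suite stays
desk-scale while every planted effect remains comfortably detectable.
"""

from __future__ import annotations

import numpy as np
import pytest

from sbdecode.protocol import REST, SB_MINUS, SB_PLUS, SessionProtocol, default_protocol
from sbdecode.simulate import EffectSpec, generate_session

# quarter-scale version of the default two-block protocol: same structure
# (three rest segments, five SB alternations per block), shorter segments
SCALED_LAYOUT: tuple[tuple[str, int], ...] = tuple(
    [(REST, 28)]
    + [(SB_MINUS if i % 2 == 0 else SB_PLUS, 16) for i in range(5)]
    + [(REST, 28)]
    + [(SB_PLUS if i % 2 == 0 else SB_MINUS, 16) for i in range(5)]
    + [(REST, 28)]
)


@pytest.fixture(scope="session")
def scaled_protocol() -> SessionProtocol:
    return SessionProtocol(block_layout=SCALED_LAYOUT, sampling_rate=300.0)


@pytest.fixture(scope="session")
def full_null_session():
    """One full-protocol session with no state effects, 62 regions."""
    return generate_session(default_protocol(), EffectSpec.null(), seed=101)


@pytest.fixture(scope="session")
def full_study_session():
    """One full-protocol session with the study-like planted effects."""
    return generate_session(default_protocol(), EffectSpec.study_like(), seed=202)


@pytest.fixture(scope="session")
def small_null_session(scaled_protocol):
    """Scaled-protocol null session with 8 regions, for fast unit tests."""
    return generate_session(
        scaled_protocol, EffectSpec.null(region_count=8), seed=11
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
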
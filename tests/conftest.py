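"""Shared fixtures: all test inputs are generated, nothing is downloaded."""

from __future__ import annotations

import pytest

from rlmscan.rlm_search import match_rlm
from rlmscan.sse_matrix import assign_sse, build_interaction_matrix
from rlmscan.synthetic_data import (
    DECOY_KINDS,
    FixtureSpec,
    make_decoy,
    make_ideal_rlm,
)


@pytest.fixture(scope="session")
def ideal():
    """(structure, ground-truth match) for the canonical sandwich."""
    return make_ideal_rlm()


@pytest.fixture(scope="session")
def ideal_with_insertion():
    return make_ideal_rlm(FixtureSpec(insertion=True))


@pytest.fixture(scope="session")
def decoys():
    return {kind: make_decoy(kind) for kind in DECOY_KINDS}


def scan(structure):
    """assign SSEs, build the matrix, and match -- the standard path."""
    sses = assign_sse(structure)
    matrix = build_interaction_matrix(sses, structure)
    return sses, matrix, match_rlm(matrix, sses, structure)


@pytest.fixture(scope="session")
def ideal_scan(ideal):
    return scan(ideal[0])


@pytest.fixture(scope="session")
def ideal_match(ideal_scan):
    (_, _, matches) = ideal_scan
    assert len(matches) == 1
    return matches[0]
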
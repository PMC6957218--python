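"""Motif matching, domain anchoring, and oracle equivalence."""

import copy

import numpy as np
import pytest

from oracle import brute_force_rlm, match_frames
from rlmscan.rlm_search import assign_to_domain, match_from_ranges, match_rlm
from rlmscan.sse_matrix import HELIX, assign_sse, build_interaction_matrix
from rlmscan.structure_io import parse_domain_range
from rlmscan.synthetic_data import (
    DECOY_KINDS,
    FixtureSpec,
    make_decoy,
    make_ideal_rlm,
    _assemble,
    _oriented_segment,
)

from conftest import scan


def test_ideal_yields_single_helix_iv_match(ideal, ideal_scan):
    _, truth = ideal
    _, _, matches = ideal_scan
    assert len(matches) == 1
    m = matches[0]
    assert m.variant == "helix-IV"
    # detected elements sit inside the scripted ground-truth ranges
    for name in ("I", "II", "III", "IV", "V"):
        want = truth.elements[name]
        got = m.elements[name]
        assert want.start <= got.start and got.end <= want.end
        assert len(got) >= len(want) - 2


def test_loops_are_populated(ideal_match):
    assert len(ideal_match.catalytic_loop) >= 2
    assert len(ideal_match.crossover_loop) >= 1
    cat_nums = [r.number for r in ideal_match.catalytic_loop]
    assert ideal_match.elements["I"].end < min(cat_nums)
    assert max(cat_nums) < ideal_match.elements["II"].start


def test_insertion_fixture_excludes_insertion_from_elements(ideal_with_insertion):
    st, truth = ideal_with_insertion
    _, _, matches = scan(st)
    assert len(matches) == 1
    m = matches[0]
    assert m.variant == "helix-IV"
    # element V is the post-crossover strand, not the inserted one
    assert abs(m.elements["V"].start - truth.elements["V"].start) <= 1
    assert len(m.insertions) == 2
    inserted_numbers = {r.number for s in m.insertions for r in s.residues}
    element_numbers = {
        r.number for n in ("I", "II", "III", "IV", "V") for r in m.element_residues(n)
    }
    assert not inserted_numbers & element_numbers


@pytest.mark.parametrize("kind", DECOY_KINDS)
def test_each_decoy_family_yields_zero_matches(decoys, kind):
    _, _, matches = scan(decoys[kind])
    assert matches == []


def test_determinism_identical_runs_identical_output(ideal):
    st, _ = ideal
    a = scan(st)[2]
    b = scan(st)[2]
    assert [repr(m) for m in a] == [repr(m) for m in b]


@pytest.mark.parametrize(
    "fixture_fn",
    [
        lambda: make_ideal_rlm()[0],
        lambda: make_ideal_rlm(FixtureSpec(insertion=True))[0],
    ]
    + [lambda k=k: make_decoy(k) for k in DECOY_KINDS],
)
def test_matcher_equals_brute_force_enumeration(fixture_fn):
    st = fixture_fn()
    sses = assign_sse(st)
    assert len(sses) <= 12
    matrix = build_interaction_matrix(sses, st)
    got = match_frames(match_rlm(matrix, sses, st))
    want = brute_force_rlm(matrix, sses, st)
    assert got == want


def test_remote_helix_never_removes_a_match(ideal):
    st, _ = ideal
    base_frames = match_frames(scan(st)[2])
    st2 = copy.deepcopy(st)
    # a helix far from everything, appended after element V
    far = _oriented_segment(8, -57.0, -47.0, (0, 1, 0), (60.0, 0.0, 0.0))
    last = max(r.number for r in st2.chains[0].residues)
    extra, _ = _assemble("x", [("h", far)])
    for i, res in enumerate(extra.chains[0].residues, start=last + 10):
        res.number = i
        st2.chains[0].residues.append(res)
    sses2 = assign_sse(st2)
    assert sum(1 for s in sses2 if s.kind == HELIX) == 3
    frames2 = match_frames(match_rlm(build_interaction_matrix(sses2, st2), sses2, st2))
    assert base_frames <= frames2


def test_match_kept_only_when_inside_one_domain(ideal, ideal_match):
    st, _ = ideal
    m = copy.deepcopy(ideal_match)
    last = max(r.number for r in st.polymer_residues())
    inside = [("d1", parse_domain_range(f"A:1-{last}"))]
    kept = assign_to_domain([m], inside)
    assert len(kept) == 1 and kept[0].domain_id == "d1"

    # element V (and more) outside every domain -> discarded
    short = [("d1", parse_domain_range(f"A:1-{m.elements['V'].start - 1}"))]
    assert assign_to_domain([copy.deepcopy(ideal_match)], short) == []


def test_match_spanning_two_domains_is_discarded(ideal, ideal_match):
    st, _ = ideal
    m = copy.deepcopy(ideal_match)
    split = m.elements["III"].start
    last = max(r.number for r in st.polymer_residues())
    doms = [
        ("d1", parse_domain_range(f"A:1-{split - 1}")),
        ("d2", parse_domain_range(f"A:{split}-{last}")),
    ]
    assert assign_to_domain([m], doms) == []


def test_two_matches_in_one_domain_flagged_with_canonical_tiebreak():
    m1 = match_from_ranges(
        {"I": "A:1-5", "II": "A:10-17", "III": "A:20-25", "IV": "A:30-37", "V": "A:40-45"}
    )
    m2 = match_from_ranges(
        {"I": "A:50-55", "II": "A:60-67", "III": "A:70-75", "IV": "A:80-87", "V": "A:90-95"}
    )
    doms = [("d1", parse_domain_range("A:1-100"))]
    kept = assign_to_domain([m2, m1], doms)
    assert len(kept) == 2
    canon = [m for m in kept if m.canonical]
    assert len(canon) == 1
    assert canon[0].elements["I"].start == 1  # earliest element-I start wins


def test_overlapping_domains_warn():
    m = match_from_ranges(
        {"I": "A:1-5", "II": "A:10-17", "III": "A:20-25", "IV": "A:30-37", "V": "A:40-45"}
    )
    doms = [
        ("d1", parse_domain_range("A:1-50")),
        ("d2", parse_domain_range("A:40-90")),
    ]
    with pytest.warns(UserWarning):
        kept = assign_to_domain([m], doms)
    # residues 40-45 fall in two domains -> not "exactly one" -> discarded
    assert kept == []
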
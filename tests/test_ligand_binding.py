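"""Ligand contacts, compound taxonomy, Kabsch superposition, pooling."""

import copy

import numpy as np
import pytest

from rlmscan.ligand_binding import (
    CTP_OVERRIDE,
    GENERIC_SUPERCLASS,
    LigandContact,
    NUCLEOTIDE_SUPERCLASS,
    classify_compound,
    find_contacts,
    flag_significance,
    kabsch,
    pool_ligands,
    superpose_rlm,
)
from rlmscan.structure_io import Residue
from rlmscan.synthetic_data import (
    CREVICE_LIGAND,
    FixtureSpec,
    make_ideal_rlm,
    _rotation_between,
)

from conftest import scan


def add_ligand(structure, position, name="LIG"):
    st = copy.deepcopy(structure)
    chain = st.chains[0]
    num = max(r.number for r in chain.residues) + 10
    res = Residue(chain_id="A", number=num, icode="", name=name, is_polymer=False)
    res.atoms["C1"] = np.asarray(position, float)
    res.elements["C1"] = "C"
    chain.residues.append(res)
    return st


def outermost_atom(match, element):
    pts = [
        (xyz, r) for r in match.element_residues(element) for xyz in [*r.atoms.values()]
    ]
    return max(pts, key=lambda t: t[0][0])[0]


def test_contact_at_cutoff_boundary(ideal, ideal_match):
    st, _ = ideal
    q = outermost_atom(ideal_match, "V")
    inside = add_ligand(st, q + np.array([3.9, 0.0, 0.0]))
    contacts = find_contacts(inside, inside.polymer_residues(), ideal_match)
    assert len(contacts) == 1
    assert contacts[0].regions == frozenset({"V"})
    assert contacts[0].min_distance == pytest.approx(3.9, abs=1e-6)

    outside = add_ligand(st, q + np.array([4.1, 0.0, 0.0]))
    assert find_contacts(outside, outside.polymer_residues(), ideal_match) == []


def test_bridging_ligand_attributed_to_both_elements(ideal, ideal_match):
    st, _ = ideal
    st2 = add_ligand(st, np.array([3.5, 4.75, 4.75]))
    contacts = find_contacts(st2, st2.polymer_residues(), ideal_match)
    assert len(contacts) == 1
    # brute-force distance oracle over every region
    want = set()
    p = np.array([3.5, 4.75, 4.75])
    for name, residues in ideal_match.regions().items():
        dmin = min(
            np.linalg.norm(xyz - p) for r in residues for xyz in r.heavy_coords()
        )
        if dmin <= 4.0:
            want.add(name)
    assert want == {"II", "V"}
    assert contacts[0].regions == frozenset(want)


def test_contacts_monotone_in_cutoff(ideal, ideal_match):
    st, _ = ideal
    spec = FixtureSpec(ligands=(CREVICE_LIGAND,))
    st2, _ = make_ideal_rlm(spec)
    small = find_contacts(st2, st2.polymer_residues(), ideal_match, cutoff=3.0)
    large = find_contacts(st2, st2.polymer_residues(), ideal_match, cutoff=5.0)
    assert {c.ligand_key for c in small} <= {c.ligand_key for c in large}


def test_crevice_ligand_touches_I_V_and_catalytic_loop(ideal_match):
    st, _ = make_ideal_rlm(FixtureSpec(ligands=(CREVICE_LIGAND,)))
    contacts = find_contacts(st, st.polymer_residues(), ideal_match)
    assert len(contacts) == 1
    assert contacts[0].regions == frozenset({"I", "V", "catalytic_loop"})


def test_blocklisted_additives_are_skipped(ideal, ideal_match):
    st, _ = ideal
    q = outermost_atom(ideal_match, "V")
    st2 = add_ligand(st, q + np.array([3.0, 0.0, 0.0]), name="GOL")
    assert find_contacts(st2, st2.polymer_residues(), ideal_match) == []
    assert len(find_contacts(st2, st2.polymer_residues(), ideal_match,
                             blocklist=frozenset())) == 1


def test_classify_precedence_override_table_fallback():
    table = {"C00063": ("Organic compounds", "Wrong superclass", None),
             "C00025": ("Organic compounds", "Organic acids and derivatives",
                        "Carboxylic acids and derivatives")}
    for cid in sorted(CTP_OVERRIDE):
        rec = classify_compound(cid, table)
        assert rec.superclass == NUCLEOTIDE_SUPERCLASS
        assert rec.source == "manual-override"
    rec = classify_compound("C00025", table)
    assert rec.superclass == "Organic acids and derivatives"
    assert rec.source == "taxonomy-table"
    rec = classify_compound("C99999", table)
    assert rec.superclass == GENERIC_SUPERCLASS
    assert rec.source == "generic-fallback"


def _contact(compound_id):
    return LigandContact(
        structure_id="s", domain_id=None, ligand_name="NAD",
        ligand_key=("A", 99, ""), regions=frozenset({"I"}),
        min_distance=3.0, compound_id=compound_id,
    )


def test_significance_rules():
    subs, prods, cofs = {"C00003"}, {"C00004"}, {"C00305"}
    assert flag_significance(_contact("C00003"), subs, prods, cofs) == "significant"
    assert flag_significance(_contact("C00004"), subs, prods, cofs) == "significant"
    assert flag_significance(_contact("C00305"), subs, prods, cofs) == "significant"
    assert flag_significance(_contact("C00095"), subs, prods, cofs) == "uncertain"
    assert flag_significance(_contact(None), subs, prods, cofs) == "uncertain"


def test_kabsch_identity_and_exact_transform_recovery():
    rng = np.random.default_rng(0)
    pts = rng.normal(scale=5.0, size=(20, 3))
    sup = kabsch(pts, pts)
    assert sup.rmsd < 1e-12
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)

    theta = np.deg2rad(37.0)
    R = np.array(
        [[np.cos(theta), -np.sin(theta), 0.0],
         [np.sin(theta), np.cos(theta), 0.0],
         [0.0, 0.0, 1.0]]
    )
    t = np.array([5.0, -2.0, 1.0])
    moved = pts @ R.T + t
    sup = kabsch(pts, moved)
    assert sup.rmsd < 1e-9
    assert np.allclose(sup.rotation, R, atol=1e-9)
    assert np.allclose(sup.translation, t, atol=1e-9)
    # inverse transform maps back
    inv = kabsch(moved, pts)
    assert np.allclose(inv.rotation, R.T, atol=1e-9)
    assert np.allclose(inv.apply(sup.apply(pts)), pts, atol=1e-9)


def test_kabsch_beats_random_search():
    rng = np.random.default_rng(1)
    a = rng.normal(size=(12, 3))
    b = a + rng.normal(scale=0.5, size=(12, 3))
    best = kabsch(a, b).rmsd
    for _ in range(10_000):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0, 2 * np.pi)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * K @ K
        moved = a @ R.T
        t = b.mean(axis=0) - moved.mean(axis=0)
        rmsd = np.sqrt(((moved + t - b) ** 2).sum(axis=1).mean())
        assert rmsd >= best - 1e-12


def rotated_copy(structure, match, seed):
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    R = _rotation_between(np.array([0.0, 0.0, 1.0]), axis)
    t = rng.normal(scale=15.0, size=3)
    st = copy.deepcopy(structure)
    st.id = f"{structure.id}_rot{seed}"
    for chain in st.chains:
        for res in chain.residues:
            for name in res.atoms:
                res.atoms[name] = R @ res.atoms[name] + t
    _, _, matches = scan(st)
    assert len(matches) == 1
    return st, matches[0]


def test_superpose_self_is_identity(ideal, ideal_match):
    st, _ = ideal
    sup = superpose_rlm((st, ideal_match), (st, ideal_match))
    assert sup.rmsd < 1e-12
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-9)
    assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-10)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)


def test_superpose_recovers_rigid_motion(ideal, ideal_match):
    st, _ = ideal
    moved, m2 = rotated_copy(st, ideal_match, seed=4)
    sup = superpose_rlm((moved, m2), (st, ideal_match))
    assert sup.rmsd < 1e-6
    assert sup.n_atoms >= 9


def test_superpose_different_loop_lengths_finite_rmsd(ideal, ideal_match):
    st, _ = ideal
    other, truth = make_ideal_rlm(FixtureSpec(loop_len=6, strand_len=8))
    _, _, matches = scan(other)
    assert len(matches) == 1
    sup = superpose_rlm((other, matches[0]), (st, ideal_match))
    assert np.isfinite(sup.rmsd)
    # trimmed correspondence: never more atoms than the shorter element set
    assert sup.n_atoms >= 9


def test_superpose_requires_strand_elements(ideal, ideal_match):
    broken = copy.deepcopy(ideal_match)
    broken.elements["V"] = None
    with pytest.raises(ValueError):
        superpose_rlm((ideal[0], broken), (ideal[0], ideal_match))


def test_pooled_clouds_coincide_and_order_invariant():
    st, _ = make_ideal_rlm(FixtureSpec(ligands=(CREVICE_LIGAND,)))
    _, _, matches = scan(st)
    match = matches[0]
    contacts = find_contacts(st, st.polymer_residues(), match)
    members = [(st, match, contacts)]
    for seed in (7, 8):
        st2, m2 = rotated_copy(st, match, seed)
        members.append((st2, m2, find_contacts(st2, st2.polymer_residues(), m2)))

    pooled, quality = pool_ligands(members, reference_index=0)
    assert len(quality) == 3
    coords = {}
    for atom in pooled:
        coords.setdefault(atom["atom"], []).append((atom["x"], atom["y"], atom["z"]))
    for atom_name, pts in coords.items():
        arr = np.asarray(pts)
        assert len(arr) == 3
        assert np.abs(arr - arr[0]).max() < 1e-6  # clouds coincide

    reordered, _ = pool_ligands(members[::-1], reference_index=2)
    a = sorted((p["structure"], p["atom"], round(p["x"], 6)) for p in pooled)
    b = sorted((p["structure"], p["atom"], round(p["x"], 6)) for p in reordered)
    assert a == b


def test_non_superposable_member_skipped_with_warning(caplog):
    st, _ = make_ideal_rlm(FixtureSpec(ligands=(CREVICE_LIGAND,)))
    _, _, matches = scan(st)
    match = matches[0]
    contacts = find_contacts(st, st.polymer_residues(), match)
    bad_match = copy.deepcopy(match)
    bad_match.elements["V"] = None
    members = [(st, match, contacts), (st, bad_match, contacts)]
    import logging

    with caplog.at_level(logging.WARNING, logger="rlmscan.ligand_binding"):
        pooled, quality = pool_ligands(members, reference_index=0)
    assert len(quality) == 1
    assert any("skipping" in rec.message for rec in caplog.records)
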
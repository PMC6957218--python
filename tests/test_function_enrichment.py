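"""EC handling, family categories, Fisher enrichment, percent reporting."""

import numpy as np
import pandas as pd
import pytest

from oracle import fisher_two_sided
from rlmscan.function_enrichment import (
    CATEGORIES,
    ECNumber,
    FGroupRecord,
    PathwayTable,
    classify_fgroup,
    cofactor_join,
    enrichment_test,
    filter_dashed,
    normalize_cofactor,
    percent_report,
)

EC = ECNumber.parse


def test_ec_parse_str_roundtrip_and_dashes():
    e = EC("2.4.1.-")
    assert e.dashed and str(e) == "2.4.1.-"
    assert not EC("1.5.1.3").dashed
    assert EC("1.5.1.3").sub_subclass == (1, 5, 1)
    with pytest.raises(ValueError):
        EC("1.2.3")
    with pytest.raises(ValueError):
        EC("9.1.1.1")  # class digit out of range


def test_filter_dashed_keeps_numeric_in_order():
    kept, removed = filter_dashed([EC("2.4.1.-"), EC("1.5.1.3")])
    assert [str(e) for e in kept] == ["1.5.1.3"] and removed == 1
    all_numeric = [EC("1.1.1.1"), EC("7.1.2.2")]
    kept, removed = filter_dashed(all_numeric)
    assert kept == all_numeric and removed == 0


def test_filter_dashed_on_mapping_sized_input():
    # 1472 assignments of which 94 are dashed -> 1378 mappable
    rng = np.random.default_rng(0)
    ecs = [ECNumber(int(rng.integers(1, 8)), 1, 1, i) for i in range(1378)]
    ecs += [ECNumber(int(rng.integers(1, 8)), 4, 1, None) for _ in range(94)]
    order = rng.permutation(len(ecs))
    shuffled = [ecs[i] for i in order]
    kept, removed = filter_dashed(shuffled)
    assert (len(shuffled), removed, len(kept)) == (1472, 94, 1378)
    # idempotent, never grows
    again, removed2 = filter_dashed(kept)
    assert again == kept and removed2 == 0


@pytest.mark.parametrize(
    "ecs, want",
    [
        (set(), "null"),
        ({"1.1.1.1"}, "homogeneous"),
        ({"1.1.1.1", "1.1.1.2"}, "heterogeneous_substrate"),
        ({"2.8.1.1", "3.1.3.48"}, "heterogeneous_reaction"),  # rhodanese pair
        ({"2.4.1.-"}, "homogeneous"),  # a dashed EC still counts as assigned
    ],
)
def test_classify_fgroup_categories(ecs, want):
    rec = FGroupRecord(fgroups=("f1",), ecs={EC(e) for e in ecs})
    assert classify_fgroup(rec) == want


def test_classification_partitions_random_records():
    rng = np.random.default_rng(5)
    for _ in range(200):
        n = int(rng.integers(0, 5))
        ecs = {
            ECNumber(
                int(rng.integers(1, 8)), int(rng.integers(1, 3)),
                int(rng.integers(1, 3)), int(rng.integers(1, 4)),
            )
            for _ in range(n)
        }
        got = classify_fgroup(FGroupRecord(fgroups=("x",), ecs=ecs))
        assert got in CATEGORIES  # total function, exactly one label


def test_fisher_example_against_enumeration_oracle():
    res = enrichment_test(class_rlm=1, class_all=12, group_rlm=10, group_all=24)
    # table [[1, 9], [11, 3]]
    assert res.table == ((1, 9), (11, 3))
    assert res.p_value == pytest.approx(fisher_two_sided(1, 9, 11, 3), rel=1e-9)
    assert res.p_value == pytest.approx(0.00276, abs=5e-5)


def test_fisher_matches_oracle_on_random_tables():
    rng = np.random.default_rng(2)
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 16, size=4))
        if (a + b) == 0 or (a + c) > (a + b + c + d):
            continue
        group_rlm, group_all = a + b, a + b + c + d
        if group_rlm == 0 or group_all == 0:
            continue
        res = enrichment_test(a, a + c, group_rlm, group_all)
        assert res.p_value == pytest.approx(fisher_two_sided(a, b, c, d), rel=1e-9)


def test_enrichment_trivial_and_errors():
    res = enrichment_test(5, 5, 20, 20)
    assert res.ratio == pytest.approx(1.0) and res.p_value == pytest.approx(1.0)
    with pytest.raises(ValueError):
        enrichment_test(1, 1, 0, 10)
    with pytest.raises(ValueError):
        enrichment_test(5, 20, 10, 20)  # negative cell


def test_random_rlm_assignment_gives_mean_ratio_one():
    rng = np.random.default_rng(9)
    n = 4000
    classes = rng.integers(0, 6, size=n)
    is_rlm = rng.random(n) < 0.3
    group_rlm, group_all = int(is_rlm.sum()), n
    weighted = 0.0
    for k in range(6):
        mask = classes == k
        res = enrichment_test(int(is_rlm[mask].sum()), int(mask.sum()), group_rlm, group_all)
        weighted += res.ratio * mask.sum() / n
    assert weighted == pytest.approx(1.0, abs=0.05)


@pytest.mark.parametrize(
    "part, whole, want",
    [
        (21, 31, 68),
        (16, 21, 76),
        (39, 44, 89),
        (28, 44, 64),
        (53, 190, 28),
        (48, 55, 87),
        (0, 7, 0),
        (1, 8, 13),   # 12.5 rounds half-UP
        (1, 40, 3),   # 2.5 rounds half-up, not to even
    ],
)
def test_percent_report_half_up(part, whole, want):
    assert percent_report(part, whole) == want


def test_percent_report_rejects_bad_input():
    with pytest.raises(ValueError):
        percent_report(1, 0)
    with pytest.raises(ValueError):
        percent_report(5, 4)


def test_pathway_table_rejects_dashed_members():
    with pytest.raises(ValueError):
        PathwayTable(members={"map00970": {EC("2.4.1.-")}})
    pt = PathwayTable(
        members={"map00230": {EC("2.7.4.3")}, "map00240": {EC("2.7.4.14")}},
        hierarchy={"map00230": ("nucleotide metabolism", "global metabolism"),
                   "map00240": ("nucleotide metabolism", "global metabolism")},
    )
    assert pt.class_members("nucleotide metabolism") == {EC("2.7.4.3"), EC("2.7.4.14")}


def test_cofactor_join_class_breakdown_and_hybrid_merge():
    # 44 iron-sulfur ECs: 28 oxidoreductases (class 1), 5 transferases,
    # 2 hydrolases, 9 lyases
    rows = []
    counts = {1: 28, 2: 5, 3: 2, 4: 9}
    i = 0
    for klass, n in counts.items():
        for _ in range(n):
            i += 1
            rows.append({"ec": f"{klass}.1.1.{i}", "cofactor": "[4Fe-4S]"})
    # hybrid cluster variants collapse
    rows.append({"ec": "1.7.99.1", "cofactor": "[Fe-O-S] hybrid variant 2"})
    rows.append({"ec": "1.2.7.4", "cofactor": "Ni-Fe-S cluster"})
    df = pd.DataFrame(rows)
    out = cofactor_join(df, records=[])
    by = out.set_index("cofactor")
    assert by.loc["[4Fe-4S]", "n_ecs"] == 44
    assert by.loc["[4Fe-4S]", "pct_class_1"] == 64  # 28 of 44
    assert by.loc["[4Fe-4S]", "pct_class_4"] == 20  # 9 of 44
    assert set(by.index) == {"[4Fe-4S]", "[Fe-O-S]", "[Ni-Fe-S]"}


def test_cofactor_join_empty_and_normalizer():
    assert cofactor_join(pd.DataFrame(columns=["ec", "cofactor"]), []).empty
    assert normalize_cofactor("FE-O-S hybrid") == "[Fe-O-S]"
    assert normalize_cofactor("Mg(2+)") == "Mg(2+)"
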
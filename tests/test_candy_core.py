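import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from candykano._round import round_half_up
from candykano.candy_core import (
    AggregateScores,
    IntervalThresholds,
    LikertCoding,
    SatisfactionProfile,
    aggregate,
    classify_all,
    classify_candy,
    classify_ratio,
    code_answer,
    compute_thresholds,
    count_categories,
    normalize,
)
from candykano.survey_io import ResponseSet

from conftest import make_record


# ------------------------------------------------------------ coding

def test_code_answer_rules():
    assert code_answer(5, "forward") == 5
    assert code_answer(1, "reverse") == 5
    assert code_answer(3, "forward") == code_answer(3, "reverse") == 3


def test_code_answer_domain_error():
    with pytest.raises(ValueError):
        code_answer(0, "forward")
    with pytest.raises(ValueError):
        code_answer(3, "sideways")


def test_coding_is_bijection_and_reverse_is_involution():
    fwd, rev = LikertCoding("forward"), LikertCoding("reverse")
    assert sorted(fwd.mapping.values()) == [1, 2, 3, 4, 5]
    assert sorted(rev.mapping.values()) == [1, 2, 3, 4, 5]
    for i in range(1, 6):
        assert rev.mapping[rev.mapping[i]] == i


# ------------------------------------------------------------ aggregate

def test_aggregate_two_identical_respondents(tiny_catalog):
    codes = [it.code for it in tiny_catalog]
    recs = [make_record(f"r{i}", codes, [5, 5, 5], [1, 1, 1]) for i in range(2)]
    a = aggregate(ResponseSet(catalog=tiny_catalog, records=recs))
    assert a.alpha_pos["A1"] == 10
    assert a.alpha_neg["A1"] == 10


def test_aggregate_neutral_respondent(tiny_catalog):
    codes = [it.code for it in tiny_catalog]
    recs = [make_record("r1", codes, [3, 3, 3], [3, 3, 3])]
    a = aggregate(ResponseSet(catalog=tiny_catalog, records=recs))
    assert all(a.alpha_pos[c] == 3 for c in codes)


def test_aggregate_matches_brute_force_double_loop(tiny_rs):
    a = aggregate(tiny_rs)
    for code in tiny_rs.codes:
        want_pos = sum(
            r.forward[code] for r in tiny_rs.records if r.forward[code] is not None
        )
        want_neg = sum(
            6 - r.reverse[code] for r in tiny_rs.records if r.reverse[code] is not None
        )
        assert a.alpha_pos[code] == want_pos
        assert a.alpha_neg[code] == want_neg


def test_aggregate_tracks_q_per_item(tiny_catalog):
    codes = [it.code for it in tiny_catalog]
    recs = [
        make_record("r1", codes, [5, None, 3], [1, 2, 3]),
        make_record("r2", codes, [4, 4, 4], [2, None, 2]),
    ]
    a = aggregate(ResponseSet(catalog=tiny_catalog, records=recs))
    assert a.q_pos == {"A1": 2, "B1": 1, "C1": 2}
    assert a.q_neg == {"A1": 2, "B1": 1, "C1": 2}


def test_aggregate_empty_errors(tiny_catalog):
    with pytest.raises(ValueError):
        aggregate(ResponseSet(catalog=tiny_catalog, records=[]))


# ------------------------------------------------------------ normalize

def _scores(codes, pos, neg):
    return AggregateScores(
        codes=list(codes),
        alpha_pos=dict(zip(codes, pos)),
        alpha_neg=dict(zip(codes, neg)),
        q_pos=dict.fromkeys(codes, 1),
        q_neg=dict.fromkeys(codes, 1),
    )


def test_normalize_simple_shares():
    p = normalize(_scores("abc", [2, 1, 1], [1, 1, 2]))
    assert [p.beta_pos[c] for c in "abc"] == [0.5, 0.25, 0.25]
    assert [p.beta_neg[c] for c in "abc"] == [0.25, 0.25, 0.5]


def test_normalize_uniform_gives_theta():
    p = normalize(_scores("abcd", [3, 3, 3, 3], [3, 3, 3, 3]))
    assert all(v == pytest.approx(0.25) for v in p.beta_pos.values())


def test_normalize_scale_invariance():
    p1 = normalize(_scores("abc", [2, 1, 1], [3, 1, 2]))
    p2 = normalize(_scores("abc", [14, 7, 7], [21, 7, 14]))
    assert p1.beta_pos == pytest.approx(p2.beta_pos)
    assert p1.beta_neg == pytest.approx(p2.beta_neg)


def test_normalize_rejects_nonpositive():
    with pytest.raises(ValueError):
        normalize(_scores("ab", [0, 1], [1, 1]))


@given(
    st.lists(st.floats(min_value=0.5, max_value=100), min_size=2, max_size=12),
    st.lists(st.floats(min_value=0.5, max_value=100), min_size=2, max_size=12),
)
def test_normalize_conservation(pos, neg):
    k = min(len(pos), len(neg))
    codes = [f"i{j}" for j in range(k)]
    p = normalize(_scores(codes, pos[:k], neg[:k]))
    assert sum(p.beta_pos.values()) == pytest.approx(1.0)
    assert sum(p.beta_neg.values()) == pytest.approx(1.0)
    assert all(v > 0 for v in p.beta_pos.values())


def test_monotonicity_raising_one_answer(tiny_rs):
    """Raising one respondent's forward answer on one item raises that
    item's beta+ and lowers every other item's beta+."""
    before = normalize(aggregate(tiny_rs))
    bumped = ResponseSet(catalog=tiny_rs.catalog, records=[r for r in tiny_rs.records])
    rec = bumped.records[3]
    assert rec.forward["A1"] < 5
    rec.forward = {**rec.forward, "A1": 5}
    after = normalize(aggregate(bumped))
    assert after.beta_pos["A1"] > before.beta_pos["A1"]
    for other in ("B1", "C1"):
        assert after.beta_pos[other] < before.beta_pos[other]


# ------------------------------------------------------------ thresholds

def test_thresholds_from_printed_profile(profile9):
    t = compute_thresholds(profile9, v=1 / 6)
    assert t.n == 46
    assert t.phi == pytest.approx(0.0249 - 0.0179)
    assert round_half_up(t.theta, 5) == 0.02174
    assert round_half_up(t.theta_low, 5) == 0.02057
    assert round_half_up(t.theta_up, 5) == 0.02291


def test_thresholds_degenerate_all_equal():
    p = SatisfactionProfile(
        codes=["a", "b"], beta_pos={"a": 0.5, "b": 0.5}, beta_neg={"a": 0.5, "b": 0.5}
    )
    t = compute_thresholds(p)
    assert t.phi == 0
    assert t.theta_low == t.theta == t.theta_up == 0.5


def test_thresholds_arithmetic():
    p = SatisfactionProfile(
        codes=[f"i{j}" for j in range(10)],
        beta_pos={f"i{j}": 0.1 for j in range(10)},
        beta_neg={f"i{j}": 0.1 for j in range(10)},
    )
    # override phi via a direct construction to check the +/- v*phi arithmetic
    t = IntervalThresholds(n=10, theta=0.1, phi=0.03, v=1 / 6,
                           theta_low=0.1 - 0.03 / 6, theta_up=0.1 + 0.03 / 6)
    assert t.theta_low == pytest.approx(0.095)
    assert t.theta_up == pytest.approx(0.105)


def test_thresholds_symmetry_invariant(profile9):
    t = compute_thresholds(profile9, v=0.25)
    assert t.theta - t.theta_low == pytest.approx(t.theta_up - t.theta)


# ------------------------------------------------------------ classifiers

THETA46 = 1 / 46


def test_classify_ratio_printed_examples():
    assert classify_ratio(0.0217, 0.0223, THETA46) == "M"  # C4
    assert classify_ratio(0.0220, 0.0213, THETA46) == "A"  # C10
    assert classify_ratio(0.0214, 0.0202, THETA46) == "I"  # E7


def test_classify_candy_printed_examples(profile9):
    t = compute_thresholds(profile9)
    assert classify_candy(0.0234, 0.0249, t) == "C"  # A5
    assert classify_candy(0.0225, 0.0231, t) == "M"  # A1
    assert classify_candy(0.0213, 0.0204, t) == "A"  # C5
    assert classify_candy(0.0221, 0.0224, t) == "O"  # A2
    assert classify_candy(0.0203, 0.0202, t) == "I"  # A3


def test_classify_candy_center_point_is_O(profile9):
    t = compute_thresholds(profile9)
    assert classify_candy(t.theta, t.theta, t) == "O"


def _oracle_candy(p, n, t):
    """Independent 9-cell region oracle: each beta is below, inside, or
    above the interval; the 3x3 cell determines the label."""
    def zone(x):
        if x < t.theta_low:
            return "below"
        if x > t.theta_up:
            return "above"
        return "in"

    cell = (zone(p), zone(n))
    table = {
        ("in", "in"): "O",
        ("above", "above"): "C",
        ("below", "below"): "I",
        ("above", "below"): "A",
        ("above", "in"): "A",
        ("in", "below"): "A",
        ("below", "above"): "M",
        ("in", "above"): "M",
        ("below", "in"): "M",
    }
    return table[cell]


def test_classify_candy_matches_region_oracle_on_dense_grid(profile9):
    t = compute_thresholds(profile9)
    grid = np.linspace(1e-6, 2 * t.theta, 101)
    for p in grid:
        for n in grid:
            assert classify_candy(p, n, t) == _oracle_candy(p, n, t)


def test_classify_candy_total_on_boundaries(profile9):
    t = compute_thresholds(profile9)
    specials = [t.theta_low, t.theta, t.theta_up, t.theta_low / 2, 2 * t.theta_up]
    for p in specials:
        for n in specials:
            assert classify_candy(p, n, t) in set("CMOAI")


def test_degenerate_interval_matches_ratio(profile9):
    """With v=0 the interval collapses to theta: candy C coincides with the
    ratio O region, and A/M/I regions agree (off the measure-zero boundary)."""
    t0 = compute_thresholds(profile9, v=0.0)
    grid = np.linspace(1e-6, 2 * t0.theta, 80)
    for p in grid:
        for n in grid:
            if p == t0.theta or n == t0.theta:
                continue
            candy = classify_candy(p, n, t0)
            ratio = classify_ratio(p, n, t0.theta)
            assert candy == ("C" if ratio == "O" else ratio)


# ------------------------------------------------------------ full-table

def test_classify_all_ratio_reproduces_printed_column(table9, profile9):
    result = classify_all(profile9, method="ratio")
    printed = dict(zip(table9.code, table9.label_ratio))
    assert result.labels == printed


def test_classify_all_candy_reproduces_45_of_46(table9, profile9):
    result = classify_all(profile9, method="candy", params={"v": 1 / 6})
    printed = dict(zip(table9.code, table9.label_candy))
    mismatches = [c for c in printed if result.labels[c] != printed[c]]
    assert mismatches == ["D2"]  # rounding artifact of the 4-decimal betas
    assert result.labels["D2"] == "O" and printed["D2"] == "A"


def test_classify_all_uniform_profile_all_O():
    codes = [f"i{j}" for j in range(8)]
    p = SatisfactionProfile(
        codes=codes,
        beta_pos=dict.fromkeys(codes, 1 / 8),
        beta_neg=dict.fromkeys(codes, 1 / 8),
    )
    result = classify_all(p, method="candy")
    assert set(result.labels.values()) == {"O"}


def test_classify_all_unknown_method(profile9):
    with pytest.raises(ValueError):
        classify_all(profile9, method="fuzzy")


def test_count_categories_candy_counts(profile9):
    res = classify_all(profile9, method="candy")
    counts = count_categories(res)
    assert counts["C"] == 5
    assert counts["M"] == 7
    assert counts["I"] == 7


def test_count_categories_ratio_counts(profile9):
    counts = count_categories(classify_all(profile9, method="ratio"))
    assert counts == {"O": 21, "I": 15, "M": 4, "A": 6}


def test_count_categories_single_item():
    p = SatisfactionProfile(codes=["x"], beta_pos={"x": 1.0}, beta_neg={"x": 1.0})
    assert count_categories(classify_all(p, method="ratio")) == {"I": 1}


def test_count_categories_sum_to_n(profile9):
    for method in ("ratio", "candy"):
        assert sum(count_categories(classify_all(profile9, method)).values()) == 46
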
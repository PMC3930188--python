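import numpy as np
import pandas as pd
import pytest

from cidprognet.core_io import CohortDefinition, ExpressionMatrix
from cidprognet.prognostic_screen import (
    assign_feature_type,
    consensus_signature,
    coxph_fit,
    dichotomize_top_decile,
    km_estimate,
    logrank_test,
    screen_probes,
)


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,expected_high", [(10, 1), (100, 10), (181, 18), (95, 10)])
def test_top_decile_group_size_is_rank_based(rng, n, expected_high):
    labels = dichotomize_top_decile(rng.normal(size=n))
    assert (labels == "high").sum() == expected_high


def test_top_decile_selects_largest_values(rng):
    v = rng.normal(size=50)
    labels = dichotomize_top_decile(v)
    assert v[labels == "high"].min() >= v[labels == "low"].max()


def test_tied_values_warn_and_stay_deterministic():
    v = np.ones(20)
    with pytest.warns(UserWarning, match="tie"):
        labels = dichotomize_top_decile(v)
    assert (labels == "high").sum() == 2
    assert labels[-2:].tolist() == ["high", "high"]  # stable id-order tail


def test_small_cohort_rejected():
    with pytest.raises(ValueError, match="too small"):
        dichotomize_top_decile(np.arange(9))


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_fixture_with_censoring():
    """Product limit for times (6,7,10,15), events (1,0,1,1)."""
    curve = km_estimate([6, 7, 10, 15], [1, 0, 1, 1])
    assert curve.event_times.tolist() == [6, 10, 15]
    assert curve.survival == pytest.approx([0.75, 0.375, 0.0])
    assert curve.at_risk.tolist() == [4, 2, 1]


def test_km_no_events_stays_at_one():
    curve = km_estimate([5, 8, 12], [0, 0, 0])
    assert curve.event_times.size == 0
    assert curve.survival_at(100.0) == 1.0


def test_km_all_events_matches_empirical_survivor():
    curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    assert curve.survival == pytest.approx([0.75, 0.5, 0.25, 0.0])


def test_km_rejects_bad_input():
    with pytest.raises(ValueError):
        km_estimate([], [])
    with pytest.raises(ValueError, match="positive"):
        km_estimate([0.0, 1.0], [1, 1])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank_bruteforce(time, event, group):
    """Independent O/E/V tabulation with hypergeometric variance."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    g = np.asarray(group)
    levels = np.unique(g)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        n1 = (at_risk & (g == levels[0])).sum()
        d1 = ((time == t) & (event == 1) & (g == levels[0])).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_identical_groups_is_null():
    t = [3.0, 5.0, 7.0, 9.0] * 2
    e = [1, 0, 1, 1] * 2
    g = ["A"] * 4 + ["B"] * 4
    stat, p = logrank_test(t, e, g)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_hypergeometric_oracle(rng):
    t = [2.0, 4.0, 4.0, 6.0, 7.0, 9.0, 11.0, 14.0]
    e = [1, 1, 0, 1, 1, 0, 1, 1]
    g = ["A", "B", "A", "B", "A", "B", "A", "B"]
    stat, p = logrank_test(t, e, g)
    oracle = logrank_bruteforce(t, e, g)
    assert stat == pytest.approx(oracle, rel=1e-9)
    from scipy import stats as sps

    assert p == pytest.approx(sps.chi2.sf(oracle, 1), rel=1e-9)


def test_logrank_separated_groups_is_significant():
    t = list(range(1, 21)) + list(range(100, 120))
    e = [1] * 40
    g = ["early"] * 20 + ["late"] * 20
    _, p = logrank_test(t, e, g)
    assert p < 0.01


def test_logrank_label_swap_invariance(rng):
    t = rng.exponential(10, size=30)
    e = rng.integers(0, 2, size=30)
    e[0] = 1
    g = np.where(rng.random(30) < 0.5, "A", "B")
    s1, _ = logrank_test(t, e, g)
    s2, _ = logrank_test(t, e, np.where(g == "A", "B", "A"))
    assert s1 == pytest.approx(s2)


def test_logrank_edge_cases():
    with pytest.raises(ValueError, match="2"):
        logrank_test([1, 2], [1, 1], ["A", "A"])
    with pytest.warns(UserWarning, match="no events"):
        _, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])
    assert p == 1.0


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_screen_constant_probe_propagates_tie_warning(rng):
    n = 20
    ids = [f"s{i}" for i in range(n)]
    expr = ExpressionMatrix(
        ["flat", "var"], ids,
        np.vstack([np.zeros(n), rng.normal(size=n)]),
    )
    surv = pd.DataFrame(
        {"surv_time": rng.exponential(20, n) + 0.1, "event": rng.integers(0, 2, n)},
        index=ids,
    )
    surv.iloc[0, 1] = 1
    cohorts = {"all": CohortDefinition("all", tuple(ids))}
    with pytest.warns(UserWarning, match="tie"):
        calls = screen_probes(expr, ["flat", "var"], cohorts, surv)
    assert set(calls["call"]) <= {"S", "NS"}
    assert len(calls) == 2


def test_screen_small_cohort_marked_unavailable(rng):
    ids = [f"s{i}" for i in range(6)]
    expr = ExpressionMatrix(["p"], ids, rng.normal(size=(1, 6)))
    surv = pd.DataFrame(
        {"surv_time": np.ones(6), "event": np.ones(6, int)}, index=ids
    )
    with pytest.warns(UserWarning, match="unavailable"):
        calls = screen_probes(expr, ["p"], {"tiny": CohortDefinition("tiny", tuple(ids))}, surv)
    assert (calls["call"] == "unavailable").all()


# ---------------------------------------------------------------------------
# feature typing / consensus
# ---------------------------------------------------------------------------

TRUTH_TABLE = [
    (("S", "S", "S"), "I"),
    (("NS", "S", "S"), "II"),
    (("S", "NS", "S"), "III"),
    (("NS", "NS", "S"), "IV"),
    (("S", "S", "NS"), "untyped"),
    (("NS", "S", "NS"), "untyped"),
    (("S", "NS", "NS"), "untyped"),
    (("NS", "NS", "NS"), "untyped"),
]


@pytest.mark.parametrize("triple,expected", TRUTH_TABLE)
def test_feature_type_truth_table(triple, expected):
    """All 8 S/NS triples: 4 map to types I-IV, 4 stay untyped."""
    calls = {"91A": triple[0], "181A": triple[1], "90A": triple[2]}
    got = assign_feature_type(calls, "90A", "p")
    assert got.feature_type == expected


def test_feature_type_role_mapping_depends_on_network_cohort():
    calls = {"91A": "S", "181A": "NS", "90A": "S"}
    assert assign_feature_type(calls, "90A").feature_type == "III"
    assert assign_feature_type(calls, "181A").feature_type == "untyped"


def test_feature_type_requires_all_calls():
    with pytest.raises(ValueError, match="missing"):
        assign_feature_type({"91A": "S", "90A": "S"}, "90A")
    with pytest.raises(ValueError, match="invalid call"):
        assign_feature_type({"91A": "S", "181A": "maybe", "90A": "S"}, "90A")


def test_consensus_is_sorted_intersection():
    assert consensus_signature(["c", "a", "b"], ["b", "d", "c"]) == ["b", "c"]
    with pytest.warns(UserWarning, match="empty"):
        assert consensus_signature(["a"], ["b"]) == []


# ---------------------------------------------------------------------------
# Cox PH
# ---------------------------------------------------------------------------

def test_coxph_recovers_hazard_direction(rng):
    n = 300
    x = rng.integers(0, 2, size=n)
    t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
    covs = pd.DataFrame({"x": x})
    fit = coxph_fit(t, np.ones(n, int), covs, mode="univariate")
    row = fit.iloc[0]
    assert row["converged"]
    assert row["ci_lower"] < 2.0 < row["ci_upper"]


def test_coxph_univariate_vs_multivariate_shapes(rng):
    n = 120
    covs = pd.DataFrame(
        {"a": rng.normal(size=n), "b": rng.integers(0, 2, size=n)}
    )
    t = rng.exponential(20, size=n)
    e = np.ones(n, int)
    uni = coxph_fit(t, e, covs, mode="univariate")
    multi = coxph_fit(t, e, covs, mode="multivariate")
    assert list(uni["covariate"]) == ["a", "b"] == list(multi["covariate"])


def test_coxph_zero_events_rejected(rng):
    covs = pd.DataFrame({"x": rng.normal(size=20)})
    with pytest.raises(ValueError, match="events"):
        coxph_fit(np.ones(20), np.zeros(20, int), covs)
    with pytest.raises(ValueError, match="mode"):
        coxph_fit(np.ones(20), np.ones(20, int), covs, mode="bayes")
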
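import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cidprognet.core_io import CohortDefinition, ExpressionMatrix
from cidprognet.dependence_network import (
    _perm_matrix,
    bivariate_cid,
    cid,
    cid_permutation_pvalues,
    classify_mechanism,
    full_network,
    gpcc,
    make_subgroups,
    network_pools,
    permutation_pvalue,
    univariate_network,
)


def cid_bruteforce(y, groups):
    """Independent double-loop ECDF implementation of CID/subCID."""
    y = list(y)
    n = len(y)
    pooled = [sum(yi <= yj for yi in y) / n for yj in y]
    subcids, total = [], 0.0
    for g in groups:
        fk = [sum(y[i] <= yj for i in g) / len(g) for yj in y]
        s = 3.0 / n * sum((a - b) ** 2 for a, b in zip(fk, pooled))
        subcids.append(s)
        total += len(g) / n * s
    return total, subcids


# ---------------------------------------------------------------------------
# subgrouping
# ---------------------------------------------------------------------------

def test_even_subgroups():
    scheme = make_subgroups(np.arange(100), 10)
    assert scheme.sizes.tolist() == [10] * 10


def test_remainder_goes_to_top_expression_groups(rng):
    scheme = make_subgroups(rng.normal(size=91), 10)
    assert scheme.sizes.tolist() == [9] * 9 + [10]


def test_subgroups_too_small_errors():
    with pytest.raises(ValueError, match="smaller K"):
        make_subgroups(np.arange(15), 10)
    with pytest.raises(ValueError, match="K"):
        make_subgroups(np.arange(15), 1)


def test_tied_conditioning_values_split_by_stable_order():
    scheme = make_subgroups([1.0, 1.0, 1.0, 1.0], 2)
    assert scheme.groups[0].tolist() == [0, 1]
    assert scheme.groups[1].tolist() == [2, 3]


def test_groups_are_ordered_by_conditioning_level(rng):
    v = rng.normal(size=40)
    scheme = make_subgroups(v, 4)
    maxima = [v[g].max() for g in scheme.groups]
    minima = [v[g].min() for g in scheme.groups]
    assert all(maxima[k] <= minima[k + 1] for k in range(3))


# ---------------------------------------------------------------------------
# CID
# ---------------------------------------------------------------------------

def test_cid_hand_example_perfect_monotone():
    """N=4, K=2, target ordered with the TF: CID = 0.28125 in both blocks."""
    scheme = make_subgroups([1.0, 2.0, 3.0, 4.0], 2)
    res = cid([10.0, 20.0, 30.0, 40.0], scheme)
    assert res.cid == pytest.approx(0.28125, abs=1e-15)
    assert res.subcid == pytest.approx([0.28125, 0.28125], abs=1e-15)


def test_cid_constant_target_is_zero():
    scheme = make_subgroups(np.arange(10), 2)
    res = cid(np.full(10, 3.3), scheme)
    assert res.cid == 0.0
    assert np.all(res.subcid == 0.0)


def test_cid_invariant_under_monotone_transform(rng):
    y = rng.normal(size=30)
    scheme = make_subgroups(rng.normal(size=30), 3)
    assert cid(np.exp(y), scheme).cid == cid(y, scheme).cid


@given(st.integers(4, 12), st.integers(0, 500))
def test_cid_matches_bruteforce_oracle(n, seed):
    """Exact agreement with the explicit double-loop ECDF formula (ties too)."""
    r = np.random.default_rng(seed)
    y = r.integers(0, 5, size=n).astype(float)  # heavy ties on purpose
    scheme = make_subgroups(r.normal(size=n), 2)
    res = cid(y, scheme)
    oracle_total, oracle_sub = cid_bruteforce(y, [g.tolist() for g in scheme.groups])
    assert res.cid == pytest.approx(oracle_total, abs=1e-12)
    assert res.subcid == pytest.approx(oracle_sub, abs=1e-12)


@given(st.integers(0, 500), st.integers(2, 5))
def test_cid_bounds_and_weighted_decomposition(seed, K):
    r = np.random.default_rng(seed)
    n = int(r.integers(2 * K, 60))
    y = r.normal(size=n)
    scheme = make_subgroups(r.normal(size=n), K)
    res = cid(y, scheme)
    assert np.all(res.subcid >= 0.0) and np.all(res.subcid < 1.0)
    assert 0.0 <= res.cid < 1.0
    recomposed = float(np.sum(scheme.sizes / n * res.subcid))
    assert res.cid == pytest.approx(recomposed, abs=1e-12)


# ---------------------------------------------------------------------------
# GPCC
# ---------------------------------------------------------------------------

def test_gpcc_linear_relation_is_one(rng):
    x = rng.normal(size=20)
    r, p = gpcc(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p < 1e-12


def test_gpcc_hand_example():
    r, _ = gpcc([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
    assert r == pytest.approx(0.5)


def test_gpcc_constant_vector_flagged_not_crashed():
    r, p = gpcc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(r) and np.isnan(p)


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

def test_extreme_observed_statistic_gives_minimal_pvalue():
    v = np.arange(40, dtype=float)
    scheme = make_subgroups(v, 2)
    p = permutation_pvalue(lambda y, s: cid(y, s).cid, v, scheme, B=99, seed=1)
    assert p == pytest.approx(1 / 100)


def test_constant_target_pvalue_is_one():
    scheme = make_subgroups(np.arange(40, dtype=float), 2)
    p = permutation_pvalue(
        lambda y, s: cid(y, s).cid, np.full(40, 2.0), scheme, B=99, seed=1
    )
    assert p == 1.0


def test_small_B_rejected():
    scheme = make_subgroups(np.arange(40, dtype=float), 2)
    with pytest.raises(ValueError, match="B"):
        permutation_pvalue(lambda y, s: cid(y, s).cid, np.arange(40.0), scheme, B=50)


def test_fast_engine_equals_generic_permutation_test(rng):
    """The O(BN) engine and the direct statistic-permutation agree exactly."""
    n = 36
    P = _perm_matrix(n, 199, 9)
    scheme = make_subgroups(rng.normal(size=n), 3)
    for _ in range(5):
        y = np.round(rng.normal(size=n), 1)  # ties included
        p_gen = permutation_pvalue(
            lambda yy, ss: cid(yy, ss).cid, y, scheme, perm_matrix=P
        )
        p_fast = cid_permutation_pvalues(y[None, :], scheme, perm_matrix=P)[0]
        assert p_fast == pytest.approx(p_gen, abs=1e-12)


# ---------------------------------------------------------------------------
# univariate network
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_network():
    from cidprognet.synthetic_cohort import PlantedEdge, SyntheticConfig, generate_cohort

    edges = (
        PlantedEdge("lin", "linear", 1.5, 1.0),
        PlantedEdge("nonmono", "nonmonotone", 1.5, 1.0),
    )
    cfg = SyntheticConfig(n_probes=30, planted_edges=edges,
                          signature_probes=("lin",), seed=3)
    expr, samples, truth = generate_cohort(cfg)
    cohort = CohortDefinition("181A", tuple(s.sample_id for s in samples))
    net = univariate_network(expr, "TF1", cohort, B=199, seed=3)
    return net


def test_planted_targets_enter_network_by_the_right_arm(tiny_network):
    frame = tiny_network.frame.set_index("probe_id")
    lin = frame.loc["lin"]
    assert lin["in_network"] and lin["p_gpcc"] <= 0.05
    nm = frame.loc["nonmono"]
    assert nm["in_network"] and nm["sig_cid"]
    assert abs(nm["gpcc"]) < 0.2


def test_union_rule_contains_both_arms(tiny_network):
    frame = tiny_network.frame
    assert (frame["in_network"] == (frame["sig_cid"] | frame["sig_gpcc"])).all()
    assert frame.loc[frame["sig_cid"], "in_network"].all()
    assert frame.loc[frame["sig_gpcc"], "in_network"].all()


def test_network_excludes_tf_and_requires_cohort_size(tiny_network):
    assert "TF1" not in set(tiny_network.frame["probe_id"])
    expr = ExpressionMatrix(["TF1", "a"], [f"s{i}" for i in range(12)],
                            np.random.default_rng(0).normal(size=(2, 12)))
    with pytest.raises(ValueError, match="2K"):
        univariate_network(expr, "TF1", [f"s{i}" for i in range(12)], K=10, B=99)


# ---------------------------------------------------------------------------
# bivariate CID and mechanism pools
# ---------------------------------------------------------------------------

def test_bivariate_with_identical_tfs_degenerates_to_univariate(rng):
    tf = rng.normal(size=40)
    y = rng.normal(size=40)
    uni = cid(y, make_subgroups(tf, 4))
    biv, scheme = bivariate_cid(y, tf, tf, K=4)
    assert biv.cid == uni.cid
    assert np.array_equal(biv.subcid, uni.subcid)
    assert scheme.groups[0].tolist() == make_subgroups(tf, 4).groups[0].tolist()


def test_bivariate_constant_target_is_zero(rng):
    biv, _ = bivariate_cid(np.full(40, 1.0), rng.normal(size=40),
                           rng.normal(size=40), K=4)
    assert biv.cid == 0.0


def test_joint_and_target_peaks_in_top_joint_subgroups():
    """An AND-gated target is strongest where both TFs are high.

    The gate saturates over the top joint blocks (nearly every sample there
    has both TFs above median), so the highest subCID lives in the top
    blocks of the joint conditioning score.
    """
    rng = np.random.default_rng(12)
    from cidprognet.synthetic_cohort import simulate_target

    tf1 = rng.normal(size=181)
    tf2 = rng.normal(size=181)
    y = simulate_target(tf1, tf2, "joint_and", 1.5, 1.0, rng)
    res, scheme = bivariate_cid(y, tf1, tf2, K=10)
    assert res.argmax_subgroup >= 9
    assert res.subcid[8:].sum() > res.subcid[:5].sum()


@pytest.mark.parametrize(
    "p1,p2,pj,expected",
    [
        (0.01, 0.01, 0.01, "M1"),
        (0.01, 0.50, 0.01, "M2"),
        (0.50, 0.01, 0.01, "M3"),
        (0.50, 0.50, 0.01, "M4"),
        (0.01, 0.01, 0.50, "none"),
    ],
)
def test_mechanism_classification(p1, p2, pj, expected):
    assert classify_mechanism(p1, p2, pj, alpha=0.05) == expected


def test_mechanism_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        classify_mechanism(0.0, 0.5, 0.5)


def test_pool_set_algebra():
    pools = network_pools({"a", "b", "c"}, {"b", "c", "d"}, {"b": "M1"})
    assert pools["U"] == {"c"}
    assert pools["M1"] == {"b"}
    pools = network_pools({"a", "b", "c"}, {"b", "c", "d"}, {})
    assert pools["U"] == {"b", "c"}
    assert full_network(pools) == {"b", "c"}


def test_pools_match_bruteforce_on_random_toy(rng):
    probes = [f"p{i}" for i in range(50)]
    net1 = {p for p in probes if rng.random() < 0.4}
    net2 = {p for p in probes if rng.random() < 0.4}
    mech = {}
    for p in probes:
        label = rng.choice(["none", "M1", "M2", "M3", "M4"])
        if label != "none":
            mech[p] = label
    pools = network_pools(net1, net2, mech)
    # independent recount
    for m in ("M1", "M2", "M3", "M4"):
        assert pools[m] == {p for p, l in mech.items() if l == m}
    classified = set(mech)
    assert pools["U"] == (net1 & net2) - classified
    # pools pairwise disjoint, union = full network
    all_pools = [pools[m] for m in ("U", "M1", "M2", "M3", "M4")]
    assert sum(len(s) for s in all_pools) == len(set().union(*all_pools))
    assert full_network(pools) == set().union(*all_pools)
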
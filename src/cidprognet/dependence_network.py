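"""CID/subCID dependence statistics and the CIDUGPCC union network.

The coefficient of intrinsic dependence (CID) quantifies how strongly the
distribution of a target gene shifts across subgroups of samples defined by
a conditioning transcription factor's expression.  Samples are split into K
contiguous rank blocks of the TF (the "1/10th subgrouping", K=10 by
default).  Within subgroup k with members G_k,

    subCID_k = (3/N) * sum_j (F_k(y_j) - F(y_j))^2
    CID      = sum_k (n_k/N) * subCID_k

where F and F_k are the pooled and subgroup empirical CDFs of the target,
both evaluated at all N observed target values.  Both quantities lie in
[0, 1) and are invariant under strictly monotone transforms of the target.

A probe enters the univariate TF network if it is significant by the CID
permutation test *or* by the Pearson correlation (GPCC) t-test — the union
rule ("CIDUGPCC").  For a TF pair, CID on subgroups of a joint conditioning
score (mean of the two TF rank-percentiles) yields a multivariate network
whose probes are partitioned into combinatorial mechanism pools U, M1-M4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import CohortDefinition, ExpressionMatrix

__all__ = [
    "SubgroupScheme",
    "CidResult",
    "DependenceResult",
    "NetworkResult",
    "make_subgroups",
    "cid",
    "gpcc",
    "permutation_pvalue",
    "cid_permutation_pvalues",
    "univariate_network",
    "joint_conditioning_score",
    "bivariate_cid",
    "bivariate_network",
    "classify_mechanism",
    "network_pools",
    "full_network",
]

MECHANISMS = ("U", "M1", "M2", "M3", "M4")


# ---------------------------------------------------------------------------
# subgrouping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupScheme:
    """K contiguous rank blocks of the conditioning variable.

    ``groups`` holds 0-based sample positions, ordered from the lowest to the
    highest conditioning block; sizes differ by at most one, with remainder
    members assigned to the highest-expression blocks (the analysis
    privileges the top decile).
    """

    K: int
    groups: tuple
    n: int

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups], dtype=np.int64)

    @property
    def labels(self) -> np.ndarray:
        """Group index (0-based) per sample position."""
        lab = np.empty(self.n, dtype=np.int64)
        for k, g in enumerate(self.groups):
            lab[g] = k
        return lab


def make_subgroups(values: Sequence[float], K: int = 10) -> SubgroupScheme:
    """Split samples into K contiguous rank blocks of ``values``.

    Ties are broken by stable input (sample-id) order.  When N mod K = r > 0
    the r extra members go one each to the highest blocks.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("conditioning values contain missing entries")
    n = v.size
    if K < 2:
        raise ValueError("K must be at least 2")
    if n < 2 * K:
        raise ValueError(
            f"N={n} is too small for K={K} subgroups (need N >= 2K); use a smaller K"
        )
    order = np.argsort(v, kind="stable")
    base, r = divmod(n, K)
    sizes = [base] * (K - r) + [base + 1] * r
    groups, start = [], 0
    for s in sizes:
        groups.append(np.sort(order[start:start + s]))
        start += s
    return SubgroupScheme(K=K, groups=tuple(groups), n=n)


# ---------------------------------------------------------------------------
# CID / subCID
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CidResult:
    cid: float
    subcid: np.ndarray

    @property
    def argmax_subgroup(self) -> int:
        """1-based index of the subgroup with the highest subCID."""
        return int(np.argmax(self.subcid)) + 1


def cid(target_values: Sequence[float], scheme: SubgroupScheme) -> CidResult:
    """CID and the per-subgroup subCID vector of a target given a scheme."""
    y = np.asarray(target_values, dtype=float)
    if y.size == 0:
        raise ValueError("empty target vector")
    if y.size != scheme.n:
        raise ValueError("scheme does not cover the target samples")
    if np.isnan(y).any():
        raise ValueError("target contains missing values; reject the probe instead")
    n = y.size
    ys = np.sort(y, kind="stable")
    pooled = np.searchsorted(ys, y, side="right") / n
    subcid = np.empty(scheme.K)
    for k, g in enumerate(scheme.groups):
        yk = np.sort(y[g], kind="stable")
        fk = np.searchsorted(yk, y, side="right") / len(g)
        subcid[k] = 3.0 / n * np.sum((fk - pooled) ** 2)
    total = float(np.sum(scheme.sizes / n * subcid))
    return CidResult(cid=total, subcid=subcid)


def gpcc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value.

    Returns ``(nan, nan)`` (the undefined flag) when either vector is
    constant; such probes can still enter a network through the CID arm.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("vectors differ in length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations for GPCC")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return (float("nan"), float("nan"))
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

def _perm_matrix(n: int, B: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(B)], dtype=np.int64)


def permutation_pvalue(
    statistic_fn: Callable[[np.ndarray, SubgroupScheme], float],
    target_values: Sequence[float],
    scheme: SubgroupScheme,
    B: int = 999,
    seed: int | None = 0,
    perm_matrix: np.ndarray | None = None,
) -> float:
    """One-sided permutation p-value of a dependence statistic.

    The target is permuted against the fixed subgrouping scheme;
    p = (1 + #{stat(permuted) >= stat(observed)}) / (B + 1).
    """
    y = np.asarray(target_values, dtype=float)
    if perm_matrix is None:
        if B < 99:
            raise ValueError("B must be at least 99")
        perm_matrix = _perm_matrix(y.size, B, seed)
    obs = statistic_fn(y, scheme)
    tol = 1e-9 * (1.0 + abs(obs))
    count = sum(
        1 for row in perm_matrix if statistic_fn(y[row], scheme) >= obs - tol
    )
    return (1 + count) / (perm_matrix.shape[0] + 1)


# --- fast engine ------------------------------------------------------------
#
# Only the quadratic part of CID varies under permutation of the subgroup
# labels.  With cg_i = #{j : y_j >= y_i},
#
#     CID = (3/N^2) * T + const(y),
#     T   = sum_k (1/n_k) sum_{i,i' in G_k} min(cg_i, cg_i'),
#
# and the pairwise min over a group equals sum_t cg_(t) * (2t - 1) with the
# group's members taken in ascending target order.  The permutation null of
# CID is therefore the null of T, computed in O(B*N) per probe.

def _perm_T_python(labels_perm, orders, cgs, sizes):
    n_lab, n = labels_perm.shape
    n_probes = orders.shape[0]
    K = sizes.shape[0]
    out = np.empty((n_probes, n_lab))
    onehot = np.empty((n_lab, n, K), dtype=np.int16)
    for p in range(n_probes):
        lab_sorted = labels_perm[:, orders[p]]
        for k in range(K):
            onehot[:, :, k] = lab_sorted == k
        counts = np.cumsum(onehot, axis=1, dtype=np.int32)
        contrib = onehot * (2 * counts - 1) * cgs[p][None, :, None]
        out[p] = (contrib.sum(axis=1) / sizes[None, :]).sum(axis=1)
    return out


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=False)
    def _perm_T_numba(labels_perm, orders, cgs, sizes):  # pragma: no cover
        n_lab, n = labels_perm.shape
        n_probes = orders.shape[0]
        K = sizes.shape[0]
        out = np.empty((n_probes, n_lab))
        counts = np.zeros(K, dtype=np.int64)
        acc = np.zeros(K, dtype=np.float64)
        for p in range(n_probes):
            for b in range(n_lab):
                counts[:] = 0
                acc[:] = 0.0
                for j in range(n):
                    k = labels_perm[b, orders[p, j]]
                    counts[k] += 1
                    acc[k] += (2 * counts[k] - 1) * cgs[p, j]
                t = 0.0
                for k in range(K):
                    t += acc[k] / sizes[k]
                out[p, b] = t
        return out

    _perm_T = _perm_T_numba
except Exception:  # pragma: no cover
    _perm_T = _perm_T_python


def cid_permutation_pvalues(
    target_matrix: np.ndarray,
    scheme: SubgroupScheme,
    B: int = 999,
    seed: int | None = 0,
    perm_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Permutation p-values of CID for many probes against one scheme.

    All probes share one permutation-index matrix (one seed, one matrix),
    which keeps genome-wide runs reproducible and fast.  Equivalent to
    :func:`permutation_pvalue` applied probe by probe with the same matrix.
    """
    Y = np.atleast_2d(np.asarray(target_matrix, dtype=float))
    n = scheme.n
    if Y.shape[1] != n:
        raise ValueError("target matrix does not match scheme sample count")
    if perm_matrix is None:
        if B < 99:
            raise ValueError("B must be at least 99")
        perm_matrix = _perm_matrix(n, B, seed)
    B_eff = perm_matrix.shape[0]
    g = scheme.labels
    # labels under permutation b of the *target*: member multiset of group k
    # becomes perm_b[G_k], i.e. labels scattered through the inverse.
    labels_perm = np.empty((B_eff + 1, n), dtype=np.int64)
    labels_perm[0] = g
    labels_perm[1:] = g[np.argsort(perm_matrix, axis=1)]

    orders = np.argsort(Y, axis=1, kind="stable").astype(np.int64)
    # cg at sorted positions: #{j : y_j >= y_(t)} (tie-aware)
    cgs = np.empty_like(Y)
    for p in range(Y.shape[0]):
        ys = Y[p, orders[p]]
        cgs[p] = n - np.searchsorted(ys, ys, side="left")

    T = _perm_T(labels_perm, orders, cgs, scheme.sizes.astype(np.int64))
    obs = T[:, 0]
    tol = 1e-9 * (1.0 + np.abs(obs))
    count = (T[:, 1:] >= (obs - tol)[:, None]).sum(axis=1)
    return (1 + count) / (B_eff + 1)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DependenceResult:
    """Per probe x TF(s) dependence summary."""

    probe_id: str
    tf_ids: tuple[str, ...]
    cid: float
    subcid: np.ndarray
    argmax_subgroup: int
    gpcc: float
    p_cid: float
    p_gpcc: float
    in_network: bool
    mechanism: str = "none"


@dataclass
class NetworkResult:
    """Result of a univariate (one TF) or multivariate (TF pair) network run."""

    tf_ids: tuple[str, ...]
    cohort_name: str
    alpha: float
    B: int
    K: int
    seed: int | None
    fdr_method: str
    frame: pd.DataFrame
    subcid: np.ndarray
    scheme: SubgroupScheme = field(repr=False, default=None)
    skipped_probes: tuple[str, ...] = ()

    def members(self) -> set[str]:
        return set(self.frame.loc[self.frame["in_network"], "probe_id"])

    def probe_universe(self) -> set[str]:
        return set(self.frame["probe_id"])

    def result_for(self, probe_id: str) -> DependenceResult:
        idx = self.frame.index[self.frame["probe_id"] == probe_id]
        if len(idx) == 0:
            raise KeyError(probe_id)
        row = self.frame.loc[idx[0]]
        return DependenceResult(
            probe_id=probe_id,
            tf_ids=self.tf_ids,
            cid=float(row["cid"]),
            subcid=self.subcid[idx[0]],
            argmax_subgroup=int(row["argmax_subgroup"]),
            gpcc=float(row["gpcc"]),
            p_cid=float(row["p_cid"]),
            p_gpcc=float(row["p_gpcc"]),
            in_network=bool(row["in_network"]),
            mechanism=str(row.get("mechanism", "none")),
        )

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(1, "tf_ids", ",".join(self.tf_ids))
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _cohort_ids(cohort) -> list[str]:
    if isinstance(cohort, CohortDefinition):
        return list(cohort.sample_ids)
    return list(cohort)


def _cohort_name(cohort) -> str:
    return cohort.name if isinstance(cohort, CohortDefinition) else "custom"


def _collect_targets(expr: ExpressionMatrix, sample_ids, exclude: set[str]):
    """Target probes with complete data in the cohort (missing => rejected)."""
    sub = expr.subset(sample_ids=sample_ids)
    keep, skipped = [], []
    for i, pid in enumerate(sub.probe_ids):
        if pid in exclude:
            continue
        if np.isnan(sub.values[i]).any():
            skipped.append(pid)
        else:
            keep.append(i)
    if skipped:
        warnings.warn(
            f"{len(skipped)} probes with missing values excluded from network run",
            stacklevel=3,
        )
    probe_ids = [sub.probe_ids[i] for i in keep]
    return probe_ids, sub.values[keep], tuple(skipped)


def _gpcc_columns(tf_values: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = tf_values.size
    xc = tf_values - tf_values.mean()
    sx = np.sqrt(np.sum(xc**2))
    yc = Y - Y.mean(axis=1, keepdims=True)
    sy = np.sqrt(np.sum(yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (sy * sx)
    r = np.clip(r, -1.0, 1.0)
    undefined = (sy == 0) | (sx == 0)
    r[undefined] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[undefined] = np.nan
    return r, p


def _arm_significance(p: np.ndarray, alpha: float, fdr_method: str) -> np.ndarray:
    """Per-arm significance calls; NaN p-values are never significant."""
    ok = np.isfinite(p)
    sig = np.zeros(p.shape, dtype=bool)
    if fdr_method == "none":
        sig[ok] = p[ok] <= alpha
    elif fdr_method == "bh":
        if ok.any():
            sig[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown fdr_method {fdr_method!r}")
    return sig


def univariate_network(
    expr: ExpressionMatrix,
    tf_probe: str,
    cohort,
    alpha: float = 0.05,
    B: int = 999,
    K: int = 10,
    seed: int | None = 0,
    fdr_method: str = "none",
) -> NetworkResult:
    """CIDUGPCC univariate network of one TF in one cohort.

    Every other probe is tested by the CID permutation test (subgroups from
    the TF's expression) and by GPCC; ``in_network`` is the union of the two
    arms at level ``alpha``.  ``fdr_method="bh"`` applies Benjamini-Hochberg
    within each arm before taking the union (off by default).
    """
    sample_ids = _cohort_ids(cohort)
    tf_values = expr.probe_values(tf_probe, sample_ids)
    if np.isnan(tf_values).any():
        raise ValueError(f"TF probe {tf_probe!r} has missing values in cohort")
    if len(sample_ids) < 2 * K:
        raise ValueError(f"cohort of {len(sample_ids)} samples is smaller than 2K={2*K}")
    scheme = make_subgroups(tf_values, K)
    probe_ids, Y, skipped = _collect_targets(expr, sample_ids, {tf_probe})

    cid_vals = np.empty(len(probe_ids))
    subcids = np.empty((len(probe_ids), K))
    for i in range(len(probe_ids)):
        res = cid(Y[i], scheme)
        cid_vals[i] = res.cid
        subcids[i] = res.subcid
    p_cid = cid_permutation_pvalues(Y, scheme, B=B, seed=seed)
    r, p_gpcc = _gpcc_columns(tf_values, Y)

    sig_cid = _arm_significance(p_cid, alpha, fdr_method)
    sig_gpcc = _arm_significance(p_gpcc, alpha, fdr_method)
    frame = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "cid": cid_vals,
            "argmax_subgroup": np.argmax(subcids, axis=1) + 1,
            "gpcc": r,
            "p_cid": p_cid,
            "p_gpcc": p_gpcc,
            "sig_cid": sig_cid,
            "sig_gpcc": sig_gpcc,
            "in_network": sig_cid | sig_gpcc,
            "mechanism": "none",
        }
    )
    return NetworkResult(
        tf_ids=(tf_probe,), cohort_name=_cohort_name(cohort), alpha=alpha, B=B,
        K=K, seed=seed, fdr_method=fdr_method, frame=frame, subcid=subcids,
        scheme=scheme, skipped_probes=skipped,
    )


# --- bivariate --------------------------------------------------------------

def joint_conditioning_score(tf1_values, tf2_values) -> np.ndarray:
    """Mean of the two TFs' rank-percentiles; high = high in both TFs."""
    v1 = np.asarray(tf1_values, dtype=float)
    v2 = np.asarray(tf2_values, dtype=float)
    if v1.size != v2.size:
        raise ValueError("TF vectors differ in length")
    if np.ptp(v1) == 0 or np.ptp(v2) == 0:
        raise ValueError("constant TF vector in bivariate conditioning")
    n = v1.size
    p1 = sps.rankdata(v1, method="average") / n
    p2 = sps.rankdata(v2, method="average") / n
    return (p1 + p2) / 2.0


def bivariate_cid(
    target_values, tf1_values, tf2_values, K: int = 10
) -> tuple[CidResult, SubgroupScheme]:
    """CID of a target conditioned jointly on a TF pair.

    The top subgroup collects the samples high in *both* TFs; with identical
    TF vectors this degenerates exactly to the univariate scheme.
    """
    score = joint_conditioning_score(tf1_values, tf2_values)
    scheme = make_subgroups(score, K)
    return cid(target_values, scheme), scheme


def bivariate_network(
    expr: ExpressionMatrix,
    tf1_probe: str,
    tf2_probe: str,
    cohort,
    alpha: float = 0.05,
    B: int = 999,
    K: int = 10,
    seed: int | None = 0,
) -> NetworkResult:
    """Multivariate-CID run for a TF pair: joint-scheme CID per probe.

    ``p_cid`` here is the joint permutation p-value; ``in_network`` marks
    joint significance.  GPCC is undefined for a pair (NaN columns).
    """
    sample_ids = _cohort_ids(cohort)
    if len(sample_ids) < 2 * K:
        raise ValueError(f"cohort of {len(sample_ids)} samples is smaller than 2K={2*K}")
    v1 = expr.probe_values(tf1_probe, sample_ids)
    v2 = expr.probe_values(tf2_probe, sample_ids)
    if np.isnan(v1).any() or np.isnan(v2).any():
        raise ValueError("TF probe has missing values in cohort")
    score = joint_conditioning_score(v1, v2)
    scheme = make_subgroups(score, K)
    probe_ids, Y, skipped = _collect_targets(
        expr, sample_ids, {tf1_probe, tf2_probe}
    )
    cid_vals = np.empty(len(probe_ids))
    subcids = np.empty((len(probe_ids), K))
    for i in range(len(probe_ids)):
        res = cid(Y[i], scheme)
        cid_vals[i] = res.cid
        subcids[i] = res.subcid
    p_joint = cid_permutation_pvalues(Y, scheme, B=B, seed=seed)
    frame = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "cid": cid_vals,
            "argmax_subgroup": np.argmax(subcids, axis=1) + 1,
            "gpcc": np.nan,
            "p_cid": p_joint,
            "p_gpcc": np.nan,
            "sig_cid": p_joint <= alpha,
            "sig_gpcc": False,
            "in_network": p_joint <= alpha,
            "mechanism": "none",
        }
    )
    return NetworkResult(
        tf_ids=(tf1_probe, tf2_probe), cohort_name=_cohort_name(cohort),
        alpha=alpha, B=B, K=K, seed=seed, fdr_method="none", frame=frame,
        subcid=subcids, scheme=scheme, skipped_probes=skipped,
    )


def classify_mechanism(p_tf1: float, p_tf2: float, p_joint: float,
                       alpha: float = 0.05) -> str:
    """Combinatorial mechanism label from the three CID p-values.

    Jointly non-significant probes get ``none``; otherwise M1 (both TFs
    univariately significant), M2 (TF1 only), M3 (TF2 only) or M4
    (joint-only).
    """
    for name, p in (("p_tf1", p_tf1), ("p_tf2", p_tf2), ("p_joint", p_joint)):
        if not (0.0 < p <= 1.0):
            raise ValueError(f"{name}={p} outside (0, 1]")
    if p_joint > alpha:
        return "none"
    s1, s2 = p_tf1 <= alpha, p_tf2 <= alpha
    if s1 and s2:
        return "M1"
    if s1:
        return "M2"
    if s2:
        return "M3"
    return "M4"


def network_pools(
    net_tf1, net_tf2, mechanisms: Mapping[str, str]
) -> dict[str, set[str]]:
    """Partition a TF pair's probes into the pools U and M1-M4.

    U is the overlap of the two univariate networks stripped of every
    mechanism-classified probe, so the five pools are pairwise disjoint; the
    full TF1_TF2 network is their union.
    """
    if isinstance(net_tf1, NetworkResult) and isinstance(net_tf2, NetworkResult):
        if net_tf1.probe_universe() != net_tf2.probe_universe():
            raise ValueError("the two networks cover different probe universes")
        set1, set2 = net_tf1.members(), net_tf2.members()
    else:
        set1, set2 = set(net_tf1), set(net_tf2)
    pools: dict[str, set[str]] = {m: set() for m in MECHANISMS}
    for probe, label in mechanisms.items():
        if label in ("M1", "M2", "M3", "M4"):
            pools[label].add(probe)
    classified = pools["M1"] | pools["M2"] | pools["M3"] | pools["M4"]
    pools["U"] = (set1 & set2) - classified
    return pools


def full_network(pools: Mapping[str, set[str]]) -> set[str]:
    """The full TF1_TF2 network: union of U and the four mechanism pools."""
    out: set[str] = set()
    for m in MECHANISMS:
        out |= set(pools.get(m, ()))
    return out
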
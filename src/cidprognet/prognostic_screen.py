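"""Top-decile survival dichotomization, KM/log-rank screening and feature typing.

Every network probe is screened for prognostic relevance: within each cohort
the samples are split at the 90th expression percentile (high = top 10%),
the two groups' survival is compared by the log-rank test, and the probe is
called S (p <= alpha) or NS per cohort.  A probe's S/NS triple across the
91A, "other" and network cohorts maps it to feature type I-IV; the consensus
signature is the intersection of the type-II sets of the 90A- and
181A-anchored networks.

Kaplan-Meier curves, the log-rank test and Cox proportional-hazards fits are
computed with lifelines (Efron handling of tied event times in Cox fits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .core_io import CohortDefinition, ExpressionMatrix

__all__ = [
    "KMCurve",
    "PrognosticCall",
    "FeatureTypeAssignment",
    "dichotomize_top_decile",
    "km_estimate",
    "logrank_test",
    "screen_probes",
    "assign_feature_type",
    "consensus_signature",
    "coxph_fit",
]

FEATURE_TYPE_MAP = {
    ("S", "S", "S"): "I",
    ("NS", "S", "S"): "II",
    ("S", "NS", "S"): "III",
    ("NS", "NS", "S"): "IV",
}


# ---------------------------------------------------------------------------
# dichotomization
# ---------------------------------------------------------------------------

def dichotomize_top_decile(
    values: Sequence[float], q: float = 0.9,
) -> np.ndarray:
    """Label each sample ``high`` (top 10% by value) or ``low``.

    The high group holds the top round(N*(1-q)) samples by rank (at least
    one); ties are broken by stable input order, with a warning when the cut
    falls inside a tie block.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 10:
        raise ValueError(f"N={n} is too small to dichotomize at q={q}")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if np.isnan(v).any():
        raise ValueError("values contain missing entries")
    # n - n*q is numerically cleaner than n*(1-q); halves round up
    n_high = max(1, int(np.floor((n - n * q) + 0.5)))
    # stable ascending sort; the last n_high positions are the high group
    order = np.argsort(v, kind="stable")
    high_idx = order[n - n_high:]
    labels = np.array(["low"] * n, dtype=object)
    labels[high_idx] = "high"
    cut_value = v[order[n - n_high]]
    if n_high < n and v[order[n - n_high - 1]] == cut_value:
        warnings.warn(
            "tie at the top-decile cut; high group chosen by stable sample order",
            stacklevel=2,
        )
    return labels


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate at the observed event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("inf")


def km_estimate(surv_time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier curve; censored subjects at a tied event time remain at
    risk through that event."""
    t = np.asarray(surv_time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    survival = np.array(
        [float(kmf.survival_function_at_times(x).iloc[0]) for x in event_times]
    )
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    censor_times = np.sort(t[e == 0])
    return KMCurve(event_times, survival, at_risk, censor_times)


def logrank_test(
    surv_time: Sequence[float],
    event: Sequence[int],
    group: Sequence[str],
) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value."""
    t = np.asarray(surv_time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {levels.size}")
    if e.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return 0.0, 1.0
    mask = g == levels[0]
    res = _ll_logrank(t[mask], t[~mask], event_observed_A=e[mask],
                      event_observed_B=e[~mask])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrognosticCall:
    probe_id: str
    cohort: str
    logrank_stat: float
    p: float
    call: str  # "S" / "NS" / "unavailable"


def screen_probes(
    expr: ExpressionMatrix,
    probes: Sequence[str],
    cohorts: Mapping[str, CohortDefinition],
    survival: pd.DataFrame,
    alpha: float = 0.05,
    q: float = 0.9,
) -> pd.DataFrame:
    """Per probe x cohort: top-decile dichotomization + log-rank S/NS call.

    ``survival`` must be indexed by sample id with ``surv_time`` and
    ``event`` columns.  The high group is recomputed inside each cohort.
    Cohorts too small to dichotomize yield ``unavailable`` calls rather than
    silent NS.
    """
    records = []
    for cname, cohort in cohorts.items():
        sample_ids = list(cohort.sample_ids)
        surv = survival.loc[sample_ids]
        t = surv["surv_time"].to_numpy(dtype=float)
        e = surv["event"].to_numpy(dtype=int)
        usable = len(sample_ids) >= 10
        if not usable:
            warnings.warn(
                f"cohort {cname} has {len(sample_ids)} samples; calls unavailable",
                stacklevel=2,
            )
        for probe in probes:
            if not usable:
                records.append((probe, cname, np.nan, np.nan, "unavailable"))
                continue
            values = expr.probe_values(probe, sample_ids)
            if np.isnan(values).any():
                records.append((probe, cname, np.nan, np.nan, "unavailable"))
                continue
            labels = dichotomize_top_decile(values, q=q)
            stat, p = logrank_test(t, e, labels)
            records.append((probe, cname, stat, p, "S" if p <= alpha else "NS"))
    return pd.DataFrame(
        records, columns=["probe_id", "cohort", "logrank_stat", "p", "call"]
    )


# ---------------------------------------------------------------------------
# feature typing and consensus signature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureTypeAssignment:
    probe_id: str
    network_cohort: str
    feature_type: str  # I / II / III / IV / untyped


def assign_feature_type(
    calls: Mapping[str, str], network_cohort: str, probe_id: str = ""
) -> FeatureTypeAssignment:
    """Map a probe's S/NS call triple to its feature type.

    The triple is read in the cohort roles (91A, other-of-{90A,181A},
    network cohort); (S,S,S) -> I, (NS,S,S) -> II, (S,NS,S) -> III,
    (NS,NS,S) -> IV.  A probe that is NS in the network cohort falls outside
    the four published patterns and is kept as ``untyped``.
    """
    if network_cohort not in ("90A", "181A"):
        raise ValueError(f"network cohort must be 90A or 181A, got {network_cohort!r}")
    other = "181A" if network_cohort == "90A" else "90A"
    triple = []
    for cohort in ("91A", other, network_cohort):
        if cohort not in calls:
            raise ValueError(f"missing call for cohort {cohort}")
        c = calls[cohort]
        if c not in ("S", "NS"):
            raise ValueError(f"invalid call {c!r} for cohort {cohort}")
        triple.append(c)
    ftype = FEATURE_TYPE_MAP.get(tuple(triple), "untyped")
    return FeatureTypeAssignment(probe_id, network_cohort, ftype)


def consensus_signature(
    type2_from_90A: Sequence[str], type2_from_181A: Sequence[str]
) -> list[str]:
    """Probes in feature type II of both cohort-anchored networks, sorted."""
    shared = set(type2_from_90A) & set(type2_from_181A)
    if not shared:
        warnings.warn("consensus signature is empty", stacklevel=2)
    return sorted(shared)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def coxph_fit(
    surv_time: Sequence[float],
    event: Sequence[int],
    covariates: pd.DataFrame,
    mode: str = "univariate",
) -> pd.DataFrame:
    """Cox PH hazard-ratio table (HR, 95% CI, p) via partial likelihood.

    ``univariate`` fits each covariate alone; ``multivariate`` fits all
    jointly.  Non-convergent fits (e.g. perfect separation) are returned as
    flagged rows, never as silent estimates.
    """
    t = np.asarray(surv_time, dtype=float)
    e = np.asarray(event, dtype=int)
    if e.sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    base = pd.DataFrame({"surv_time": t, "event": e})
    base.index = covariates.index

    def _fit_one(cols: list[str]) -> list[dict]:
        data = pd.concat([base, covariates[cols]], axis=1)
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(data, duration_col="surv_time", event_col="event")
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as err:
            return [
                {"covariate": c, "HR": np.nan, "ci_lower": np.nan,
                 "ci_upper": np.nan, "p": np.nan, "converged": False,
                 "note": str(err).splitlines()[0][:120]}
                for c in cols
            ]
        out = []
        summary = cph.summary
        for c in cols:
            row = summary.loc[c]
            out.append(
                {"covariate": c, "HR": float(row["exp(coef)"]),
                 "ci_lower": float(row["exp(coef) lower 95%"]),
                 "ci_upper": float(row["exp(coef) upper 95%"]),
                 "p": float(row["p"]), "converged": True, "note": ""}
            )
        return out

    cols = list(covariates.columns)
    rows: list[dict] = []
    if mode == "univariate":
        for c in cols:
            rows.extend(_fit_one([c]))
    else:
        rows.extend(_fit_one(cols))
    return pd.DataFrame(rows)
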
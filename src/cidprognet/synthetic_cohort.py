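"""Synthetic breast-tumor cohort generator with planted regulatory truth.

The generator emulates the statistical structure the analysis assumes: a
181-sample cohort with the study's IHC subtype composition (90 ER+ / 91
ER-), a TF1 probe (MYB-like, elevated in ER+ tumors) and a TF2 probe
(ARNT2-like partner), planted TF->target relationships of several
functional forms, clinical indices drawn monotone in a latent
aggressiveness score negatively coupled to TF1, and exponential
proportional-hazards survival whose log-hazard is linear in a planted
signature score.  Ground truth (edges, scores, hazard parameters) is
returned for recovery scoring.

Functional forms are chosen so the two network arms separate: ``linear``
targets are detectable by Pearson correlation, ``nonmonotone`` targets
(|z| of the TF) have near-zero Pearson correlation by construction but are
CID-detectable, and ``joint_*`` targets respond only to combinations of the
two TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .core_io import ExpressionMatrix, SampleRecord

__all__ = [
    "PlantedEdge",
    "SyntheticConfig",
    "SyntheticTruth",
    "RecoveryScore",
    "DEFAULT_COMPOSITION",
    "benchmark_edges",
    "benchmark_config",
    "generate_cohort",
    "simulate_target",
    "simulate_survival",
    "score_recovery",
    "write_truth",
]

#: IHC subtype composition of the emulated 181-tumor cohort (ER+ 90 / ER- 91).
DEFAULT_COMPOSITION: dict[str, int] = {
    "Group IE": 61,
    "Group IIE": 29,
    "TN": 48,
    "ERBB2+": 29,
    "ER(-)PR(+)HER(-)": 5,
    "ER(-)PR(+)HER(+)": 6,
    "ER(-)PR(+)HER(?)": 3,
}

_SUBTYPE_STATUSES: dict[str, tuple[str, str, str]] = {
    "Group IE": ("pos", "pos", "unknown"),
    "Group IIE": ("pos", "neg", "unknown"),
    "TN": ("neg", "neg", "neg"),
    "ERBB2+": ("neg", "neg", "pos"),
    "ER(-)PR(+)HER(-)": ("neg", "pos", "neg"),
    "ER(-)PR(+)HER(+)": ("neg", "pos", "pos"),
    "ER(-)PR(+)HER(?)": ("neg", "pos", "unknown"),
}

MECHANISMS = ("linear", "nonmonotone", "joint_and", "joint_or",
              "tf1_only", "tf2_only")


@dataclass(frozen=True)
class PlantedEdge:
    target: str
    mechanism: str
    effect_size: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not self.noise_sd >= 0:
            raise ValueError("noise_sd must be non-negative")

    def tf_roles(self) -> tuple[str, ...]:
        """Which TF slots ('tf1'/'tf2') this edge genuinely depends on."""
        if self.mechanism in ("linear", "nonmonotone", "tf1_only"):
            return ("tf1",)
        if self.mechanism == "tf2_only":
            return ("tf2",)
        return ("tf1", "tf2")


def benchmark_edges(
    n_linear: int = 30,
    n_nonmonotone: int = 30,
    n_joint: int = 20,
    effect_size: float = 1.5,
    noise_sd: float = 1.0,
) -> tuple[PlantedEdge, ...]:
    """The documented benchmark edge set (30 linear / 30 nonmonotone / 20 joint)."""
    edges = [
        PlantedEdge(f"tgt_linear_{i:02d}", "linear", effect_size, noise_sd)
        for i in range(1, n_linear + 1)
    ]
    edges += [
        PlantedEdge(f"tgt_nonmono_{i:02d}", "nonmonotone", effect_size, noise_sd)
        for i in range(1, n_nonmonotone + 1)
    ]
    edges += [
        PlantedEdge(f"tgt_joint_{i:02d}", "joint_and", effect_size, noise_sd)
        for i in range(1, n_joint + 1)
    ]
    return tuple(edges)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the documented benchmark.

    ``n_probes`` counts target probes (planted + null); the TF probes are
    two extra rows.  ``hazard_baseline`` is the baseline event rate per
    month, ``hazard_beta`` the log-hazard per unit (standardized) signature
    score, and ``er_neg_activity`` the attenuation of the signature's
    hazard effect in ER- tumors (the planted protective program is an
    ER+-enriched pathway).
    """

    composition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    n_probes: int = 1000
    planted_edges: tuple[PlantedEdge, ...] = field(default_factory=benchmark_edges)
    tf1_probe: str = "TF1"
    tf2_probe: str = "TF2"
    tf1_er_shift: float = 1.5
    tf2_er_shift: float = 0.0
    signature_probes: tuple[str, ...] | None = None  # default: linear targets
    hazard_baseline: float = 0.012
    hazard_beta: float = -2.2
    er_neg_activity: float = 0.10
    censor_rate: float = 0.20
    seed: int = 20240101

    def resolved_signature(self) -> tuple[str, ...]:
        if self.signature_probes is not None:
            return tuple(self.signature_probes)
        return tuple(e.target for e in self.planted_edges
                     if e.mechanism == "linear")

    def validate(self) -> None:
        for label, count in self.composition.items():
            if label not in _SUBTYPE_STATUSES:
                raise ValueError(f"unknown subtype label {label!r}")
            if count < 0:
                raise ValueError(f"negative count for subtype {label!r}")
        if sum(self.composition.values()) < 2:
            raise ValueError("cohort must have at least 2 samples")
        targets = [e.target for e in self.planted_edges]
        if len(set(targets)) != len(targets):
            raise ValueError("planted targets must be unique")
        if self.n_probes < len(targets) + 2:
            raise ValueError(
                f"n_probes={self.n_probes} too small for "
                f"{len(targets)} planted targets"
            )
        for e in self.planted_edges:
            if e.noise_sd <= 0:
                raise ValueError(f"noise_sd must be positive for {e.target}")
        if not self.hazard_baseline > 0:
            raise ValueError("hazard_baseline must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        missing = set(self.resolved_signature()) - set(targets)
        if missing:
            raise ValueError(f"signature probes not planted: {sorted(missing)}")


def benchmark_config(seed: int = 20240101, **overrides) -> SyntheticConfig:
    """The documented benchmark configuration (1,000 probes, 181 samples)."""
    return replace(SyntheticConfig(seed=seed), **overrides)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    tf1_probe: str
    tf2_probe: str
    probe_ids: tuple[str, ...]  # all non-TF probes
    edges: tuple[PlantedEdge, ...]
    signature_probes: tuple[str, ...]
    sample_ids: tuple[str, ...]
    signature_score: np.ndarray  # standardized, per sample
    hazard_baseline: float
    hazard_beta: float
    censor_rate: float
    er_neg_activity: float

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Planted (tf_probe, target) pairs (joint edges expand to both TFs)."""
        tf_of = {"tf1": self.tf1_probe, "tf2": self.tf2_probe}
        pairs = set()
        for e in self.edges:
            for role in e.tf_roles():
                pairs.add((tf_of[role], e.target))
        return pairs

    def edge_universe(self) -> set[tuple[str, str]]:
        return {(tf, t) for tf in (self.tf1_probe, self.tf2_probe)
                for t in self.probe_ids}


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def simulate_target(
    tf1_values,
    tf2_values,
    mechanism: str,
    effect_size: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One planted target probe as a function of the TF levels plus noise.

    ``linear``: effect * z(TF1); ``nonmonotone``: effect * |z(TF1)| (near-
    zero Pearson correlation by symmetry); ``joint_and``/``joint_or``:
    effect where both / either TF rank-percentile exceeds 0.5;
    ``tf1_only``/``tf2_only``: linear in the named TF alone.
    """
    v1 = np.asarray(tf1_values, dtype=float)
    v2 = np.asarray(tf2_values, dtype=float)
    if v1.size != v2.size:
        raise ValueError("TF vectors differ in length")
    n = v1.size
    if mechanism in ("linear", "tf1_only"):
        signal = _standardize(v1)
    elif mechanism == "tf2_only":
        signal = _standardize(v2)
    elif mechanism == "nonmonotone":
        signal = np.abs(_standardize(v1))
    elif mechanism in ("joint_and", "joint_or"):
        p1 = sps.rankdata(v1, method="average") / n
        p2 = sps.rankdata(v2, method="average") / n
        both = (p1 > 0.5) & (p2 > 0.5) if mechanism == "joint_and" \
            else (p1 > 0.5) | (p2 > 0.5)
        signal = both.astype(float)
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return effect_size * signal + noise_sd * rng.standard_normal(n)


def simulate_survival(
    signature_score,
    hazard_baseline: float,
    hazard_beta: float,
    censor_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards survival with independent censoring.

    Event time ~ Exponential(lambda0 * exp(beta * score)).  The censoring
    rate constant is calibrated so the expected censored fraction matches
    ``censor_rate``; ``censor_rate=0`` means every event is observed.
    """
    score = np.asarray(signature_score, dtype=float)
    if not hazard_baseline > 0:
        raise ValueError("hazard_baseline must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rates = hazard_baseline * np.exp(hazard_beta * score)
    event_times = rng.exponential(1.0 / rates)
    if censor_rate == 0.0:
        return event_times, np.ones(score.size, dtype=int)

    def expected_censored(log_lc: float) -> float:
        lc = np.exp(log_lc)
        return float(np.mean(lc / (lc + rates))) - censor_rate

    log_lc = optimize.brentq(
        expected_censored,
        np.log(hazard_baseline) - 30, np.log(hazard_baseline) + 30,
    )
    censor_times = rng.exponential(np.exp(-log_lc), size=score.size)
    surv_time = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    return surv_time, event


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleRecord], SyntheticTruth]:
    """Generate one cohort: expression, clinical records and planted truth.

    Subtype counts match the composition exactly for every seed; identical
    config and seed give bit-identical output.  TF1 carries an ER+ mean
    shift; non-planted probes are independent standard-normal noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subtype_per_sample: list[str] = []
    for label, count in config.composition.items():
        subtype_per_sample.extend([label] * count)
    n = len(subtype_per_sample)
    width = max(3, len(str(n)))
    sample_ids = [f"S{i:0{width}d}" for i in range(1, n + 1)]
    er_flag = np.array(
        [_SUBTYPE_STATUSES[s][0] == "pos" for s in subtype_per_sample], dtype=float
    )

    tf1 = rng.standard_normal(n) + config.tf1_er_shift * er_flag
    tf2 = rng.standard_normal(n) + config.tf2_er_shift * er_flag

    probe_ids = [config.tf1_probe, config.tf2_probe]
    rows = [tf1, tf2]
    for edge in config.planted_edges:
        rows.append(
            simulate_target(tf1, tf2, edge.mechanism, edge.effect_size,
                            edge.noise_sd, rng)
        )
        probe_ids.append(edge.target)
    n_null = config.n_probes - len(config.planted_edges)
    null_width = max(4, len(str(n_null)))
    for i in range(1, n_null + 1):
        probe_ids.append(f"null_{i:0{null_width}d}")
        rows.append(rng.standard_normal(n))
    expr = ExpressionMatrix(probe_ids, list(sample_ids), np.vstack(rows))

    signature = config.resolved_signature()
    if signature:
        sig_rows = np.vstack(
            [rows[probe_ids.index(p)] for p in signature]
        )
        score = _standardize(sig_rows.mean(axis=0))
    else:
        score = np.zeros(n)
    activity = np.where(er_flag == 1.0, 1.0, config.er_neg_activity)
    surv_time, event = simulate_survival(
        score * activity, config.hazard_baseline, config.hazard_beta,
        config.censor_rate, rng,
    )

    # clinical indices: monotone in a latent aggressiveness score that is
    # negatively coupled to TF1 (high TF1 ~ early clinical statuses)
    z1 = _standardize(tf1)
    aggress = 0.8 * rng.standard_normal(n) - 0.5 * z1
    grade = np.digitize(aggress, [-0.6, 0.6]) + 1
    np_score = np.clip(grade + rng.integers(-1, 2, size=n), 1, 3)
    mc_score = np.clip(grade + rng.integers(-1, 2, size=n), 1, 3)
    tf_score = np.clip(grade + rng.integers(-1, 2, size=n), 1, 3)
    lvi = (rng.random(n) < 1.0 / (1.0 + np.exp(-(aggress - 0.3)))).astype(int)
    lnm = rng.poisson(np.exp(-0.3 + 0.6 * aggress))
    lym = (lnm > 0).astype(int)
    size_cm = np.round(np.exp(0.8 + 0.25 * aggress
                              + 0.2 * rng.standard_normal(n)), 1)
    size_cm = np.maximum(size_cm, 0.1)
    stage_score = size_cm / 2.0 + lnm
    stage = np.array(["I", "II", "III", "IV"])[
        np.digitize(stage_score, [1.5, 3.0, 6.0])
    ]
    age = np.clip(np.round(rng.normal(52, 10, size=n), 1), 25, 85)

    samples = []
    for i, sid in enumerate(sample_ids):
        er, pr, her = _SUBTYPE_STATUSES[subtype_per_sample[i]]
        samples.append(
            SampleRecord(
                sample_id=sid, er=er, pr=pr, her=her,
                grade=int(grade[i]), np=int(np_score[i]), mc=int(mc_score[i]),
                tf_score=int(tf_score[i]), lvi=int(lvi[i]), lym=int(lym[i]),
                lnm=int(lnm[i]), size_cm=float(size_cm[i]),
                stage=str(stage[i]), age_years=float(age[i]),
                surv_time=float(surv_time[i]), event=int(event[i]),
            )
        )

    truth = SyntheticTruth(
        tf1_probe=config.tf1_probe,
        tf2_probe=config.tf2_probe,
        probe_ids=tuple(probe_ids[2:]),
        edges=tuple(config.planted_edges),
        signature_probes=signature,
        sample_ids=tuple(sample_ids),
        signature_score=score,
        hazard_baseline=config.hazard_baseline,
        hazard_beta=config.hazard_beta,
        censor_rate=config.censor_rate,
        er_neg_activity=config.er_neg_activity,
    )
    return expr, samples, truth


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: float
    specificity: float
    fdr: float
    n_called: int
    fdr_defined: bool


def score_recovery(
    inferred_edges: Sequence[tuple[str, str]], truth: SyntheticTruth
) -> RecoveryScore:
    """Confusion-matrix scoring of inferred (tf, target) edges against truth.

    Sensitivity = TP/planted, specificity = TN/non-planted, FDR =
    FP/called; an empty call set reports FDR 0 with ``fdr_defined=False``.
    """
    universe = truth.edge_universe()
    planted = truth.edge_pairs()
    called = set(inferred_edges)
    stray = called - universe
    if stray:
        raise ValueError(f"inferred edges outside the probe universe: {sorted(stray)[:5]}")
    tp = len(called & planted)
    fp = len(called - planted)
    tn = len(universe - planted - called)
    sensitivity = tp / len(planted) if planted else 1.0
    non_planted = len(universe) - len(planted)
    specificity = tn / non_planted if non_planted else 1.0
    if called:
        return RecoveryScore(sensitivity, specificity, fp / len(called),
                             len(called), True)
    return RecoveryScore(sensitivity, specificity, 0.0, 0, False)


def write_truth(truth: SyntheticTruth, path) -> None:
    """Truth-table TSV: target, tf, mechanism, effect (one row per edge pair)."""
    tf_of = {"tf1": truth.tf1_probe, "tf2": truth.tf2_probe}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("target\ttf\tmechanism\teffect_size\n")
        for e in truth.edges:
            for role in e.tf_roles():
                fh.write(f"{e.target}\t{tf_of[role]}\t{e.mechanism}\t"
                         f"{e.effect_size:.10g}\n")
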
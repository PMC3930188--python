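"""Config-driven end-to-end orchestration.

Stages, in order: cohort build -> univariate TF networks in the 90A and
181A cohorts -> bivariate mechanism pools (U, M1-M4) per network cohort ->
prognostic screen of each network's probes in {91A, 90A, 181A} -> feature
typing -> type-II consensus intersection -> subcohort extraction with KM
comparison -> tabular report.  Every output table carries the seed and a
hash of the configuration; a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    CohortDefinition,
    ExpressionMatrix,
    build_cohorts,
    read_expression,
    read_samples,
    samples_to_frame,
    write_expression,
    write_samples,
)
from .cohort_stats import SubcohortResult, extract_subcohorts
from .dependence_network import (
    NetworkResult,
    bivariate_network,
    full_network,
    network_pools,
    univariate_network,
)
from .prognostic_screen import (
    assign_feature_type,
    consensus_signature,
    screen_probes,
)
from .synthetic_cohort import (
    PlantedEdge,
    SyntheticConfig,
    SyntheticTruth,
    generate_cohort,
    write_truth,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "validate_config",
    "run_pipeline",
    "config_from_yaml",
]

NETWORK_COHORTS = ("90A", "181A")
SCREEN_COHORTS = ("91A", "90A", "181A")
FEATURE_TYPES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; ``synthetic`` mode is the default."""

    mode: str = "synthetic"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    expression_path: str | None = None
    samples_path: str | None = None
    tf1: str = "TF1"
    tf2: str | None = "TF2"
    alpha: float = 0.05
    K: int = 10
    B: int = 999
    q: float = 0.9
    n_groups: int = 2
    fdr_method: str = "none"
    seed: int = 0
    out_dir: str | None = None


def validate_config(config: PipelineConfig,
                    expr: ExpressionMatrix | None = None) -> list[str]:
    """Collect every content problem (never raises on content)."""
    errors: list[str] = []
    if config.mode not in ("synthetic", "files"):
        errors.append(f"unknown mode {config.mode!r}")
    if not 0.0 < config.alpha < 1.0:
        errors.append(f"alpha={config.alpha} outside (0, 1)")
    if config.K < 2:
        errors.append(f"K={config.K} must be >= 2")
    if config.B < 99:
        errors.append(f"B={config.B} must be >= 99")
    if not 0.0 < config.q < 1.0:
        errors.append(f"q={config.q} outside (0, 1)")
    if config.n_groups < 2:
        errors.append(f"n_groups={config.n_groups} must be >= 2")
    if config.fdr_method not in ("none", "bh"):
        errors.append(f"unknown fdr_method {config.fdr_method!r}")
    if config.mode == "synthetic":
        try:
            config.synthetic.validate()
        except ValueError as err:
            errors.append(str(err))
    elif config.mode == "files":
        for label, path in (("expression_path", config.expression_path),
                            ("samples_path", config.samples_path)):
            if path is None:
                errors.append(f"{label} is required in files mode")
            elif not Path(path).exists():
                errors.append(f"{label} does not exist: {path}")
    if expr is not None:
        for tf in filter(None, (config.tf1, config.tf2)):
            if tf not in expr.probe_ids:
                errors.append(f"TF probe {tf!r} not found in expression matrix")
    return errors


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)  # where the bundle lands is not analytic
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    expr: ExpressionMatrix
    samples: list
    cohorts: dict[str, CohortDefinition]
    truth: SyntheticTruth | None
    networks: dict[str, dict]
    pools: dict[str, dict[str, set[str]]]
    full_networks: dict[str, set[str]]
    calls: pd.DataFrame
    feature_types: pd.DataFrame
    table1: dict[str, pd.DataFrame]
    pool_sizes: pd.DataFrame
    consensus: list[str]
    subcohorts: dict[str, SubcohortResult]
    manifest: dict


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _mechanism_from_flags(s1: bool, s2: bool, sj: bool) -> str:
    if not sj:
        return "none"
    if s1 and s2:
        return "M1"
    if s1:
        return "M2"
    if s2:
        return "M3"
    return "M4"


def _table1_layout(feature_types: pd.DataFrame, calls: pd.DataFrame,
                   network_cohort: str) -> pd.DataFrame:
    """Counts of type-I..IV probes significant in each screening cohort."""
    sig = calls[calls["call"] == "S"]
    s_sets = {c: set(sig.loc[sig["cohort"] == c, "probe_id"])
              for c in SCREEN_COHORTS}
    block = feature_types[
        (feature_types["network_cohort"] == network_cohort)
        & (feature_types["feature_type"].isin(FEATURE_TYPES))
    ]
    rows = []
    for ftype in FEATURE_TYPES:
        probes = set(block.loc[block["feature_type"] == ftype, "probe_id"])
        rows.append(
            {"feature_type": ftype,
             **{f"n_{c}": len(probes & s_sets[c]) for c in SCREEN_COHORTS}}
        )
    table = pd.DataFrame(rows)
    total = {"feature_type": "total",
             **{f"n_{c}": int(table[f"n_{c}"].sum()) for c in SCREEN_COHORTS}}
    return pd.concat([table, pd.DataFrame([total])], ignore_index=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the whole analysis; outputs are written only on success."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid pipeline config: " + "; ".join(errors))

    stage = "load"
    try:
        truth = None
        if config.mode == "synthetic":
            expr, samples, truth = generate_cohort(config.synthetic)
        else:
            expr = read_expression(config.expression_path)
            samples = read_samples(config.samples_path)
        errors = validate_config(config, expr)
        if errors:
            raise ValueError("; ".join(errors))

        stage = "cohorts"
        cohorts = build_cohorts(samples)
        surv = samples_to_frame(samples).set_index("sample_id")

        stage = "networks"
        networks: dict[str, dict] = {}
        pools: dict[str, dict[str, set[str]]] = {}
        full_networks: dict[str, set[str]] = {}
        tf_set = {config.tf1} | ({config.tf2} if config.tf2 else set())
        for ci, cname in enumerate(NETWORK_COHORTS):
            cohort = cohorts[cname]
            net1 = univariate_network(
                expr, config.tf1, cohort, alpha=config.alpha, B=config.B,
                K=config.K, seed=[config.seed, ci, 1],
                fdr_method=config.fdr_method,
            )
            entry: dict = {"tf1": net1}
            if config.tf2 is None:
                full = net1.members() - tf_set
                pools[cname] = {"TF1": full}
            else:
                net2 = univariate_network(
                    expr, config.tf2, cohort, alpha=config.alpha, B=config.B,
                    K=config.K, seed=[config.seed, ci, 2],
                    fdr_method=config.fdr_method,
                )
                bivar = bivariate_network(
                    expr, config.tf1, config.tf2, cohort, alpha=config.alpha,
                    B=config.B, K=config.K, seed=[config.seed, ci, 3],
                )
                entry["tf2"], entry["bivariate"] = net2, bivar
                f1 = net1.frame.set_index("probe_id")
                f2 = net2.frame.set_index("probe_id")
                fj = bivar.frame.set_index("probe_id")
                universe = sorted(set(fj.index) - tf_set)
                mech = {
                    p: _mechanism_from_flags(
                        bool(f1.loc[p, "sig_cid"]), bool(f2.loc[p, "sig_cid"]),
                        bool(fj.loc[p, "sig_cid"]),
                    )
                    for p in universe
                }
                entry["mechanisms"] = mech
                pools[cname] = network_pools(
                    net1.members() - tf_set, net2.members() - tf_set, mech
                )
                full = full_network(pools[cname])
            full_networks[cname] = full
            networks[cname] = entry

        stage = "screen"
        all_probes = sorted(full_networks["90A"] | full_networks["181A"])
        calls = screen_probes(
            expr, all_probes,
            {c: cohorts[c] for c in SCREEN_COHORTS},
            surv, alpha=config.alpha, q=config.q,
        )
        call_map = {
            (r.probe_id, r.cohort): r.call for r in calls.itertuples()
        }

        stage = "feature_types"
        ft_rows = []
        for cname in NETWORK_COHORTS:
            for probe in sorted(full_networks[cname]):
                probe_calls = {c: call_map[(probe, c)] for c in SCREEN_COHORTS}
                if "unavailable" in probe_calls.values():
                    ftype = "unavailable"
                else:
                    ftype = assign_feature_type(
                        probe_calls, cname, probe
                    ).feature_type
                ft_rows.append(
                    {"probe_id": probe, "network_cohort": cname,
                     "feature_type": ftype}
                )
        feature_types = pd.DataFrame(
            ft_rows, columns=["probe_id", "network_cohort", "feature_type"]
        )

        stage = "tables"
        table1 = {
            cname: _table1_layout(feature_types, calls, cname)
            for cname in NETWORK_COHORTS
        }
        pool_rows = []
        for cname in NETWORK_COHORTS:
            for pool_name in sorted(pools[cname]):
                pool_rows.append(
                    {"network_cohort": cname, "pool": pool_name,
                     "n_probes": len(pools[cname][pool_name])}
                )
        pool_sizes = pd.DataFrame(pool_rows)

        stage = "consensus"
        type2 = {
            cname: feature_types.loc[
                (feature_types["network_cohort"] == cname)
                & (feature_types["feature_type"] == "II"), "probe_id",
            ].tolist()
            for cname in NETWORK_COHORTS
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            consensus = consensus_signature(type2["90A"], type2["181A"])

        stage = "subcohorts"
        subcohorts: dict[str, SubcohortResult] = {}
        if len(consensus) >= 2 and config.tf2 is not None:
            for cname in NETWORK_COHORTS:
                try:
                    subcohorts[cname] = extract_subcohorts(
                        expr, consensus, cohorts[cname].sample_ids,
                        config.tf1, config.tf2, n_groups=config.n_groups,
                        survival=surv,
                    )
                except ValueError as err:
                    warnings.warn(
                        f"subcohort extraction skipped in {cname}: {err}",
                        stacklevel=2,
                    )

        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "n_probes": expr.n_probes,
            "n_samples": expr.n_samples,
        }
        result = PipelineResult(
            config=config, expr=expr, samples=samples, cohorts=cohorts,
            truth=truth, networks=networks, pools=pools,
            full_networks=full_networks, calls=calls,
            feature_types=feature_types, table1=table1, pool_sizes=pool_sizes,
            consensus=consensus, subcohorts=subcohorts, manifest=manifest,
        )
    except Exception as err:  # noqa: BLE001 - abort with stage context
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err

    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    """Write the report bundle; tables are only written after full success."""
    out_dir.mkdir(parents=True, exist_ok=True)
    header = (f"# seed={result.config.seed} "
              f"config_hash={result.manifest['config_hash']}\n")

    def _write_frame(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    for cname in NETWORK_COHORTS:
        entry = result.networks[cname]
        for key in ("tf1", "tf2", "bivariate"):
            if key in entry:
                net: NetworkResult = entry[key]
                frame = net.frame.copy()
                if key != "bivariate" and "mechanisms" in entry:
                    frame["mechanism"] = [
                        entry["mechanisms"].get(p, "none")
                        for p in frame["probe_id"]
                    ]
                frame.insert(1, "tf_ids", ",".join(net.tf_ids))
                _write_frame(frame, f"network_{cname}_{key}.tsv")
        _write_frame(result.table1[cname], f"table1_layout_{cname}.tsv")
    _write_frame(result.calls, "prognostic_calls.tsv")
    _write_frame(result.feature_types, "feature_types.tsv")
    _write_frame(result.pool_sizes, "pool_sizes.tsv")
    _write_frame(
        pd.DataFrame({"probe_id": result.consensus}), "consensus_signature.tsv"
    )
    sub_rows = []
    for cname, sub in result.subcohorts.items():
        for sid, lab in zip(sub.sample_ids, sub.labels):
            sub_rows.append(
                {"network_cohort": cname, "sample_id": sid, "subcohort": lab,
                 "logrank_stat": sub.logrank_stat, "p": sub.p}
            )
    _write_frame(
        pd.DataFrame(
            sub_rows,
            columns=["network_cohort", "sample_id", "subcohort",
                     "logrank_stat", "p"],
        ),
        "subcohorts.tsv",
    )
    if result.truth is not None:
        write_truth(result.truth, out_dir / "planted_truth.tsv")
        write_expression(result.expr, out_dir / "expression.tsv")
        write_samples(result.samples, out_dir / "samples.tsv")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")


def config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (keys mirror the dataclass)."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        if "planted_edges" in syn:
            syn["planted_edges"] = tuple(
                PlantedEdge(**e) for e in syn["planted_edges"]
            )
        if "composition" in syn:
            syn["composition"] = dict(syn["composition"])
        raw["synthetic"] = SyntheticConfig(**syn)
    return PipelineConfig(**raw)
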
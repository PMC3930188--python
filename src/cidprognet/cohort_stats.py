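"""Median centering, hierarchical clustering, clinical ANOVA, subcohorts.

These are the descriptive-statistics stages around the network/screening
core: per-probe median centering of log2 ratios, unsupervised complete-
linkage clustering on Euclidean distances, one-way ANOVA of a TF's mRNA
level against a clinical index, dendrogram-cut extraction of signature-
defined patient subcohorts, and heatmap/TSV export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .core_io import ExpressionMatrix
from .prognostic_screen import logrank_test

__all__ = [
    "ClusterResult",
    "AnovaResult",
    "SubcohortResult",
    "median_center",
    "hcluster",
    "anova_assoc",
    "extract_subcohorts",
    "export_heatmap",
]


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each probe row's median across samples (idempotent)."""
    values = matrix.values.copy()
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = [matrix.probe_ids[i] for i in np.nonzero(all_missing)[0]]
        raise ValueError(f"probes with all values missing: {bad}")
    med = np.nanmedian(values, axis=1, keepdims=True)
    return ExpressionMatrix(
        list(matrix.probe_ids), list(matrix.sample_ids), values - med
    )


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative merge tree (scipy linkage encoding) plus leaf order."""

    axis: str  # "probes" or "samples"
    ids: tuple[str, ...]
    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix
    leaf_order: tuple[str, ...]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hcluster(matrix: ExpressionMatrix, axis: str = "samples") -> ClusterResult:
    """Complete-linkage clustering on Euclidean distances along one axis.

    Deterministic for a given input order; merge-height ties resolve to the
    smallest-index pair first (scipy's ordering of the condensed distances).
    Rows/columns with missing values are rejected.
    """
    if axis not in ("probes", "samples"):
        raise ValueError(f"axis must be 'probes' or 'samples', got {axis!r}")
    data = matrix.values if axis == "probes" else matrix.values.T
    ids = matrix.probe_ids if axis == "probes" else matrix.sample_ids
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if np.isnan(data).any():
        raise ValueError("missing values present; reject incomplete probes first")
    Z = hierarchy.linkage(data, method="complete", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    return ClusterResult(
        axis=axis, ids=tuple(ids), linkage=Z,
        leaf_order=tuple(ids[i] for i in leaves),
    )


@dataclass(frozen=True)
class AnovaResult:
    index_name: str
    levels: tuple
    level_n: tuple[int, ...]
    level_means: tuple[float, ...]
    F: float
    p: float
    n_excluded: int


def anova_assoc(tf_values, index_labels, index_name: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA of TF expression across index levels.

    Samples with a missing index value are excluded listwise (and counted).
    Per-level means are reported so callers can read off which status
    carries the highest TF level; both dichotomous and multichotomous
    indices are supported.
    """
    v = np.asarray(tf_values, dtype=float)
    lab = pd.Series(list(index_labels))
    keep = lab.notna().to_numpy() & ~np.isnan(v)
    n_excluded = int((~keep).sum())
    v, lab = v[keep], lab[keep]
    levels = sorted(pd.unique(lab))
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least 2 index levels")
    groups = [v[(lab == lv).to_numpy()] for lv in levels]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every index level needs at least 2 samples")
    F, p = sps.f_oneway(*groups)
    return AnovaResult(
        index_name=index_name,
        levels=tuple(levels),
        level_n=tuple(len(g) for g in groups),
        level_means=tuple(float(g.mean()) for g in groups),
        F=float(F),
        p=float(p),
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class SubcohortResult:
    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]  # "high"/"low" for n_groups=2, else "G1"...
    high_label: str
    logrank_stat: float | None
    p: float | None


def extract_subcohorts(
    expr: ExpressionMatrix,
    signature_probes,
    cohort_sample_ids,
    tf1_probe: str,
    tf2_probe: str,
    n_groups: int = 2,
    survival: pd.DataFrame | None = None,
) -> SubcohortResult:
    """Cluster a cohort on its signature submatrix and cut into subcohorts.

    The median-centered signature submatrix is clustered over samples
    (complete linkage, Euclidean) and cut into ``n_groups`` by merge height.
    The group with the higher mean TF1+TF2 expression is the "high"
    subcohort.  When survival data is supplied and n_groups == 2, the
    log-rank comparison of the two groups is attached.
    """
    sample_ids = list(cohort_sample_ids)
    if len(sample_ids) < max(4, n_groups):
        raise ValueError("cohort too small for subcohort extraction")
    sub = expr.subset(probe_ids=list(signature_probes), sample_ids=sample_ids)
    if np.ptp(sub.values) == 0:
        raise ValueError("all samples identical on the signature submatrix")
    centered = median_center(sub)
    clust = hcluster(centered, axis="samples")
    raw = hierarchy.fcluster(clust.linkage, t=n_groups, criterion="maxclust")

    tf_sum = (expr.probe_values(tf1_probe, sample_ids)
              + expr.probe_values(tf2_probe, sample_ids))
    group_means = {g: tf_sum[raw == g].mean() for g in np.unique(raw)}
    ranked = sorted(group_means, key=group_means.get, reverse=True)
    if n_groups == 2 and len(ranked) == 2:
        names = {ranked[0]: "high", ranked[1]: "low"}
    else:
        names = {g: f"G{i+1}" for i, g in enumerate(ranked)}
    labels = tuple(names[g] for g in raw)
    high_label = names[ranked[0]]

    stat = p = None
    if survival is not None and len(set(labels)) == 2:
        surv = survival.loc[sample_ids]
        stat, p = logrank_test(
            surv["surv_time"].to_numpy(float),
            surv["event"].to_numpy(int),
            np.asarray(labels),
        )
    return SubcohortResult(
        sample_ids=tuple(sample_ids), labels=labels, high_label=high_label,
        logrank_stat=stat, p=p,
    )


def export_heatmap(
    matrix: ExpressionMatrix,
    row_order,
    col_order,
    path_prefix,
    rectangles=(),
) -> dict[str, str]:
    """Write the reordered matrix TSV and a heatmap image.

    ``rectangles`` are (row_start, row_stop, col_start, col_stop) index
    ranges (0-based, stop-exclusive) drawn as group outlines; the plot is
    presentation-only.  Returns the paths written.
    """
    rows = list(row_order)
    cols = list(col_order)
    if sorted(rows) != sorted(matrix.probe_ids):
        raise ValueError("row order is not a permutation of probe ids")
    if sorted(cols) != sorted(matrix.sample_ids):
        raise ValueError("column order is not a permutation of sample ids")
    reordered = matrix.subset(probe_ids=rows, sample_ids=cols)
    for r0, r1, c0, c1 in rectangles:
        if not (0 <= r0 < r1 <= len(rows) and 0 <= c0 < c1 <= len(cols)):
            raise ValueError(f"rectangle ({r0},{r1},{c0},{c1}) outside matrix bounds")

    from .core_io import write_expression

    tsv_path = f"{path_prefix}.tsv"
    write_expression(reordered, tsv_path)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    vmax = np.nanmax(np.abs(reordered.values)) or 1.0
    ax.imshow(reordered.values, aspect="auto", cmap="RdBu_r",
              vmin=-vmax, vmax=vmax, interpolation="nearest")
    for r0, r1, c0, c1 in rectangles:
        ax.add_patch(plt.Rectangle((c0 - 0.5, r0 - 0.5), c1 - c0, r1 - r0,
                                   fill=False, edgecolor="black", lw=1.5))
    ax.set_xlabel("samples")
    ax.set_ylabel("probes")
    png_path = f"{path_prefix}.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"tsv": tsv_path, "png": png_path}
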
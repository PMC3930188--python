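"""Domain types, cohort/subtype logic, and tabular I/O.

The analysis substrate is a probes x samples matrix of log2 tumor/reference
expression ratios plus one clinical record per sample (IHC receptor statuses,
histopathological indices, survival time and event).  Cohorts are named
sample subsets: ``90A`` (ER-positive tumors), ``91A`` (ER-negative tumors)
and ``181A`` (their disjoint union).

All text formats are UTF-8, tab-separated, with a header row.  The single
missing-value sentinel in expression files is ``NA``; operations that cannot
tolerate missing values reject affected probes rather than imputing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATUS_VALUES",
    "HER_VALUES",
    "SUBTYPE_LABELS",
    "ExpressionMatrix",
    "SampleRecord",
    "CohortDefinition",
    "assign_subtype",
    "build_cohorts",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "samples_to_frame",
    "read_geo_series_matrix",
    "load_signature_fixture",
    "load_feature_count_fixture",
    "feature_count_totals",
]

STATUS_VALUES = ("pos", "neg")
HER_VALUES = ("pos", "neg", "unknown")

GROUP_IE = "Group IE"
GROUP_IIE = "Group IIE"
TN = "TN"
ERBB2 = "ERBB2+"

SUBTYPE_LABELS = (
    GROUP_IE,
    GROUP_IIE,
    TN,
    ERBB2,
    "ER(-)PR(+)HER(-)",
    "ER(-)PR(+)HER(+)",
    "ER(-)PR(+)HER(?)",
    "ER(-)PR(-)HER(?)",
)


class ParseError(ValueError):
    """Malformed tabular input; the message names the offending row/column."""


def assign_subtype(er: str, pr: str, her: str) -> str:
    """Map an (ER, PR, HER) IHC status triple to its molecular subtype label.

    ER-positive tumors map to Group IE (PR+) or Group IIE (PR-) regardless of
    HER status.  ER-negative tumors split by PR and HER: triple negatives,
    ERBB2+, and the ER(-)PR(+) groups, with HER ``unknown`` rendered as
    ``HER(?)``.
    """
    if er not in STATUS_VALUES:
        raise ValueError(f"invalid ER status {er!r}; expected one of {STATUS_VALUES}")
    if pr not in STATUS_VALUES:
        raise ValueError(f"invalid PR status {pr!r}; expected one of {STATUS_VALUES}")
    if her not in HER_VALUES:
        raise ValueError(f"invalid HER status {her!r}; expected one of {HER_VALUES}")
    if er == "pos":
        return GROUP_IE if pr == "pos" else GROUP_IIE
    her_tag = {"pos": "+", "neg": "-", "unknown": "?"}[her]
    if pr == "pos":
        return f"ER(-)PR(+)HER({her_tag})"
    if her == "neg":
        return TN
    if her == "pos":
        return ERBB2
    # ER(-)PR(-)HER(?) has no named group; keep it explicit rather than
    # folding it into TN/ERBB2+.
    return "ER(-)PR(-)HER(?)"


@dataclass(frozen=True)
class CohortDefinition:
    """A named subset of sample ids (e.g. ``90A``, ``91A``, ``181A``)."""

    name: str
    sample_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class SampleRecord:
    """Clinical annotation of one tumor sample.

    ``np``, ``mc`` and ``tf_score`` are the histological grade components
    (nuclear pleomorphism, mitotic count, tubule formation, each 1-3).
    ``lvi``/``lym`` are 0/1 indicators (lymphovascular invasion, lymph-node
    metastasis status); ``lnm`` counts metastatic lymph nodes.  ``surv_time``
    is follow-up in months; ``event`` is 1 for an observed death.
    """

    sample_id: str
    er: str
    pr: str
    her: str = "unknown"
    grade: int | None = None
    np: int | None = None
    mc: int | None = None
    tf_score: int | None = None
    lvi: int | None = None
    lym: int | None = None
    lnm: int | None = None
    size_cm: float | None = None
    stage: str | None = None
    age_years: float | None = None
    surv_time: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        # subtype validation happens here too (raises on bad tokens)
        assign_subtype(self.er, self.pr, self.her)
        if self.event is not None and self.event not in (0, 1):
            raise ValueError(f"{self.sample_id}: event must be 0/1, got {self.event}")
        if self.surv_time is not None and not self.surv_time > 0:
            raise ValueError(f"{self.sample_id}: surv_time must be positive")
        if self.lnm is not None and self.lnm < 0:
            raise ValueError(f"{self.sample_id}: lnm must be non-negative")
        if self.lym is not None and self.lnm is not None:
            if (self.lym == 1) != (self.lnm > 0):
                raise ValueError(
                    f"{self.sample_id}: lym={self.lym} inconsistent with lnm={self.lnm}"
                )

    @property
    def subtype_label(self) -> str:
        return assign_subtype(self.er, self.pr, self.her)


def build_cohorts(samples: Sequence[SampleRecord]) -> dict[str, CohortDefinition]:
    """Partition samples into the 90A (ER+), 91A (ER-) and 181A cohorts.

    Sample order is preserved as given; 181A is the disjoint union of the
    other two in input order.  An empty side is emitted with a warning.
    """
    if len(samples) == 0:
        raise ValueError("cannot build cohorts from an empty sample collection")
    pos = tuple(s.sample_id for s in samples if s.er == "pos")
    neg = tuple(s.sample_id for s in samples if s.er == "neg")
    if not pos or not neg:
        warnings.warn(
            "one ER stratum is empty; 90A/91A cohorts are degenerate", stacklevel=2
        )
    return {
        "90A": CohortDefinition("90A", pos),
        "91A": CohortDefinition("91A", neg),
        "181A": CohortDefinition("181A", tuple(s.sample_id for s in samples)),
    }


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

MISSING = "NA"


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of log2 expression ratios (NaN = missing)."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for axis_name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValueError(f"duplicate {axis_name} ids: {sorted(dupes)}")
        if np.isinf(self.values).any():
            raise ValueError("expression values must be finite or missing (NaN)")
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_values(self, probe_id: str, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        row = self.values[self._probe_index[probe_id]]
        if sample_ids is None:
            return row.copy()
        return row[[self._sample_index[s] for s in sample_ids]]

    def subset(self, probe_ids: Sequence[str] | None = None,
               sample_ids: Sequence[str] | None = None) -> "ExpressionMatrix":
        pids = list(probe_ids) if probe_ids is not None else list(self.probe_ids)
        sids = list(sample_ids) if sample_ids is not None else list(self.sample_ids)
        rows = [self._probe_index[p] for p in pids]
        cols = [self._sample_index[s] for s in sids]
        return ExpressionMatrix(pids, sids, self.values[np.ix_(rows, cols)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def read_expression(path) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column probe ids, header sample ids).

    Rejects ragged rows, duplicate ids and non-numeric cells with an error
    naming the offending row/column; cells equal to ``NA`` become NaN.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        sample_ids = header[1:]
        if not sample_ids:
            raise ParseError(f"{path}: header has no sample columns")
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != len(header):
                raise ParseError(
                    f"{path}: line {lineno} has {len(rec)} fields, expected {len(header)}"
                )
            probe_ids.append(rec[0])
            row: list[float] = []
            for col, cell in zip(sample_ids, rec[1:]):
                if cell == MISSING:
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at probe {rec[0]!r}, "
                        f"sample {col!r} (line {lineno})"
                    ) from None
            rows.append(row)
    dupes = _duplicates(probe_ids)
    if dupes:
        raise ParseError(f"{path}: duplicate probe ids: {sorted(dupes)}")
    dupes = _duplicates(sample_ids)
    if dupes:
        raise ParseError(f"{path}: duplicate sample ids: {sorted(dupes)}")
    return ExpressionMatrix(probe_ids, sample_ids, np.asarray(rows, dtype=float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix in the format :func:`read_expression` accepts."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            cells = [MISSING if np.isnan(v) else format(v, ".10g") for v in row]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# sample annotation table
# ---------------------------------------------------------------------------

_SAMPLE_COLUMNS = [
    "sample_id", "er", "pr", "her", "grade", "np", "mc", "tf_score", "lvi",
    "lym", "lnm", "size_cm", "stage", "age_years", "surv_time", "event",
]
_INT_COLS = {"grade", "np", "mc", "tf_score", "lvi", "lym", "lnm", "event"}
_FLOAT_COLS = {"size_cm", "age_years", "surv_time"}


def samples_to_frame(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [{c: getattr(s, c) for c in _SAMPLE_COLUMNS} for s in samples]
    )
    frame["subtype_label"] = [s.subtype_label for s in samples]
    return frame


def write_samples(samples: Sequence[SampleRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(_SAMPLE_COLUMNS) + "\n")
        for s in samples:
            cells = []
            for c in _SAMPLE_COLUMNS:
                v = getattr(s, c)
                if v is None:
                    cells.append(MISSING)
                elif isinstance(v, float):
                    cells.append(format(v, ".10g"))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")


def read_samples(path) -> list[SampleRecord]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise ParseError(f"{path}: missing sample_id column")
        records = []
        for lineno, row in enumerate(reader, start=2):
            kwargs: dict = {}
            for c in _SAMPLE_COLUMNS:
                cell = row.get(c)
                if cell is None or cell == MISSING or cell == "":
                    if c in ("sample_id", "er", "pr"):
                        raise ParseError(f"{path}: line {lineno}: {c} is required")
                    kwargs[c] = "unknown" if c == "her" else None
                elif c in _INT_COLS:
                    kwargs[c] = int(cell)
                elif c in _FLOAT_COLS:
                    kwargs[c] = float(cell)
                else:
                    kwargs[c] = cell
            records.append(SampleRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# GEO series-matrix reader (optional real-data path)
# ---------------------------------------------------------------------------

def read_geo_series_matrix(path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Parse a GEO series-matrix text file.

    Returns the expression table plus a metadata frame with one row per
    ``!Sample_*`` header line (raw strings; no semantic parsing of the
    ``characteristics`` lines is attempted).
    """
    meta_rows: list[dict] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                parts = line[1:].split("\t")
                meta_rows.append(
                    {"key": parts[0], "values": [p.strip('"') for p in parts[1:]]}
                )
    if not saw_begin:
        raise ParseError(f"{path}: no table (missing series_matrix_table_begin)")
    if not saw_end:
        raise ParseError(f"{path}: truncated table (missing series_matrix_table_end)")
    if not table_lines:
        raise ParseError(f"{path}: empty series-matrix table")
    header = [c.strip('"') for c in table_lines[0].split("\t")]
    sample_ids = header[1:]
    probe_ids, rows = [], []
    for line in table_lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}: ragged series-matrix row {parts[0]!r}")
        probe_ids.append(parts[0].strip('"'))
        rows.append([np.nan if p in ("", "null", "NA", '"NA"') else float(p)
                     for p in parts[1:]])
    matrix = ExpressionMatrix(probe_ids, sample_ids, np.asarray(rows, dtype=float))
    return matrix, pd.DataFrame(meta_rows)


# ---------------------------------------------------------------------------
# packaged fixtures (published summary tables, transcribed verbatim)
# ---------------------------------------------------------------------------

def _fixture_path(name: str):
    return resources.files("cidprognet.data").joinpath(name)


def load_signature_fixture() -> pd.DataFrame:
    """The published 41-probe prognostic signature annotation table.

    Columns: ``feature_no`` (array feature number), ``gene_symbol``,
    ``myb_direction`` (Up/Down regulation under MYB), ``mybl_direction``
    (Up/Down/none under MYBL1 & MYBL2), ``annotation``.
    """
    with resources.as_file(_fixture_path("table2_signature.tsv")) as p:
        table = pd.read_csv(p, sep="\t", dtype={"feature_no": int})
    expected = ["feature_no", "gene_symbol", "myb_direction", "mybl_direction",
                "annotation"]
    if list(table.columns) != expected:
        raise RuntimeError("signature fixture is corrupt: unexpected columns")
    if table["feature_no"].duplicated().any():
        raise RuntimeError("signature fixture is corrupt: duplicate feature_no")
    if not table["myb_direction"].isin(["Up", "Down"]).all():
        raise RuntimeError("signature fixture is corrupt: bad myb_direction")
    if not table["mybl_direction"].isin(["Up", "Down", "none"]).all():
        raise RuntimeError("signature fixture is corrupt: bad mybl_direction")
    return table


def load_feature_count_fixture() -> pd.DataFrame:
    """Published feature-type counts per network cohort (types I-IV x cohorts).

    One row per (network_cohort, feature_type); the count columns say in how
    many probes of that type the prognostic call was significant in each of
    the three screening cohorts.
    """
    with resources.as_file(_fixture_path("table1_feature_counts.tsv")) as p:
        table = pd.read_csv(p, sep="\t")
    expected = ["network_cohort", "feature_type", "n_90A", "n_91A", "n_181A"]
    if list(table.columns) != expected:
        raise RuntimeError("feature-count fixture is corrupt: unexpected columns")
    counts = table[["n_90A", "n_91A", "n_181A"]]
    if (counts < 0).any().any():
        raise RuntimeError("feature-count fixture is corrupt: negative count")
    for nc, grp in table.groupby("network_cohort"):
        if sorted(grp["feature_type"]) != ["I", "II", "III", "IV"]:
            raise RuntimeError(
                f"feature-count fixture is corrupt: incomplete types for {nc}"
            )
    return table


def feature_count_totals(table: pd.DataFrame, network_cohort: str) -> pd.Series:
    """Column totals (per screening cohort) for one network cohort's block."""
    block = table[table["network_cohort"] == network_cohort]
    if block.empty:
        raise KeyError(f"no such network cohort in fixture: {network_cohort!r}")
    return block[["n_90A", "n_91A", "n_181A"]].sum()
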
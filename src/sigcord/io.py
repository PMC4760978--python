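"""Readers, writers and the shared data model.

Expression matrices are tab-separated text with a probe-id first column and
a header row of sample ids; values are log2 intensities. Clinical and
survival tables are CSV with fixed headers::

    sample_id,size_cm,grade,node_status
    sample_id,time_months,event,endpoint

Empty cells in the clinical table denote missing values, which are preserved
(never imputed). Readers validate and reject malformed input rather than
coercing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ENDPOINTS = ("DMFS", "BCSS")

CLINICAL_COLUMNS = ["sample_id", "size_cm", "grade", "node_status"]
SURVIVAL_COLUMNS = ["sample_id", "time_months", "event", "endpoint"]


class ExpressionMatrix:
    """A probes x samples grid of finite log2 intensities.

    Thin wrapper around a :class:`pandas.DataFrame` (index = probe ids,
    columns = sample ids) that enforces unique identifiers and finiteness.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at probe {values.index[i]!r}, "
                f"sample {values.columns[j]!r}"
            )
        self._values = values.astype(float)

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def probe_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def probe(self, probe_id: str) -> pd.Series:
        """Expression of one probe across samples."""
        if probe_id not in self._values.index:
            raise KeyError(f"probe {probe_id!r} not in expression matrix")
        return self._values.loc[probe_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self._values.columns]
        if missing:
            raise KeyError(f"samples not in expression matrix: {missing[:5]}")
        return ExpressionMatrix(self._values.loc[:, list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, ExpressionMatrix) and self._values.equals(
            other._values
        )


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    size_cm: float | None  # tumour size, cm; > 0 when present
    grade: int | None  # Elston-Ellis grade 1-3
    node_status: int | None  # 0 = node negative, 1 = node positive


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time_months: float
    event: int  # 1 = event observed, 0 = censored
    endpoint: str  # DMFS or BCSS


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load a probes x samples TSV; reject duplicates, NaNs, ragged rows."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.hasnans or any(df.isna().any()):
        bad = df.index[df.isna().any(axis=1)]
        raise ValueError(
            f"{path}: missing/non-numeric values in rows {list(bad[:5])!r}"
        )
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric column(s) {non_numeric[:5]!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


def _parse_optional(value, kind, field, row_label):
    if pd.isna(value) or value == "":
        return None
    try:
        out = kind(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"row {row_label}: bad {field} {value!r}") from exc
    return out


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Load the clinical CSV; empty cells denote missing values."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    if list(df.columns) != CLINICAL_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {CLINICAL_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for i, row in df.iterrows():
        label = f"{i + 2} of {path}"  # header is line 1
        size = _parse_optional(row["size_cm"], float, "size_cm", label)
        if size is not None and size <= 0:
            raise ValueError(f"row {label}: size_cm must be > 0, got {size}")
        grade = _parse_optional(row["grade"], lambda v: int(float(v)), "grade", label)
        if grade is not None and grade not in (1, 2, 3):
            raise ValueError(f"row {label}: grade must be 1, 2 or 3, got {grade}")
        node = _parse_optional(
            row["node_status"], lambda v: int(float(v)), "node_status", label
        )
        if node is not None and node not in (0, 1):
            raise ValueError(f"row {label}: node_status must be 0 or 1, got {node}")
        records.append(ClinicalRecord(str(row["sample_id"]), size, grade, node))
    return records


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Load the survival CSV (one row per sample per endpoint)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "endpoint": str})
    if list(df.columns) != SURVIVAL_COLUMNS:
        raise ValueError(
            f"{path}: expected columns {SURVIVAL_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for i, row in df.iterrows():
        label = f"{i + 2} of {path}"
        time = float(row["time_months"])
        if not np.isfinite(time) or time < 0:
            raise ValueError(f"row {label}: time_months must be >= 0, got {time}")
        event = int(row["event"])
        if event not in (0, 1):
            raise ValueError(f"row {label}: event must be 0 or 1, got {event}")
        endpoint = str(row["endpoint"])
        if endpoint not in ENDPOINTS:
            raise ValueError(
                f"row {label}: endpoint must be one of {ENDPOINTS}, got {endpoint!r}"
            )
        records.append(SurvivalRecord(str(row["sample_id"]), time, event, endpoint))
    return records


def clinical_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.sample_id, r.size_cm, r.grade, r.node_status) for r in records],
        columns=CLINICAL_COLUMNS,
    )
    return df.set_index("sample_id")


def survival_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.sample_id, r.time_months, r.event, r.endpoint) for r in records],
        columns=SURVIVAL_COLUMNS,
    )


def write_clinical(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    clinical_frame(records).reset_index().to_csv(path, index=False)


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    survival_frame(records).to_csv(path, index=False)


@dataclass
class Cohort:
    """Inner join of expression, clinical and survival sources.

    Sample order follows the expression matrix columns. ``dropped`` records
    how many samples each source lost in the join.
    """

    expression: ExpressionMatrix
    clinical: pd.DataFrame  # index sample_id; size_cm, grade, node_status
    survival: pd.DataFrame  # long format, one row per sample per endpoint
    dropped: dict[str, int]

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    def survival_for(self, endpoint: str) -> pd.DataFrame:
        """Survival rows for one endpoint, indexed by sample_id."""
        if endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        sub = self.survival[self.survival["endpoint"] == endpoint]
        return sub.set_index("sample_id")


def align_cohort(
    expr: ExpressionMatrix,
    clinical: Iterable[ClinicalRecord],
    survival: Iterable[SurvivalRecord],
) -> Cohort:
    """Inner-join the three sources on sample_id (expression order).

    Samples only need expression + clinical to be retained; survival rows
    for absent samples are dropped. An empty intersection is an error.
    """
    cdf = clinical_frame(clinical)
    sdf = survival_frame(survival)
    expr_ids = expr.sample_ids
    keep = [s for s in expr_ids if s in cdf.index]
    if not keep:
        raise ValueError("no samples shared between expression and clinical tables")
    dropped = {
        "expression": len(expr_ids) - len(keep),
        "clinical": len(cdf) - len(keep),
        "survival": int((~sdf["sample_id"].isin(keep)).sum()),
    }
    for source, n in dropped.items():
        if n:
            log.info("align_cohort: dropped %d sample rows from %s", n, source)
    return Cohort(
        expression=expr.subset_samples(keep),
        clinical=cdf.loc[keep],
        survival=sdf[sdf["sample_id"].isin(keep)].reset_index(drop=True),
        dropped=dropped,
    )
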
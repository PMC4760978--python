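"""Modified Nottingham Prognostic Index.

The classic NPI combines tumour size, histological grade and nodal stage.
When only binary nodal status is known, the modified form

    NPI = 0.2 x size_cm + grade + 1.5 x node_status + 1

is used, with risk strata: NPI < 3.4 low, 3.4 <= NPI <= 5.4 intermediate,
NPI > 5.4 high (both boundary values fall in the intermediate stratum).
Samples with any missing or out-of-range input get a missing NPI and are
excluded from NPI-stratified analyses but retained elsewhere.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LOW_CUT = 3.4
HIGH_CUT = 5.4
GROUPS = ("low", "intermediate", "high")


def compute_npi(size_cm: float, grade: int, node_status: int) -> float:
    """Modified NPI; NaN when any input is missing or out of range."""
    if (
        size_cm is None
        or grade is None
        or node_status is None
        or not np.isfinite(size_cm)
        or size_cm <= 0
        or grade not in (1, 2, 3)
        or node_status not in (0, 1)
    ):
        return math.nan
    return 0.2 * size_cm + grade + 1.5 * node_status + 1


def npi_group(npi: float) -> str | None:
    """Risk stratum of an NPI value (None for missing)."""
    if npi is None or not np.isfinite(npi):
        return None
    if npi < LOW_CUT:
        return "low"
    if npi <= HIGH_CUT:
        return "intermediate"
    return "high"


def npi_table(clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-sample NPI and stratum from a clinical frame.

    ``clinical`` is indexed by sample_id with columns size_cm, grade,
    node_status (missing values as NaN/None).
    """
    rows = []
    n_missing = 0
    for sample_id, row in clinical.iterrows():
        size = None if pd.isna(row["size_cm"]) else float(row["size_cm"])
        grade = None if pd.isna(row["grade"]) else int(row["grade"])
        node = None if pd.isna(row["node_status"]) else int(row["node_status"])
        npi = compute_npi(size, grade, node)
        group = npi_group(npi)
        if group is None:
            n_missing += 1
        rows.append((sample_id, npi, group))
    if n_missing:
        log.info("npi_table: %d sample(s) with missing NPI inputs", n_missing)
    df = pd.DataFrame(rows, columns=["sample_id", "npi", "group"])
    return df.set_index("sample_id")
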
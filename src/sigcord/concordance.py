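"""Agreement statistics across binary prognosis calls.

For k signatures, a sample's poor count is the number of signatures calling
it poor (row sum of the call matrix). Concordance is count-based:

strict
    Concordant iff the count is 0 or k (all signatures agree).
broad
    Concordant iff the count is 0, 1, k-1 or k (at most one dissenter).

Both definitions generalize to any subset of k' >= 2 signatures; note that
for k' <= 3 the broad definition admits every outcome (rate 1), a
degenerate regime rather than an error. Subset concordance enumerates all
C(k, k') column subsets in lexicographic order and reports each subset's
rate plus the median across subsets (midpoint convention for even counts).
NPI-stratified summaries decompose each stratum into concordant-good
(count 0 or 1), discordant (2..k-2) and concordant-poor (k-1 or k)
fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .signatures import PrognosisCallMatrix

log = logging.getLogger(__name__)

MODES = ("strict", "broad")


def poor_count(calls: PrognosisCallMatrix | pd.DataFrame) -> pd.Series:
    """Per-sample number of poor-prognosis calls (row sums)."""
    frame = calls.calls if isinstance(calls, PrognosisCallMatrix) else calls
    if frame.shape[1] < 2:
        raise ValueError("poor_count requires at least 2 signatures")
    return frame.sum(axis=1).astype(int).rename("poor_count")


def _concordant_counts(k: int, mode: str) -> set[int]:
    if mode == "strict":
        return {0, k}
    if mode == "broad":
        return {0, 1, k - 1, k}
    raise ValueError(f"mode must be one of {MODES}, got {mode!r}")


def concordance_flags(
    poor_counts, k: int, mode: str = "strict"
) -> tuple[np.ndarray, float]:
    """Boolean concordance flags and the concordant fraction."""
    counts = np.asarray(poor_counts, dtype=int)
    if counts.size == 0:
        raise ValueError("empty poor counts")
    if (counts < 0).any() or (counts > k).any():
        raise ValueError(f"poor counts must lie in [0, {k}]")
    flags = np.isin(counts, sorted(_concordant_counts(k, mode)))
    return flags, float(flags.mean())


def event_capture_table(poor_counts, events, k: int) -> pd.DataFrame:
    """Patients and events captured at each poor-call count 0..k.

    Percentages are over column totals, so each percentage column sums to
    100 up to rounding.
    """
    counts = np.asarray(poor_counts, dtype=int)
    events = np.asarray(events, dtype=int)
    if counts.shape != events.shape:
        raise ValueError("poor_counts and events must have equal length")
    rows = []
    n_total = counts.size
    e_total = events.sum()
    for c in range(k + 1):
        mask = counts == c
        n = int(mask.sum())
        e = int(events[mask].sum())
        rows.append(
            {
                "poor_count": c,
                "n_patients": n,
                "pct_patients": 100.0 * n / n_total if n_total else 0.0,
                "n_events": e,
                "pct_events": 100.0 * e / e_total if e_total else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("poor_count")


@dataclass
class SubsetConcordance:
    subset_size: int
    mode: str
    rates: pd.Series  # index: tuple of signature names, lexicographic order
    median: float


def subset_concordance(
    calls: PrognosisCallMatrix | pd.DataFrame, subset_size: int, mode: str = "strict"
) -> SubsetConcordance:
    """Concordance over every C(k, k') signature subset.

    Subsets are enumerated in lexicographic order of column positions, so
    per-subset output is deterministic and diffable.
    """
    frame = calls.calls if isinstance(calls, PrognosisCallMatrix) else calls
    k = frame.shape[1]
    if not 2 <= subset_size <= k:
        raise ValueError(f"subset size must be in [2, {k}], got {subset_size}")
    arr = frame.to_numpy(dtype=int)
    names = list(frame.columns)
    rates = {}
    for combo in combinations(range(k), subset_size):
        counts = arr[:, combo].sum(axis=1)
        _, rate = concordance_flags(counts, subset_size, mode)
        rates[tuple(names[i] for i in combo)] = rate
    series = pd.Series(rates, name=f"{mode}_rate")
    return SubsetConcordance(
        subset_size=subset_size,
        mode=mode,
        rates=series,
        median=float(np.median(series.to_numpy())),
    )


def subset_median_curve(
    calls: PrognosisCallMatrix | pd.DataFrame, mode: str = "strict"
) -> pd.Series:
    """Median subset concordance for every subset size 2..k (size k's single
    "subset" is the full panel)."""
    frame = calls.calls if isinstance(calls, PrognosisCallMatrix) else calls
    k = frame.shape[1]
    medians = {
        size: subset_concordance(frame, size, mode).median for size in range(2, k + 1)
    }
    return pd.Series(medians, name=f"median_{mode}_concordance").rename_axis(
        "subset_size"
    )


@dataclass
class StratumSummary:
    n: int
    strict_rate: float
    broad_rate: float
    concordant_good: float  # fraction with count in {0, 1}
    concordant_poor: float  # fraction with count in {k-1, k}
    discordant: float  # fraction with count in 2..k-2
    subset_medians: pd.Series = field(default_factory=pd.Series)


def stratum_summary(
    frame: pd.DataFrame, with_subsets: bool = True
) -> StratumSummary:
    k = frame.shape[1]
    counts = poor_count(frame)
    _, strict = concordance_flags(counts, k, "strict")
    _, broad = concordance_flags(counts, k, "broad")
    good = float(counts.isin([0, 1]).mean())
    poor = float(counts.isin([k - 1, k]).mean())
    return StratumSummary(
        n=len(frame),
        strict_rate=strict,
        broad_rate=broad,
        concordant_good=good,
        concordant_poor=poor,
        discordant=1.0 - good - poor,
        subset_medians=subset_median_curve(frame) if with_subsets else pd.Series(),
    )


def stratified_concordance(
    calls: PrognosisCallMatrix | pd.DataFrame,
    strata: pd.Series,
    order: tuple[str, ...] = ("low", "intermediate", "high"),
    with_subsets: bool = True,
) -> dict[str, StratumSummary]:
    """Concordance decomposition within each NPI stratum.

    ``strata`` maps sample_id -> stratum (None/NaN for missing, excluded
    and counted in the log). Empty strata are omitted with a warning.
    """
    frame = calls.calls if isinstance(calls, PrognosisCallMatrix) else calls
    strata = strata.reindex(frame.index)
    n_missing = int(strata.isna().sum())
    if n_missing:
        log.info("stratified_concordance: %d sample(s) without stratum", n_missing)
    out: dict[str, StratumSummary] = {}
    for group in order:
        members = frame.loc[strata == group]
        if members.empty:
            log.warning("stratified_concordance: stratum %r is empty", group)
            continue
        out[group] = stratum_summary(members, with_subsets=with_subsets)
    return out
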
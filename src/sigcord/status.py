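"""ER/HER2 status calls from single designated probes.

ER status comes from probe 205225_at (ESR1) with a fixed log2 cutoff of
1.834; HER2 status from probe 216836_s_at (ERBB2), whose cutoff is either
fixed or located automatically as the density valley between the two modes
of its bimodal distribution across the whole cohort. A sample is called
positive when its probe value is strictly greater than the cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

ER_PROBE = "205225_at"
HER2_PROBE = "216836_s_at"
ER_CUTOFF = 1.834

KDE_GRID_SIZE = 512
MIN_BIMODAL_N = 50


@dataclass
class StatusCallConfig:
    er_probe: str = ER_PROBE
    er_cutoff: float = ER_CUTOFF
    her2_probe: str = HER2_PROBE
    her2_cutoff: float | str = "auto"  # number, or "auto" for the density valley


def call_status(expr: ExpressionMatrix, probe: str, cutoff: float) -> pd.Series:
    """Boolean per-sample call: positive iff value strictly > cutoff."""
    values = expr.probe(probe)  # raises KeyError naming the probe if absent
    return values > cutoff


def find_bimodal_cutoff(values: Sequence[float], grid_size: int = KDE_GRID_SIZE) -> float:
    """Valley of a bimodal distribution, via Gaussian KDE.

    Fits a Gaussian kernel density (Silverman bandwidth) evaluated on a
    fixed grid spanning the data range, locates the two highest local
    density maxima and returns the grid point of minimum density strictly
    between them. Plateaus tie-break to the smallest grid value.

    Raises
    ------
    ValueError
        If fewer than ``MIN_BIMODAL_N`` values are supplied, or the density
        has no two local maxima ("no bimodal structure detected").
    """
    x = np.asarray(values, dtype=float)
    if x.size < MIN_BIMODAL_N:
        raise ValueError(
            f"need at least {MIN_BIMODAL_N} values to locate a bimodal cutoff, "
            f"got {x.size}"
        )
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), grid_size)
    dens = kde(grid)
    # interior local maxima: strictly above both neighbours (plateaus use the
    # left edge); endpoints qualify when above their single neighbour
    left = np.r_[-np.inf, dens[:-1]]
    right = np.r_[dens[1:], -np.inf]
    is_max = (dens > left) & (dens >= right)
    peaks = np.flatnonzero(is_max)
    if peaks.size < 2:
        raise ValueError("no bimodal structure detected")
    top_two = peaks[np.argsort(dens[peaks])][-2:]
    lo, hi = sorted(top_two)
    if hi - lo < 2:
        raise ValueError("no bimodal structure detected")
    between = dens[lo + 1 : hi]
    cut_idx = lo + 1 + int(np.argmin(between))  # argmin -> first = smallest grid value
    return float(grid[cut_idx])


def resolve_her2_cutoff(expr: ExpressionMatrix, cfg: StatusCallConfig) -> float:
    """The HER2 cutoff: fixed from config, or the density valley over the
    full input cohort (computed before any ER filtering)."""
    if cfg.her2_cutoff == "auto":
        return find_bimodal_cutoff(expr.probe(cfg.her2_probe).to_numpy())
    return float(cfg.her2_cutoff)


def status_table(expr: ExpressionMatrix, cfg: StatusCallConfig | None = None) -> pd.DataFrame:
    """Per-sample ER/HER2 calls and the ER+/HER2- selection flag."""
    cfg = cfg or StatusCallConfig()
    her2_cutoff = resolve_her2_cutoff(expr, cfg)
    er_call = call_status(expr, cfg.er_probe, cfg.er_cutoff)
    her2_call = call_status(expr, cfg.her2_probe, her2_cutoff)
    df = pd.DataFrame(
        {
            "er_call": er_call,
            "her2_call": her2_call,
            "selected": er_call & ~her2_call,
        }
    )
    df.index.name = "sample_id"
    df.attrs["her2_cutoff"] = her2_cutoff
    return df


def select_er_pos_her2_neg(
    expr: ExpressionMatrix, cfg: StatusCallConfig | None = None
) -> list[str]:
    """Sample ids called ER positive AND HER2 negative, in matrix order."""
    table = status_table(expr, cfg)
    selected = [s for s in expr.sample_ids if table.loc[s, "selected"]]
    if not selected:
        log.warning("ER+/HER2- selection is empty")
    return selected
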
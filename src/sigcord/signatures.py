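"""A generic prognostic-signature scoring engine.

A signature is a named scoring rule: a list of probe components (each with a
weight and a set label), an aggregation method, a threshold rule and a poor
direction. Four aggregations cover the published classifier families:

``mean``
    Unweighted mean over the present probes.
``weighted_sum``
    Sum of weight x expression over the present probes.
``up_minus_down``
    mean(up set) - mean(down set).
``centroid_correlation``
    Pearson correlation between the sample's expression over the centroid
    probes and the centroid vector. With two centroids — which must be
    labelled ``poor`` and ``good`` — the score is r(poor) - r(good).

The binary poor-prognosis call thresholds the score: strictly greater than
the resolved threshold when ``poor_direction`` is ``high``, strictly lower
when ``low`` (ties at the cutoff are "good"). Thresholds are ``fixed(c)``,
the cohort ``median``, or an empirical ``quantile(q)`` (linear-interpolation
convention, :func:`numpy.quantile` default).

Probes absent from the expression matrix are tolerated per set up to
``1 - min_gene_fraction`` and dropped with a warning; beyond that the
signature refuses to score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

AGGREGATIONS = ("mean", "weighted_sum", "up_minus_down", "centroid_correlation")


@dataclass(frozen=True)
class ThresholdRule:
    """fixed(c) | median | quantile(q in (0,1))."""

    kind: str
    value: float | None = None

    def __post_init__(self):
        if self.kind == "fixed":
            if self.value is None:
                raise ValueError("fixed threshold needs a value")
        elif self.kind == "quantile":
            if self.value is None or not 0 < self.value < 1:
                raise ValueError(f"quantile must be in (0,1), got {self.value}")
        elif self.kind != "median":
            raise ValueError(f"unknown threshold rule {self.kind!r}")


@dataclass(frozen=True)
class SignatureComponent:
    probe_id: str
    weight: float = 1.0
    set_label: str = "up"


@dataclass
class SignatureDefinition:
    name: str
    components: list[SignatureComponent]
    aggregation: str
    threshold_rule: ThresholdRule = field(default_factory=lambda: ThresholdRule("median"))
    poor_direction: str = "high"
    centroids: dict[str, dict[str, float]] | None = None
    min_gene_fraction: float = 0.7

    def __post_init__(self):
        if not self.components:
            raise ValueError(f"{self.name}: components must be non-empty")
        if self.aggregation not in AGGREGATIONS:
            raise ValueError(f"{self.name}: unknown aggregation {self.aggregation!r}")
        if self.poor_direction not in ("high", "low"):
            raise ValueError(f"{self.name}: poor_direction must be high or low")
        if not 0 < self.min_gene_fraction <= 1:
            raise ValueError(f"{self.name}: min_gene_fraction must be in (0,1]")
        for label in self.set_labels():
            probes = [c.probe_id for c in self.components if c.set_label == label]
            if len(probes) != len(set(probes)):
                raise ValueError(f"{self.name}: duplicate probe ids in set {label!r}")
        if self.aggregation == "up_minus_down":
            labels = self.set_labels()
            if "up" not in labels or "down" not in labels:
                raise ValueError(f"{self.name}: up_minus_down needs up and down sets")
        if self.aggregation == "centroid_correlation":
            if not self.centroids:
                raise ValueError(f"{self.name}: centroid_correlation needs centroids")
            if len(self.centroids) == 2 and set(self.centroids) != {"poor", "good"}:
                raise ValueError(
                    f"{self.name}: two centroids must be labelled poor/good"
                )

    def set_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.components:
            if c.set_label not in seen:
                seen.append(c.set_label)
        return seen

    def probes_in(self, label: str) -> list[str]:
        return [c.probe_id for c in self.components if c.set_label == label]


def _present(
    sig_name: str,
    probes: Sequence[str],
    expr: ExpressionMatrix,
    min_fraction: float,
    label: str,
) -> list[str]:
    index = set(expr.probe_ids)
    present = [p for p in probes if p in index]
    missing = [p for p in probes if p not in index]
    if len(present) < min_fraction * len(probes):
        raise ValueError(
            f"signature {sig_name!r}: only {len(present)}/{len(probes)} probes of "
            f"set {label!r} present (need {min_fraction:.0%}); missing: {missing}"
        )
    if missing:
        log.warning(
            "signature %s: dropping %d absent probe(s) from set %s",
            sig_name,
            len(missing),
            label,
        )
    return present


def score_signature(expr: ExpressionMatrix, sig: SignatureDefinition) -> pd.Series:
    """Per-sample continuous score (index = expression sample order)."""
    values = expr.values
    if sig.aggregation == "mean":
        probes = _present(
            sig.name, [c.probe_id for c in sig.components], expr,
            sig.min_gene_fraction, "all",
        )
        return values.loc[probes].mean(axis=0).rename(sig.name)
    if sig.aggregation == "weighted_sum":
        weights = {c.probe_id: c.weight for c in sig.components}
        probes = _present(
            sig.name, list(weights), expr, sig.min_gene_fraction, "all"
        )
        w = np.array([weights[p] for p in probes])
        return pd.Series(
            w @ values.loc[probes].to_numpy(), index=values.columns, name=sig.name
        )
    if sig.aggregation == "up_minus_down":
        up = _present(sig.name, sig.probes_in("up"), expr, sig.min_gene_fraction, "up")
        down = _present(
            sig.name, sig.probes_in("down"), expr, sig.min_gene_fraction, "down"
        )
        score = values.loc[up].mean(axis=0) - values.loc[down].mean(axis=0)
        return score.rename(sig.name)
    # centroid_correlation
    scores = None
    sign = {"poor": 1.0, "good": -1.0}
    for label, centroid in sig.centroids.items():
        probes = _present(
            sig.name, list(centroid), expr, sig.min_gene_fraction, label
        )
        c = np.array([centroid[p] for p in probes])
        sub = values.loc[probes].to_numpy()
        r = _pearson_columns(sub, c)
        contrib = r * (sign[label] if len(sig.centroids) == 2 else 1.0)
        scores = contrib if scores is None else scores + contrib
    return pd.Series(scores, index=values.columns, name=sig.name)


def _pearson_columns(matrix: np.ndarray, vector: np.ndarray) -> np.ndarray:
    """Pearson r between each column of ``matrix`` and ``vector``."""
    mc = matrix - matrix.mean(axis=0)
    vc = vector - vector.mean()
    denom = np.sqrt((mc**2).sum(axis=0) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (mc.T @ vc) / denom
    return np.where(denom > 0, r, 0.0)


def resolve_threshold(scores: Sequence[float], rule: ThresholdRule) -> float:
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot resolve a threshold on empty scores")
    if rule.kind == "fixed":
        return float(rule.value)
    if rule.kind == "median":
        return float(np.median(scores))
    return float(np.quantile(scores, rule.value))  # linear interpolation


@dataclass
class PrognosisCallMatrix:
    """Scores, resolved thresholds and boolean poor-prognosis calls.

    ``calls`` and ``scores`` are samples x signatures frames sharing index
    and columns; every call is derived from its score by the signature's
    resolved threshold.
    """

    scores: pd.DataFrame
    calls: pd.DataFrame
    thresholds: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_signatures(self) -> int:
        return self.calls.shape[1]


def build_call_matrix(
    expr: ExpressionMatrix, sigs: Sequence[SignatureDefinition]
) -> PrognosisCallMatrix:
    """Score every signature and threshold into poor/good calls.

    Column order follows the input signature order; a call is poor when the
    score is strictly beyond the threshold in the signature's poor direction.
    """
    names = [s.name for s in sigs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate signature names")
    scores = pd.DataFrame(index=expr.sample_ids)
    calls = pd.DataFrame(index=expr.sample_ids)
    thresholds = {}
    for sig in sigs:
        s = score_signature(expr, sig)
        t = resolve_threshold(s.to_numpy(), sig.threshold_rule)
        thresholds[sig.name] = t
        scores[sig.name] = s
        calls[sig.name] = (s > t) if sig.poor_direction == "high" else (s < t)
    scores.index.name = calls.index.name = "sample_id"
    return PrognosisCallMatrix(scores, calls, pd.Series(thresholds, name="threshold"))


# --- signature-definition files -------------------------------------------

def signature_from_dict(doc: Mapping) -> SignatureDefinition:
    rule = doc.get("threshold_rule", {"kind": "median"})
    threshold = ThresholdRule(rule["kind"], rule.get("value") or rule.get("q"))
    components = [
        SignatureComponent(
            probe_id=str(c["probe_id"]),
            weight=float(c.get("weight", 1.0)),
            set_label=str(c.get("set_label", "up")),
        )
        for c in doc["components"]
    ]
    return SignatureDefinition(
        name=str(doc["name"]),
        components=components,
        aggregation=str(doc["aggregation"]),
        threshold_rule=threshold,
        poor_direction=str(doc.get("poor_direction", "high")),
        centroids=doc.get("centroids"),
        min_gene_fraction=float(doc.get("min_gene_fraction", 0.7)),
    )


def read_signature(path: str | Path) -> SignatureDefinition:
    with open(path) as fh:
        return signature_from_dict(yaml.safe_load(fh))


def read_manifest(path: str | Path) -> list[SignatureDefinition]:
    """A manifest YAML lists signature files relative to its own directory."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [read_signature(path.parent / f) for f in doc["signatures"]]


def default_signatures() -> list[SignatureDefinition]:
    """The eight shipped signature definitions (synthetic reconstructions
    keyed to the synthetic cohort's probe naming)."""
    manifest = Path(__file__).parent / "data" / "synthetic_signatures" / "manifest.yaml"
    return read_manifest(manifest)
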
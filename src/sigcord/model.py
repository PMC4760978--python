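"""Model/Results objects orchestrating the full concordance analysis.

:class:`ConcordanceAnalysis` is built from an expression matrix, clinical
and survival tables and a panel of signature definitions; :meth:`fit` runs
the pipeline — receptor-status selection, signature scoring and calling,
modified NPI stratification, per-signature survival metrics per endpoint,
and the concordance suite — and returns a :class:`ConcordanceResults`
holding every table plus a ``summary()`` report. The analysis path is
fully deterministic: there is no resampling, and the DeLong AUC interval
is analytic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    concordance_flags,
    event_capture_table,
    poor_count,
    stratified_concordance,
    subset_median_curve,
)
from .io import (
    ClinicalRecord,
    Cohort,
    ENDPOINTS,
    ExpressionMatrix,
    SurvivalRecord,
    align_cohort,
    read_clinical,
    read_expression,
    read_survival,
)
from .npi import npi_table
from .signatures import (
    PrognosisCallMatrix,
    SignatureDefinition,
    build_call_matrix,
    default_signatures,
    read_manifest,
)
from .status import StatusCallConfig, status_table
from .survival import (
    HORIZON_MONTHS,
    cox_binary_hr,
    dichotomize,
    km_estimate,
    logrank,
    roc_auc,
)

log = logging.getLogger(__name__)


@dataclass
class ConcordanceResults:
    """Everything :meth:`ConcordanceAnalysis.fit` computes.

    Tables mirror the analysis outputs: per-signature survival performance
    per endpoint, NPI-stratum prognosis, the event-capture table over poor
    counts, overall and per-stratum concordance, and the median subset
    concordance versus panel size.
    """

    status: pd.DataFrame
    her2_cutoff: float
    selected_ids: list[str]
    call_matrix: PrognosisCallMatrix
    npi: pd.DataFrame
    npi_performance: pd.DataFrame
    npi_logrank: dict[str, tuple[float, float]]
    performance: pd.DataFrame
    event_capture: pd.DataFrame
    concordance: dict[str, float]
    strata: pd.DataFrame
    subset_medians: pd.DataFrame
    attrition: dict[str, int]
    horizon_months: float

    def summary(self) -> str:
        k = self.call_matrix.n_signatures
        lines = [
            "Signature concordance analysis",
            "=" * 34,
            f"signatures: {k} ({', '.join(self.call_matrix.signature_names)})",
            f"samples in expression matrix: {self.attrition['expression']}",
            f"ER+/HER2- selected: {self.attrition['selected']} "
            f"(HER2 cutoff {self.her2_cutoff:.3f})",
            f"analysed (clinical join): {self.attrition['analysed']}",
            "",
            "Per-signature poor-call fractions:",
        ]
        pct = (self.call_matrix.calls.mean() * 100).round(1)
        for name, value in pct.items():
            lines.append(f"  {name:<8s} {value:5.1f}% poor")
        lines.append("")
        for endpoint in self.performance["endpoint"].unique():
            sub = self.performance[self.performance["endpoint"] == endpoint]
            n = int(sub["n"].iloc[0])
            lines.append(f"{endpoint} (n = {n}): signature HR [95% CI], AUC [95% CI]")
            for _, r in sub.iterrows():
                lines.append(
                    f"  {r['signature']:<8s} HR {r['hr']:.2f} "
                    f"[{r['ci_low']:.2f}-{r['ci_high']:.2f}] p={r['p_value']:.2g}; "
                    f"AUC {r['auc']:.2f} [{r['auc_ci_low']:.2f}-{r['auc_ci_high']:.2f}]"
                )
            lines.append("")
        c = self.concordance
        lines += [
            f"strict concordance (0 or {k} poor calls): {100 * c['strict_rate']:.1f}% "
            f"(discordant {100 * (1 - c['strict_rate']):.1f}%)",
            f"broad concordance (0-1 or {k - 1}-{k}): {100 * c['broad_rate']:.1f}% "
            f"(discordant {100 * (1 - c['broad_rate']):.1f}%)",
            "",
            "Per NPI stratum (concordant-good / discordant / concordant-poor):",
        ]
        for group, r in self.strata.iterrows():
            lines.append(
                f"  {group:<12s} n={int(r['n']):4d}  "
                f"{100 * r['concordant_good']:5.1f}% / "
                f"{100 * r['discordant']:5.1f}% / "
                f"{100 * r['concordant_poor']:5.1f}%"
            )
        lines.append("")
        lines.append("Median strict concordance by panel size:")
        strict = self.subset_medians["overall_strict"]
        lines.append(
            "  " + "  ".join(f"k={s}: {100 * v:.1f}%" for s, v in strict.items())
        )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write every table as CSV plus a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _write(name: str, df: pd.DataFrame, index: bool = True):
            paths[name] = outdir / f"{name}.csv"
            df.to_csv(paths[name], index=index)

        _write("status", self.status)
        _write("scores", self.call_matrix.scores)
        _write("calls", self.call_matrix.calls.astype(int))
        _write("npi", self.npi)
        _write("npi_performance", self.npi_performance)
        _write("signature_performance", self.performance, index=False)
        _write("event_capture", self.event_capture)
        _write("strata_concordance", self.strata)
        _write("subset_medians", self.subset_medians)
        manifest = {
            "version": __version__,
            "her2_cutoff": self.her2_cutoff,
            "horizon_months": self.horizon_months,
            "concordance": self.concordance,
            "attrition": self.attrition,
            "npi_logrank": self.npi_logrank,
        }
        paths["manifest"] = outdir / "run_manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return paths


class ConcordanceAnalysis:
    """The end-to-end analysis as a fittable model object.

    Parameters
    ----------
    expression
        Probes x samples log2 matrix (must contain the ER and HER2 probes
        named in ``status_config``).
    clinical, survival
        Clinical and survival records (lists of records as produced by the
        readers or the synthetic generator).
    signatures
        Signature panel; defaults to the eight shipped synthetic
        reconstructions.
    status_config
        ER/HER2 probe and cutoff settings; HER2 defaults to the automatic
        density-valley cutoff.
    horizon_months
        Dichotomization horizon for the AUC (60 months = 5 years).
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        clinical: Iterable[ClinicalRecord],
        survival: Iterable[SurvivalRecord],
        signatures: Sequence[SignatureDefinition] | None = None,
        status_config: StatusCallConfig | None = None,
        horizon_months: float = HORIZON_MONTHS,
    ):
        self.expression = expression
        self.clinical = list(clinical)
        self.survival = list(survival)
        self.signatures = list(signatures) if signatures else default_signatures()
        self.status_config = status_config or StatusCallConfig()
        self.horizon_months = horizon_months

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        clinical_path: str | Path,
        survival_path: str | Path,
        manifest_path: str | Path | None = None,
        **kwargs,
    ) -> "ConcordanceAnalysis":
        signatures = read_manifest(manifest_path) if manifest_path else None
        return cls(
            read_expression(expression_path),
            read_clinical(clinical_path),
            read_survival(survival_path),
            signatures=signatures,
            **kwargs,
        )

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "ConcordanceAnalysis":
        """Build from a :class:`~sigcord.simulate.SyntheticCohort` (the
        truth table is deliberately not passed through)."""
        return cls(cohort.expression, cohort.clinical, cohort.survival, **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> ConcordanceResults:
        # 1. receptor status on the full input cohort (the automatic HER2
        #    cutoff uses every array, before any ER filtering)
        status = status_table(self.expression, self.status_config)
        her2_cutoff = float(status.attrs["her2_cutoff"])
        selected = [s for s in self.expression.sample_ids if status.loc[s, "selected"]]
        if not selected:
            raise ValueError("ER+/HER2- selection is empty; nothing to analyse")

        # 2. join with clinical/survival on the selected samples
        cohort = align_cohort(
            self.expression.subset_samples(selected), self.clinical, self.survival
        )
        analysed = cohort.sample_ids

        # 3. signature scores and poor/good calls
        calls = build_call_matrix(cohort.expression, self.signatures)
        k = calls.n_signatures

        # 4. modified NPI
        npi = npi_table(cohort.clinical)

        # 5. survival metrics
        pooled = self._pooled_survival(cohort)
        npi_performance, npi_logrank = self._npi_performance(npi, pooled)
        performance = self._signature_performance(cohort, calls)

        # 6. concordance suite (events pooled across endpoints, Table-3 style)
        counts = poor_count(calls)
        any_event = pooled["event"].reindex(counts.index).fillna(0).astype(int)
        capture = event_capture_table(counts.to_numpy(), any_event.to_numpy(), k)
        _, strict_rate = concordance_flags(counts, k, "strict")
        _, broad_rate = concordance_flags(counts, k, "broad")
        strata_summaries = stratified_concordance(calls, npi["group"])
        strata = pd.DataFrame(
            {
                group: {
                    "n": s.n,
                    "strict_rate": s.strict_rate,
                    "broad_rate": s.broad_rate,
                    "concordant_good": s.concordant_good,
                    "discordant": s.discordant,
                    "concordant_poor": s.concordant_poor,
                }
                for group, s in strata_summaries.items()
            }
        ).T.rename_axis("npi_group")
        subset_medians = pd.DataFrame(
            {
                "overall_strict": subset_median_curve(calls, "strict"),
                "overall_broad": subset_median_curve(calls, "broad"),
            }
        )
        for group, s in strata_summaries.items():
            subset_medians[f"{group}_strict"] = s.subset_medians

        attrition = {
            "expression": len(self.expression.sample_ids),
            "selected": len(selected),
            "analysed": len(analysed),
            "npi_available": int(npi["group"].notna().sum()),
        }
        for endpoint in ENDPOINTS:
            attrition[f"{endpoint.lower()}_available"] = int(
                (cohort.survival["endpoint"] == endpoint).sum()
            )

        return ConcordanceResults(
            status=status,
            her2_cutoff=her2_cutoff,
            selected_ids=selected,
            call_matrix=calls,
            npi=npi,
            npi_performance=npi_performance,
            npi_logrank=npi_logrank,
            performance=performance,
            event_capture=capture,
            concordance={"strict_rate": strict_rate, "broad_rate": broad_rate},
            strata=strata,
            subset_medians=subset_medians,
            attrition=attrition,
            horizon_months=self.horizon_months,
        )

    # ------------------------------------------------------------------
    @staticmethod
    def _pooled_survival(cohort: Cohort) -> pd.DataFrame:
        """Per-sample pooled outcome across endpoints: an event on either
        endpoint counts once; time is the first event (or last follow-up)."""
        sdf = cohort.survival
        rows = {}
        for sample_id, sub in sdf.groupby("sample_id"):
            ev = sub[sub["event"] == 1]
            if len(ev):
                rows[sample_id] = (float(ev["time_months"].min()), 1)
            else:
                rows[sample_id] = (float(sub["time_months"].max()), 0)
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["time_months", "event"]
        ).rename_axis("sample_id")

    def _npi_performance(self, npi: pd.DataFrame, pooled: pd.DataFrame):
        """Outcome by NPI stratum: event rates, 5-year survival, log-rank."""
        joined = npi.join(pooled, how="inner").dropna(subset=["group"])
        rows = []
        for group in ("low", "intermediate", "high"):
            sub = joined[joined["group"] == group]
            if sub.empty:
                continue
            curve = km_estimate(sub["time_months"], sub["event"])
            rows.append(
                {
                    "npi_group": group,
                    "n": len(sub),
                    "pct": 100.0 * len(sub) / len(joined),
                    "n_events": int(sub["event"].sum()),
                    "pct_events": 100.0 * sub["event"].mean(),
                    "surv_5yr": curve.survival_at(self.horizon_months),
                }
            )
        table = pd.DataFrame(rows).set_index("npi_group")
        tests = {}
        if joined["group"].nunique() >= 2:
            stat, p = logrank(
                joined["time_months"], joined["event"], joined["group"]
            )
            tests["all_groups"] = (stat, p)
        return table, tests

    def _signature_performance(
        self, cohort: Cohort, calls: PrognosisCallMatrix
    ) -> pd.DataFrame:
        """Per endpoint and signature: poor fraction, Cox HR of the poor
        call, log-rank, and the AUC of the continuous score against the
        5-year dichotomized outcome."""
        rows = []
        for endpoint in ENDPOINTS:
            surv = cohort.survival_for(endpoint)
            ids = [s for s in calls.sample_ids if s in surv.index]
            if not ids:
                log.warning("no survival rows for endpoint %s", endpoint)
                continue
            times = surv.loc[ids, "time_months"].to_numpy()
            events = surv.loc[ids, "event"].to_numpy().astype(int)
            labels = dichotomize(times, events, self.horizon_months)
            usable = labels != "excluded"
            for name in calls.signature_names:
                call = calls.calls.loc[ids, name].to_numpy().astype(int)
                score = calls.scores.loc[ids, name].to_numpy()
                row = {
                    "endpoint": endpoint,
                    "signature": name,
                    "n": len(ids),
                    "n_poor": int(call.sum()),
                    "pct_poor": 100.0 * call.mean(),
                }
                try:
                    hr = cox_binary_hr(times, events, call)
                    stat, p_lr = logrank(times, events, call)
                    row.update(
                        hr=hr.hr, ci_low=hr.ci_low, ci_high=hr.ci_high,
                        p_value=hr.p_value, logrank_p=p_lr,
                        converged=hr.converged,
                    )
                except ValueError as exc:
                    log.warning("%s/%s: %s", endpoint, name, exc)
                    row.update(
                        hr=np.nan, ci_low=np.nan, ci_high=np.nan,
                        p_value=np.nan, logrank_p=np.nan, converged=False,
                    )
                try:
                    auc, lo, hi = roc_auc(score[usable], labels[usable])
                    row.update(auc=auc, auc_ci_low=lo, auc_ci_high=hi)
                except ValueError as exc:
                    log.warning("%s/%s AUC: %s", endpoint, name, exc)
                    row.update(auc=np.nan, auc_ci_low=np.nan, auc_ci_high=np.nan)
                rows.append(row)
        return pd.DataFrame(rows)
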
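"""Synthetic ER+/HER2- breast-cancer cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without any microarray download:

* a standard-normal latent proliferation/risk factor per sample;
* signature genes loading on that factor (a deterministic 3:1 up/down sign
  pattern per signature) plus independent Gaussian noise, on a log2 scale;
* bimodal single-probe distributions for the ER probe (205225_at) and the
  HER2 probe (216836_s_at), each a two-component Gaussian mixture whose
  true density valley sits near the published cutoffs (1.834 and 1.62);
* clinical covariates tied to latent risk — grade as an ordinal cut of
  risk + noise, size log-normal with a risk shift, nodal status Bernoulli
  with a logit linear in risk;
* exponential proportional-hazards survival (log-hazard linear in the
  standardized latent risk) with independent exponential censoring and an
  administrative cutoff, drawn separately per endpoint (DMFS and BCSS,
  BCSS with a lower baseline rate) with partial availability per endpoint.

Randomness derives from a single seed; each component draws from its own
deterministic substream, so adding a component never perturbs earlier
draws. The ground truth (latent risk, true receptor classes, expected
signature scores) is carried separately and never consumed by the analysis
modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalRecord,
    ExpressionMatrix,
    SurvivalRecord,
    write_clinical,
    write_expression,
    write_survival,
)
from .status import ER_PROBE, HER2_PROBE

# stable substream codes: appending new components must not shift old draws
_STREAMS = {
    "latent": 1,
    "background": 2,
    "signatures": 3,
    "er": 4,
    "her2": 5,
    "clinical": 6,
    "survival_dmfs": 7,
    "survival_bcss": 8,
    "availability": 9,
}

UP_FRACTION = 0.75  # fraction of each signature's genes loading positively

DEFAULT_SIGNATURE_GENE_COUNTS = {
    "WANG76": 76,
    "CIN70": 70,
    "CIN25": 25,
    "CSR": 50,
    "IGS": 60,
    "T52": 52,
    "T17": 17,
    "GGI": 97,
}


@dataclass(frozen=True)
class Mixture:
    """Two-component Gaussian mixture for a receptor probe."""

    mean_neg: float
    mean_pos: float
    sd: float
    weight_pos: float


@dataclass(frozen=True)
class ClinicalLinks:
    """Coefficients tying clinical covariates to latent risk."""

    grade_thresholds: tuple[float, float] = (-0.85, 0.85)
    grade_noise_sd: float = 0.8
    size_log_mean: float = math.log(1.8)  # cm
    size_log_sd: float = 0.45
    size_risk_coef: float = 0.15  # log-size shift per risk SD
    node_intercept: float = -0.9  # logit scale
    node_risk_coef: float = 0.8


@dataclass
class CohortConfig:
    n_samples: int = 1127
    n_background_genes: int = 200
    signature_gene_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURE_GENE_COUNTS)
    )
    latent_risk_loading: float = 0.5  # log2 units per risk SD
    noise_sd: float = 0.5  # log2 units
    er_mixture: Mixture = Mixture(0.93, 3.0, 0.4, 0.8)
    her2_mixture: Mixture = Mixture(1.0, 2.4, 0.2, 0.15)
    log_hr_per_sd: float = math.log(2.5)
    baseline_hazard_rate: float = 0.003  # events / month (DMFS)
    bcss_rate_fraction: float = 0.5  # BCSS baseline relative to DMFS
    censoring_rate: float = 0.008  # censorings / month
    admin_cutoff_months: float = 240.0
    endpoint_availability: tuple[float, float] = (0.6, 0.45)  # (DMFS, BCSS)
    clinical_links: ClinicalLinks = ClinicalLinks()
    seed: int = 0

    def validate(self) -> None:
        """Raise ValueError naming the first violated field."""
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        if self.n_background_genes <= 0:
            raise ValueError("n_background_genes must be > 0")
        for name, count in self.signature_gene_counts.items():
            if count <= 0:
                raise ValueError(f"signature_gene_counts[{name!r}] must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for label, mix in (("er_mixture", self.er_mixture), ("her2_mixture", self.her2_mixture)):
            if mix.sd <= 0:
                raise ValueError(f"{label}.sd must be > 0")
            if not 0 < mix.weight_pos < 1:
                raise ValueError(f"{label}.weight_pos must be in (0, 1)")
            if not mix.mean_neg < mix.mean_pos:
                raise ValueError(f"{label}: mean_neg must be < mean_pos")
        if self.baseline_hazard_rate <= 0:
            raise ValueError("baseline_hazard_rate must be > 0")
        if not 0 < self.bcss_rate_fraction <= 1:
            raise ValueError("bcss_rate_fraction must be in (0, 1]")
        if self.censoring_rate <= 0:
            raise ValueError("censoring_rate must be > 0")
        if self.admin_cutoff_months <= 0:
            raise ValueError("admin_cutoff_months must be > 0")
        for p in self.endpoint_availability:
            if not 0 < p <= 1:
                raise ValueError("endpoint_availability entries must be in (0, 1]")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    survival: list[SurvivalRecord]
    truth: pd.DataFrame  # latent risk, true classes, expected scores
    config: CohortConfig

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write expression TSV, clinical/survival/truth CSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "expression": outdir / "expression.tsv",
            "clinical": outdir / "clinical.csv",
            "survival": outdir / "survival.csv",
            "truth": outdir / "truth.csv",
        }
        write_expression(self.expression, paths["expression"])
        write_clinical(self.clinical, paths["clinical"])
        write_survival(self.survival, paths["survival"])
        self.truth.to_csv(paths["truth"], index=False)
        return paths


def _rng(config: CohortConfig, stream: str, extra: int | None = None) -> np.random.Generator:
    key = [config.seed, _STREAMS[stream]]
    if extra is not None:
        key.append(extra)
    return np.random.default_rng(np.random.SeedSequence(key))


def signature_probe_ids(name: str, count: int) -> list[str]:
    return [f"{name}_{j + 1:03d}_at" for j in range(count)]


def signature_signs(count: int) -> np.ndarray:
    """Deterministic +1/-1 loading pattern: first 75% up, rest down."""
    n_up = math.ceil(UP_FRACTION * count)
    return np.r_[np.ones(n_up), -np.ones(count - n_up)]


def _survival_records(
    config: CohortConfig,
    sample_ids: list[str],
    z_std: np.ndarray,
    endpoint: str,
    baseline: float,
    available: np.ndarray,
) -> list[SurvivalRecord]:
    rng = _rng(config, f"survival_{endpoint.lower()}")
    n = len(sample_ids)
    rate = baseline * np.exp(config.log_hr_per_sd * z_std)
    event_time = rng.exponential(1.0 / rate)
    censor_time = np.minimum(
        rng.exponential(1.0 / config.censoring_rate, size=n),
        config.admin_cutoff_months,
    )
    observed = event_time <= censor_time
    time = np.where(observed, event_time, censor_time)
    return [
        SurvivalRecord(sample_ids[i], float(time[i]), int(observed[i]), endpoint)
        for i in range(n)
        if available[i]
    ]


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort from the generating model.

    Identical configs (including the seed) give bit-identical cohorts.
    """
    config = config or CohortConfig()
    config.validate()
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    z = _rng(config, "latent").standard_normal(n)
    z_std = (z - z.mean()) / z.std()

    # expression: background genes, then signature genes, then the 2 probes
    rows: dict[str, np.ndarray] = {}
    bg_rng = _rng(config, "background")
    bg_means = bg_rng.normal(2.0, 1.0, size=config.n_background_genes)
    for g in range(config.n_background_genes):
        rows[f"BG_{g + 1:04d}_at"] = bg_means[g] + bg_rng.normal(
            0.0, config.noise_sd, size=n
        )
    truth = pd.DataFrame({"sample_id": sample_ids, "latent_risk": z})
    for idx, (name, count) in enumerate(sorted(config.signature_gene_counts.items())):
        sig_rng = _rng(config, "signatures", extra=idx)
        signs = signature_signs(count)
        noise = sig_rng.normal(0.0, config.noise_sd, size=(count, n))
        for j, probe in enumerate(signature_probe_ids(name, count)):
            rows[probe] = 2.0 + signs[j] * config.latent_risk_loading * z + noise[j]
        # expected mean-aggregated score, up to the additive baseline
        truth[f"expected_score_{name}"] = (
            signs.mean() * config.latent_risk_loading * z
        )

    er_rng = _rng(config, "er")
    er_true = er_rng.random(n) < config.er_mixture.weight_pos
    rows[ER_PROBE] = er_rng.normal(
        np.where(er_true, config.er_mixture.mean_pos, config.er_mixture.mean_neg),
        config.er_mixture.sd,
    )
    her2_rng = _rng(config, "her2")
    her2_true = her2_rng.random(n) < config.her2_mixture.weight_pos
    rows[HER2_PROBE] = her2_rng.normal(
        np.where(her2_true, config.her2_mixture.mean_pos, config.her2_mixture.mean_neg),
        config.her2_mixture.sd,
    )
    truth["er_true"] = er_true.astype(int)
    truth["her2_true"] = her2_true.astype(int)

    expression = ExpressionMatrix(
        pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    )

    links = config.clinical_links
    cl_rng = _rng(config, "clinical")
    grade_latent = z + cl_rng.normal(0.0, links.grade_noise_sd, size=n)
    grade = 1 + (grade_latent > links.grade_thresholds[0]).astype(int) + (
        grade_latent > links.grade_thresholds[1]
    ).astype(int)
    size = np.exp(
        cl_rng.normal(links.size_log_mean, links.size_log_sd, size=n)
        + links.size_risk_coef * z
    )
    node_p = 1.0 / (1.0 + np.exp(-(links.node_intercept + links.node_risk_coef * z)))
    node = (cl_rng.random(n) < node_p).astype(int)
    clinical = [
        ClinicalRecord(sample_ids[i], float(size[i]), int(grade[i]), int(node[i]))
        for i in range(n)
    ]

    avail_rng = _rng(config, "availability")
    avail_dmfs = avail_rng.random(n) < config.endpoint_availability[0]
    avail_bcss = avail_rng.random(n) < config.endpoint_availability[1]
    survival = _survival_records(
        config, sample_ids, z_std, "DMFS", config.baseline_hazard_rate, avail_dmfs
    ) + _survival_records(
        config,
        sample_ids,
        z_std,
        "BCSS",
        config.baseline_hazard_rate * config.bcss_rate_fraction,
        avail_bcss,
    )

    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        survival=survival,
        truth=truth,
        config=config,
    )
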
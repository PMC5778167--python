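"""Seeded generator of RECIST-style trial arms with known ground truth.

The generator is the generative reading of the hierarchical piecewise
model: each patient carries normally distributed deviations of the decay
and re-growth rates (between-patient level); each of their 1-7 target
lesions carries an independent log-normal baseline diameter and further
independent normal slope deviations (within-patient level); every lesion
switches from decay to re-growth at one common day ``sp_true``; and each
scheduled visit produces the structural diameter plus additive Gaussian
measurement error, truncated at 0 mm.

Realised lesion slopes are therefore exactly additive,

    decay_ij    = decay_mean    + decay_dev_i    + decay_dev_ij,
    regrowth_ij = regrowth_mean + regrowth_dev_i + regrowth_dev_ij,

with all random variables mutually independent — in particular decay and
re-growth are uncorrelated by construction, which is what the downstream
correlation analysis is validated against.

Imaging stops once a patient reaches PD: when ``dropout_at_pd`` is set, a
patient's series is truncated after their first PD-classified visit
(death is not modelled).  The default configuration emulates a
vemurafenib-like arm: week-6 median SLD change near -35 %, about 80 % of
patients with more than one target lesion, and a clipped-at-zero
measurement fraction below 1 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_io import CohortDataset, RecistThresholds
from .piecewise import PiecewiseParams, observe

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TruthSummary",
    "generate",
    "summarize_truth",
    "load_config",
    "save_config",
]

#: Lesion-count distribution patterned on melanoma phase-III arms: support
#: {1, 2, 3, 4, 5, 7} and ~80 % of patients with more than one target lesion.
DEFAULT_LESION_PMF: dict[int, float] = {
    1: 0.20, 2: 0.28, 3: 0.22, 4: 0.15, 5: 0.10, 7: 0.05,
}


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic-cohort generator.

    Slope units are mm/day; baseline parameters are on the natural-log
    scale of diameters in mm.  ``*_sd_between`` is the patient-level SD of
    a rate, ``*_sd_within`` the lesion-level SD.
    """

    n_patients: int = 200
    lesion_count_pmf: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LESION_PMF))
    bsl_log_mean: float = 3.30       # median baseline diameter ~27 mm
    bsl_log_sd: float = 0.25
    decay_mean: float = -0.22        # week-6 median SLD change ~ -33 %
    decay_sd_between: float = 0.05
    decay_sd_within: float = 0.05
    regrowth_mean: float = 0.04
    regrowth_sd_between: float = 0.012
    regrowth_sd_within: float = 0.012
    sp_true: float = 63.0
    residual_sd: float = 1.5
    visit_days: tuple[int, ...] = (0, 42, 84, 147, 210)
    dropout_at_pd: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesion_count_pmf",
                           {int(k): float(v) for k, v in self.lesion_count_pmf.items()})
        object.__setattr__(self, "visit_days", tuple(int(d) for d in self.visit_days))
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        pmf = self.lesion_count_pmf
        if not pmf or any(k < 1 or k > 7 for k in pmf):
            raise ConfigError("lesion_count_pmf support must lie in {1,...,7}")
        if any(v < 0 for v in pmf.values()) or abs(sum(pmf.values()) - 1.0) > 1e-9:
            raise ConfigError("lesion_count_pmf must be non-negative and sum to 1")
        for name in ("bsl_log_sd", "decay_sd_between", "decay_sd_within",
                     "regrowth_sd_between", "regrowth_sd_within", "residual_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.sp_true <= 0:
            raise ConfigError("sp_true must be > 0")
        days = self.visit_days
        if not days or days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("visit_days must be strictly increasing and start at 0")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows that the analyst normally does not.

    patients : per patient: lesion count, patient-level slope deviations and
        the RECIST category at the first on-treatment visit.
    lesions : per lesion: realised :class:`PiecewiseParams` components and
        the individual random-effect draws.
    clipped_fraction : fraction of generated measurements truncated at 0 mm.
    """

    patients: pd.DataFrame
    lesions: pd.DataFrame
    config: SyntheticConfig
    clipped_fraction: float


@dataclass(frozen=True)
class TruthSummary:
    """True variability and correlation targets implied by a GroundTruth."""

    cv_table: pd.DataFrame
    decay_regrowth_corr: float
    r_squared: float
    frac_positive_decay: float
    frac_negative_regrowth: float


def generate(config: SyntheticConfig,
             seed: int | None = None) -> tuple[CohortDataset, GroundTruth]:
    """Simulate one trial arm; identical output for identical seed.

    ``seed`` overrides ``config.seed`` when given.  Returns the observed
    cohort (in :mod:`data_io` form) and the full ground truth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts = np.array(sorted(config.lesion_count_pmf))
    probs = np.array([config.lesion_count_pmf[int(k)] for k in counts])
    days = np.array(config.visit_days, dtype=int)
    on_days = days[days > 0]
    thresholds = RecistThresholds()

    meas_rows: list[tuple] = []
    pat_rows: list[tuple] = []
    les_rows: list[tuple] = []
    n_clipped = 0
    n_total = 0

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        m = int(rng.choice(counts, p=probs))
        d_i = rng.normal(0.0, config.decay_sd_between) if config.decay_sd_between else 0.0
        g_i = rng.normal(0.0, config.regrowth_sd_between) if config.regrowth_sd_between else 0.0

        lesion_params = []
        obs = np.empty((m, days.size))
        for j in range(m):
            b_ij = rng.normal(0.0, config.bsl_log_sd) if config.bsl_log_sd else 0.0
            dd_ij = rng.normal(0.0, config.decay_sd_within) if config.decay_sd_within else 0.0
            gg_ij = rng.normal(0.0, config.regrowth_sd_within) if config.regrowth_sd_within else 0.0
            params = PiecewiseParams(
                bsl=float(np.exp(config.bsl_log_mean + b_ij)),
                decay=config.decay_mean + d_i + dd_ij,
                regrowth=config.regrowth_mean + g_i + gg_ij,
                sp=config.sp_true,
            )
            lesion_params.append((params, b_ij, dd_ij, gg_ij))
            obs[j] = observe(params, days, config.residual_sd, rng)

        # an exactly-zero observation is (a.s.) one whose Gaussian draw fell
        # below zero and was truncated
        n_clipped += int((obs == 0.0).sum())
        n_total += obs.size

        # baseline-referenced RECIST category per visit, for dropout and truth
        sld = obs.sum(axis=0)
        cats = [thresholds.classify(100.0 * (sld[k] - sld[0]) / sld[0],
                                    all_zero=bool((obs[:, k] == 0.0).all()))
                for k in range(days.size)]
        last_idx = days.size - 1
        if config.dropout_at_pd:
            for k in range(1, days.size):
                if cats[k] == "PD":
                    last_idx = k
                    break
        wk6_cat = cats[1] if days.size > 1 else "SD"

        pat_rows.append((pid, m, d_i, g_i, wk6_cat))
        for j, (params, b_ij, dd_ij, gg_ij) in enumerate(lesion_params):
            lid = f"L{j + 1}"
            les_rows.append((pid, lid, params.bsl, params.decay, params.regrowth,
                             b_ij, dd_ij, gg_ij))
            for k in range(last_idx + 1):
                meas_rows.append((pid, lid, int(days[k]), obs[j, k]))

    measurements = pd.DataFrame(
        meas_rows, columns=["patient_id", "lesion_id", "day", "diameter_mm"])
    dataset = CohortDataset(measurements, tuple(config.visit_days),
                            arm_label="synthetic")
    truth = GroundTruth(
        patients=pd.DataFrame(pat_rows, columns=[
            "patient_id", "n_lesions", "decay_dev", "regrowth_dev", "wk6_category"]),
        lesions=pd.DataFrame(les_rows, columns=[
            "patient_id", "lesion_id", "bsl", "decay", "regrowth",
            "bsl_log_dev", "decay_dev", "regrowth_dev"]),
        config=config,
        clipped_fraction=n_clipped / n_total,
    )
    return dataset, truth


def _cv(sd: float, mean: float) -> float:
    # CV is undefined at mean 0; flagged as NaN, never returned as infinity
    return np.nan if mean == 0 else sd / abs(mean)


def summarize_truth(truth: GroundTruth) -> TruthSummary:
    """True CVs, slope correlation and sign-anomaly fractions of a cohort.

    CVs come from the generating configuration (they are the estimands the
    fitted variance components are compared against); the correlation and
    anomaly fractions are empirical over the realised lesions.
    """
    c = truth.config
    rows = [
        ("decay", "between_patient", c.decay_mean, c.decay_sd_between),
        ("decay", "within_patient", c.decay_mean, c.decay_sd_within),
        ("regrowth", "between_patient", c.regrowth_mean, c.regrowth_sd_between),
        ("regrowth", "within_patient", c.regrowth_mean, c.regrowth_sd_within),
    ]
    cv_table = pd.DataFrame(
        [(p, lvl, mean, sd, _cv(sd, mean)) for p, lvl, mean, sd in rows],
        columns=["parameter", "level", "mean", "sd", "cv"])
    les = truth.lesions
    if les["decay"].std() > 0 and les["regrowth"].std() > 0:
        corr = float(np.corrcoef(les["decay"], les["regrowth"])[0, 1])
    else:
        corr = np.nan
    return TruthSummary(
        cv_table=cv_table,
        decay_regrowth_corr=corr,
        r_squared=corr ** 2 if np.isfinite(corr) else np.nan,
        frac_positive_decay=float((les["decay"] > 0).mean()),
        frac_negative_regrowth=float((les["regrowth"] < 0).mean()),
    )


def load_config(path: str | Path) -> SyntheticConfig:
    """Read a :class:`SyntheticConfig` from a flat YAML mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "lesion_count_pmf" in raw:
        raw["lesion_count_pmf"] = {int(k): float(v)
                                   for k, v in raw["lesion_count_pmf"].items()}
    if "visit_days" in raw:
        raw["visit_days"] = tuple(raw["visit_days"])
    return SyntheticConfig(**raw)


def save_config(config: SyntheticConfig, path: str | Path) -> None:
    """Write a config as flat YAML (round-trips through :func:`load_config`)."""
    raw = asdict(config)
    raw["visit_days"] = list(config.visit_days)
    raw["lesion_count_pmf"] = {int(k): float(v)
                               for k, v in config.lesion_count_pmf.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
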
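"""Post-fit analysis: variability decomposition, slope correlation, diagnostics.

Four questions are answered from a fitted hierarchy (and its cohort):

* how variable are the decay and re-growth rates between patients versus
  between lesions of the same patient — coefficient of variation
  (SD / |population mean|) per parameter and level (:func:`cv_table`);
* does a lesion's shrinkage rate predict how fast it re-grows once
  resistant — r^2 of re-growth on decay over per-lesion estimates, plus
  the fraction of sign-anomalous lesions (growing under treatment, or
  shrinking after the switch) (:func:`decay_regrowth_correlation`);
* does the model describe the data — observed versus fitted diameters
  about the line of unity (:func:`observed_vs_fitted`);
* what does the arm look like clinically — baseline SLD / ILD quartiles,
  week-6 ORR and week-6 SLD-change quartiles (:func:`arm_summary`).

Per-lesion slopes default to the empirical-Bayes estimates from the fit;
EB shrinkage pulls extreme lesions toward the population mean and can
attenuate the correlation, so raw per-lesion least-squares slopes are
available via ``estimator="ols"``.  All percentiles use linear
interpolation between order statistics (NumPy default, type 7).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CohortDataset, RecistThresholds, summarize_visit
from .fitting import FitResult
from .piecewise import predict_matrix

__all__ = [
    "cv_table",
    "CorrelationReport",
    "decay_regrowth_correlation",
    "observed_vs_fitted",
    "arm_summary",
    "plot_observed_vs_fitted",
    "plot_decay_vs_regrowth",
]


def cv_table(fit: FitResult) -> pd.DataFrame:
    """Coefficient-of-variation table of the fitted variance components.

    One row per (parameter, level) present in the fitted model, with the
    population mean, the SD of that random-effect level and
    ``cv = sd / |mean|``.  A zero population mean leaves the CV undefined:
    the entry is NaN and ``flagged`` is True, never infinity.
    """
    if not fit.converged:
        raise ValueError("cv_table requires a converged fit")
    th = fit.theta
    rows = []
    for param, mean in (("decay", th.decay), ("regrowth", th.regrowth)):
        for level, attr in (("between_patient", f"sd_{param}_patient"),
                            ("within_patient", f"sd_{param}_lesion")):
            if attr not in fit.spec.sd_names:
                continue
            sd = getattr(th, attr)
            cv = np.nan if mean == 0 else sd / abs(mean)
            rows.append((param, level, mean, sd, cv, mean == 0))
    return pd.DataFrame(rows, columns=[
        "parameter", "level", "mean", "sd", "cv", "flagged"])


@dataclass(frozen=True)
class CorrelationReport:
    """Decay-vs-re-growth association over per-lesion slope estimates.

    ``r_squared`` is the coefficient of determination of an ordinary
    least-squares regression of re-growth on decay (NaN and ``flagged``
    when either slope has zero variance across lesions);
    ``fraction_positive_decay`` / ``fraction_negative_regrowth`` count the
    sign-anomalous lesions.
    """

    r_squared: float
    slope: float
    n_lesions: int
    fraction_positive_decay: float
    fraction_negative_regrowth: float
    flagged: bool = False
    estimator: str = "eb"


def _ols_lesion_slopes(dataset: CohortDataset, sp: float) -> pd.DataFrame:
    rows = []
    for (pid, lid), grp in dataset.measurements.groupby(
            ["patient_id", "lesion_id"], sort=True):
        X = predict_matrix(sp, np.asarray(grp["day"], float))
        if np.linalg.matrix_rank(X) < 3:
            continue
        beta, *_ = np.linalg.lstsq(X, np.asarray(grp["diameter_mm"], float),
                                   rcond=None)
        rows.append((pid, lid, beta[0], beta[1], beta[2]))
    return pd.DataFrame(rows, columns=[
        "patient_id", "lesion_id", "bsl", "decay", "regrowth"])


def decay_regrowth_correlation(fit: FitResult, *, estimator: str = "eb",
                               dataset: CohortDataset | None = None,
                               ) -> CorrelationReport:
    """r^2 between per-lesion decay and re-growth rates, plus sign anomalies.

    ``estimator="eb"`` uses the fit's empirical-Bayes lesion estimates;
    ``estimator="ols"`` refits each lesion by unpenalised least squares on
    the piecewise design (requires ``dataset``) and so avoids EB shrinkage.
    """
    if estimator == "eb":
        table = fit.eb_estimates
    elif estimator == "ols":
        if dataset is None:
            raise ValueError("estimator='ols' requires the dataset")
        table = _ols_lesion_slopes(dataset, fit.sp_used)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if len(table) < 3:
        raise ValueError("need at least 3 lesions with slope estimates")
    d = np.asarray(table["decay"], float)
    g = np.asarray(table["regrowth"], float)
    flagged = bool(np.std(d) == 0 or np.std(g) == 0)
    if flagged:
        r2, slope = np.nan, np.nan
    else:
        res = stats.linregress(d, g)
        r2, slope = float(res.rvalue ** 2), float(res.slope)
    return CorrelationReport(
        r_squared=r2, slope=slope, n_lesions=len(table),
        fraction_positive_decay=float((d > 0).mean()),
        fraction_negative_regrowth=float((g < 0).mean()),
        flagged=flagged, estimator=estimator)


def observed_vs_fitted(dataset: CohortDataset, fit: FitResult,
                       ) -> tuple[pd.DataFrame, dict]:
    """Observed and EB-fitted diameter per measurement, with unity-line metrics.

    Returns the paired table and a dict with ``r2_unity``
    (``1 - SS(obs - fitted) / SS(obs - mean)``, i.e. agreement about the
    line of unity) and the mean absolute error in mm.  The fit must come
    from exactly this dataset.
    """
    ft = fit.fitted
    key = ["patient_id", "lesion_id", "day"]
    same = (len(ft) == len(dataset.measurements)
            and ft[key + ["diameter_mm"]].reset_index(drop=True).equals(
                dataset.measurements[key + ["diameter_mm"]].reset_index(drop=True)))
    if not same:
        raise ValueError("fit does not correspond to this dataset")
    table = ft.rename(columns={"diameter_mm": "observed_mm"})[
        key[:2] + ["day", "observed_mm", "fitted_mm"]]
    obs = np.asarray(table["observed_mm"], float)
    pred = np.asarray(table["fitted_mm"], float)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    metrics = {
        "r2_unity": 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        "mae_mm": float(np.mean(np.abs(obs - pred))),
        "n_obs": len(obs),
    }
    return table, metrics


def arm_summary(dataset: CohortDataset, *,
                thresholds: RecistThresholds = RecistThresholds()) -> dict:
    """Arm-level imaging characteristics: the standard trial-table quantities.

    Baseline SLD and individual lesion diameter (ILD) medians with 25th and
    75th percentiles, plus — at the first on-treatment visit ("week 6" on
    the default schedule) — the responder count, ORR percent and the
    quartiles of the percent SLD change.  Without any on-treatment visit
    the record is partial and ``complete`` is False.
    """
    base = summarize_visit(dataset, 0, thresholds=thresholds)
    ild = dataset.measurements.loc[dataset.measurements["day"] == 0, "diameter_mm"]
    q = lambda v, p: float(np.percentile(np.asarray(v, float), p))  # noqa: E731
    out = {
        "n_patients": dataset.n_patients,
        "sld_baseline_median": q(base["sld_mm"], 50),
        "sld_baseline_q25": q(base["sld_mm"], 25),
        "sld_baseline_q75": q(base["sld_mm"], 75),
        "ild_baseline_median": q(ild, 50),
        "ild_baseline_q25": q(ild, 25),
        "ild_baseline_q75": q(ild, 75),
        "complete": False,
    }
    if dataset.on_treatment_days:
        first = dataset.on_treatment_days[0]
        summ = summarize_visit(dataset, first, thresholds=thresholds)
        if len(summ):
            responders = int(summ["recist_category"].isin(["CR", "PR"]).sum())
            out.update({
                "first_visit_day": first,
                "orr_n": responders,
                "orr_percent": float(round(100.0 * responders / len(summ))),
                "sld_change_median": q(summ["pct_change_from_baseline"], 50),
                "sld_change_q25": q(summ["pct_change_from_baseline"], 25),
                "sld_change_q75": q(summ["pct_change_from_baseline"], 75),
                "complete": True,
            })
    return out


def plot_observed_vs_fitted(table: pd.DataFrame, path) -> None:
    """Observed-vs-fitted scatter with the line of unity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(table["fitted_mm"], table["observed_mm"], s=6, alpha=0.4,
               edgecolors="none")
    lim = max(table["fitted_mm"].max(), table["observed_mm"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="line of unity")
    ax.set_xlabel("fitted diameter (mm)")
    ax.set_ylabel("observed diameter (mm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decay_vs_regrowth(eb_estimates: pd.DataFrame, path) -> None:
    """Per-lesion decay-vs-re-growth scatter with zero lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(eb_estimates["decay"], eb_estimates["regrowth"], s=8, alpha=0.5,
               edgecolors="none")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("decay rate (mm/day)")
    ax.set_ylabel("re-growth rate (mm/day)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
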
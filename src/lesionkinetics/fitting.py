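"""Maximum-likelihood estimation of the hierarchical piecewise-linear model.

Two random-effect structures are supported for the lesion diameter series:

``lesion_only``
    every lesion is an independent unit carrying a log-normal baseline
    random effect and normal decay / re-growth random effects;
``patient_lesion``
    lesions are nested in patients: in addition to the lesion-level effects,
    each patient carries normal decay and re-growth deviations shared by all
    their lesions.

All random effects are mutually independent (diagonal covariance), the
baseline enters as ``bsl = exp(beta0 + b)`` with ``b ~ N(0, sd_bsl^2)`` to
keep diameters positive, and a single residual SD is shared by all
observations of a fit.  The switch point ``sp`` is one fixed population
value per fit; it is chosen by profiling the marginal log-likelihood over
the midpoints of consecutive on-treatment visit days (:func:`sp_candidates`
/ :func:`select_sp`), and the two hierarchies are compared at a common
``sp`` by their maximised log-likelihoods (:func:`compare_hierarchies`).

Marginal likelihood
-------------------
Conditional on the baseline effects ``b`` the model is linear-Gaussian in
every slope random effect, so those are integrated analytically: with
``c = exp(beta0 + b)`` per lesion,

    y | b  ~  N(X (d, g) + S c,  V),      V = sigma_e^2 I + Z D Z',

where ``S`` maps lesions to their rows and ``Z D Z'`` collects the slope
random effects.  The remaining non-Gaussian integral over ``b`` (one
dimension per lesion) is evaluated either by a Laplace approximation at
its mode (default; here identical to the Laplace approximation at the
joint mode of all random effects, because the slope-block curvature does
not depend on ``b``) or by adaptive Gauss-Hermite quadrature (oracle
backend, tensor grid, at most 3 lesions per unit).

Estimation maximises this marginal log-likelihood (ML, not REML — the
model comparisons change fixed structures) over the fixed effects and the
log-parameterised variance components with L-BFGS-B, initialised from
per-lesion ordinary least squares and moment estimates of the variance
components.  A variance component that collapses below ``exp(-10)`` is
reported as requiring no variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data_io import CohortDataset
from .piecewise import predict_matrix

__all__ = [
    "ModelSpec",
    "Theta",
    "FitResult",
    "HierarchyComparison",
    "marginal_loglik",
    "fit",
    "sp_candidates",
    "select_sp",
    "compare_hierarchies",
]

LOG2PI = float(np.log(2.0 * np.pi))

#: a fitted SD below this is reported as "no variability required"
NO_VARIABILITY_SD = float(np.exp(-10.0))

_LOG_SD_BOUNDS = (-12.0, 3.0)
_INNER_TOL = 1e-10     # inner mode-finding gradient tolerance
_OUTER_FTOL = 1e-10    # relative log-likelihood change at convergence
_MAX_OUTER_ITER = 500


# ---------------------------------------------------------------------------
# model specification and parameter vector

@dataclass(frozen=True)
class ModelSpec:
    """Hierarchy choice and random-effect layout at a fixed switch point.

    ``lesion_terms`` always contains ``bsl`` (lesions differ in baseline by
    construction); ``patient_terms`` may only contain slopes and is ignored
    under the ``lesion_only`` hierarchy.
    """

    hierarchy: str = "patient_lesion"
    sp: float = 63.0
    lesion_terms: tuple[str, ...] = ("bsl", "decay", "regrowth")
    patient_terms: tuple[str, ...] = ("decay", "regrowth")

    def __post_init__(self) -> None:
        if self.hierarchy not in ("lesion_only", "patient_lesion"):
            raise ValueError(f"unknown hierarchy {self.hierarchy!r}")
        if self.sp <= 0:
            raise ValueError("sp must be > 0")
        if "bsl" not in self.lesion_terms:
            raise ValueError("bsl must carry a lesion-level random effect")
        bad = set(self.lesion_terms) - {"bsl", "decay", "regrowth"}
        if bad:
            raise ValueError(f"unknown lesion_terms {bad}")
        bad = set(self.patient_terms) - {"decay", "regrowth"}
        if bad:
            raise ValueError(f"unknown patient_terms {bad}")

    @property
    def active_patient_terms(self) -> tuple[str, ...]:
        return self.patient_terms if self.hierarchy == "patient_lesion" else ()

    @property
    def sd_names(self) -> tuple[str, ...]:
        names = ["sd_bsl"]
        names += [f"sd_{t}_lesion" for t in ("decay", "regrowth")
                  if t in self.lesion_terms]
        names += [f"sd_{t}_patient" for t in ("decay", "regrowth")
                  if t in self.active_patient_terms]
        names.append("sd_resid")
        return tuple(names)

    @property
    def n_params(self) -> int:
        return 3 + len(self.sd_names)


@dataclass(frozen=True)
class Theta:
    """Population parameters: fixed effects plus SDs of the random terms.

    ``beta0`` is the log-scale baseline fixed effect (population baseline
    diameter ``exp(beta0)`` mm); slopes are mm/day; every SD present in the
    model must be > 0 (absent terms are ``None``).
    """

    beta0: float
    decay: float
    regrowth: float
    sd_bsl: float
    sd_resid: float
    sd_decay_lesion: float | None = None
    sd_regrowth_lesion: float | None = None
    sd_decay_patient: float | None = None
    sd_regrowth_patient: float | None = None

    def pack(self, spec: ModelSpec) -> np.ndarray:
        """Vectorise as (fixed effects, log SDs) in the spec's order."""
        sds = []
        for name in spec.sd_names:
            val = getattr(self, name)
            if val is None or val <= 0:
                raise ValueError(f"{name} must be > 0 for this model, got {val}")
            sds.append(np.log(val))
        return np.array([self.beta0, self.decay, self.regrowth] + sds)

    @classmethod
    def unpack(cls, x: np.ndarray, spec: ModelSpec) -> "Theta":
        kw = dict(beta0=float(x[0]), decay=float(x[1]), regrowth=float(x[2]))
        for name, lv in zip(spec.sd_names, x[3:]):
            kw[name] = float(np.exp(lv))
        return cls(**kw)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one maximum-likelihood fit at a fixed switch point."""

    spec: ModelSpec
    theta: Theta
    log_likelihood: float
    converged: bool
    n_obs: int
    n_lesions: int
    n_patients: int
    eb_estimates: pd.DataFrame
    fitted: pd.DataFrame
    loglik_trace: tuple[float, ...] = ()

    @property
    def sp_used(self) -> float:
        return self.spec.sp

    @property
    def n_params(self) -> int:
        return self.spec.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood

    @property
    def bsl_pop_mm(self) -> float:
        """Population baseline diameter on the mm scale (exp of beta0)."""
        return float(np.exp(self.theta.beta0))

    @property
    def no_variability(self) -> tuple[str, ...]:
        """Random-effect SDs that collapsed to (numerically) zero."""
        out = []
        for name in self.spec.sd_names:
            if name == "sd_resid":
                continue
            if getattr(self.theta, name) < NO_VARIABILITY_SD:
                out.append(name)
        return tuple(out)


# ---------------------------------------------------------------------------
# internal data layout: blocks grouped by observation pattern

@dataclass
class _Pattern:
    """Shared structure of all blocks with identical per-lesion day layouts."""

    m: int                   # lesions per block
    n: int                   # observations per block
    X: np.ndarray            # (n, 2): [min(t, sp), max(t - sp, 0)]
    Zl: np.ndarray           # (n, 2m) lesion-level slope columns (decay, regrowth)*m
    Zp: np.ndarray           # (n, 2) patient-level slope columns
    offsets: np.ndarray      # (m,) start row of each lesion, for reduceat
    Y: np.ndarray = None     # (P, n) stacked observations
    block_ids: list = None   # per block: (patient_id, [lesion ids], row index arrays)


def _build_patterns(dataset: CohortDataset, spec: ModelSpec) -> list[_Pattern]:
    df = dataset.measurements.sort_values(
        ["patient_id", "lesion_id", "day"], kind="mergesort")
    if df["day"].nunique() < 2:
        raise ValueError("fewer than 2 distinct visit days: model unidentifiable")
    group_cols = (["patient_id"] if spec.hierarchy == "patient_lesion"
                  else ["patient_id", "lesion_id"])
    patterns: dict[tuple, _Pattern] = {}
    stacks: dict[tuple, list] = {}
    for key, grp in df.groupby(group_cols, sort=True):
        lesions = [(lid, lgrp) for lid, lgrp in grp.groupby("lesion_id", sort=True)]
        days_key = tuple(tuple(lgrp["day"]) for _, lgrp in lesions)
        if days_key not in patterns:
            all_days = np.concatenate([np.asarray(lg["day"], float)
                                       for _, lg in lesions])
            X = predict_matrix(spec.sp, all_days)[:, 1:]
            m = len(lesions)
            sizes = [len(lg) for _, lg in lesions]
            offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)
            Zl = np.zeros((len(all_days), 2 * m))
            for j, (start, size) in enumerate(zip(offsets, sizes)):
                rows = slice(int(start), int(start) + size)
                Zl[rows, 2 * j] = X[rows, 0]
                Zl[rows, 2 * j + 1] = X[rows, 1]
            patterns[days_key] = _Pattern(m=m, n=len(all_days), X=X, Zl=Zl,
                                          Zp=X.copy(), offsets=offsets)
            stacks[days_key] = []
        pid = key[0] if isinstance(key, tuple) else key
        stacks[days_key].append((
            np.asarray(grp["diameter_mm"], float),
            (pid, [lid for lid, _ in lesions],
             np.asarray(grp.index)),
        ))
    out = []
    for days_key, pat in patterns.items():
        ys, ids = zip(*stacks[days_key])
        pat.Y = np.vstack(ys)
        pat.block_ids = list(ids)
        out.append(pat)
    return out


def _pattern_cov(pat: _Pattern, spec: ModelSpec, th: Theta):
    """V = sigma_e^2 I + Z D Z' for one pattern, with its Cholesky pieces."""
    V = (th.sd_resid ** 2) * np.eye(pat.n)
    var_l = np.array([
        (th.sd_decay_lesion or 0.0) ** 2 if "decay" in spec.lesion_terms else 0.0,
        (th.sd_regrowth_lesion or 0.0) ** 2 if "regrowth" in spec.lesion_terms else 0.0,
    ])
    V += (pat.Zl * np.tile(var_l, pat.m)) @ pat.Zl.T
    if spec.active_patient_terms:
        var_p = np.array([
            (th.sd_decay_patient or 0.0) ** 2
            if "decay" in spec.active_patient_terms else 0.0,
            (th.sd_regrowth_patient or 0.0) ** 2
            if "regrowth" in spec.active_patient_terms else 0.0,
        ])
        V += (pat.Zp * var_p) @ pat.Zp.T
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return V, None, np.nan
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return V, cf, logdet


def _lesion_sums(W: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Row-group sums S' w for a stack of vectors W (P, n) -> (P, m)."""
    return np.add.reduceat(W, offsets, axis=1)


def _mode_newton(q0, h, A, beta0, sd_bsl, max_iter=60):
    """Batched Newton ascent for the baseline-effect posterior mode.

    Maximises, per block,
        F(b) = -(q0 - 2 c.h + c'Ac)/2 - |b|^2 / (2 sd_bsl^2),
    with c = exp(beta0 + b).  Stops on the Newton decrement (scale-aware,
    so the Laplace value — quadratic in the mode error — is accurate to
    roughly machine precision); blocks whose line search stalls are frozen.
    Returns the mode, F at the mode and the negative Hessian there.
    """
    P, m = h.shape
    prec = 1.0 / (sd_bsl * sd_bsl)
    diag = np.arange(m)

    def value(b):
        with np.errstate(over="ignore", invalid="ignore"):
            c = np.exp(np.clip(beta0 + b, -700.0, 700.0))
            quad = q0 - 2.0 * np.sum(c * h, axis=1) + np.einsum(
                "pi,ij,pj->p", c, A, c)
            out = -0.5 * quad - 0.5 * prec * np.sum(b * b, axis=1)
        return np.where(np.isnan(out), -np.inf, out)

    b = np.zeros((P, m))
    f = value(b)
    frozen = np.zeros(P, dtype=bool)
    for _ in range(max_iter):
        c = np.exp(beta0 + b)
        u = h - c @ A
        grad = c * u - prec * b
        negH = (c[:, :, None] * c[:, None, :]) * A[None, :, :]
        negH[:, diag, diag] += prec - c * u
        try:
            step = np.linalg.solve(negH, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = grad / (np.abs(negH[:, diag, diag]) + prec)
        # fall back to a scaled gradient step where Newton is not an ascent
        decr = np.sum(step * grad, axis=1)
        bad = decr <= 0
        if bad.any():
            step[bad] = grad[bad] / prec
            decr[bad] = np.sum(step[bad] * grad[bad], axis=1)
        done = frozen | (decr < _INNER_TOL * (1.0 + np.abs(f)))
        if done.all():
            break
        alpha = np.where(done, 0.0, 1.0)
        fn = f
        for _ in range(30):
            bn = b + alpha[:, None] * step
            fn = value(bn)
            worse = ~done & (fn < f - 1e-13)
            if not worse.any():
                break
            alpha[worse] *= 0.5
            stalled = worse & (alpha < 1e-8)
            if stalled.any():
                frozen |= stalled
                done |= stalled
                alpha[stalled] = 0.0
        accept = ~done & (fn >= f - 1e-13)
        b = np.where(accept[:, None], bn, b)
        f = np.where(accept, fn, f)
    c = np.exp(beta0 + b)
    u = h - c @ A
    negH = (c[:, :, None] * c[:, None, :]) * A[None, :, :]
    negH[:, diag, diag] += prec - c * u
    return b, value(b), negH


def _pattern_loglik(pat: _Pattern, spec: ModelSpec, th: Theta, *,
                    method: str = "laplace", gh_points: int = 21,
                    want_mode: bool = False):
    """Marginal log-likelihood contributions of one pattern's blocks."""
    _, cf, logdet = _pattern_cov(pat, spec, th)
    if cf is None:
        # numerically singular covariance (flagged, not raised)
        P = pat.Y.shape[0]
        nanv = np.full(P, np.nan)
        return (nanv, np.zeros((P, pat.m)), None, None) if want_mode \
            else (nanv, None, None, None)
    beta_s = np.array([th.decay, th.regrowth])
    Yt = pat.Y - pat.X @ beta_s                      # (P, n)
    W = cho_solve(cf, Yt.T).T                        # V^{-1} ytilde
    q0 = np.sum(Yt * W, axis=1)                      # (P,)
    h = _lesion_sums(W, pat.offsets)                 # (P, m)
    ViS = cho_solve(cf, _indicator(pat))             # (n, m): V^{-1} S
    # A = S' V^{-1} S, symmetric (m, m)
    A = np.add.reduceat(ViS, pat.offsets, axis=0)
    A = 0.5 * (A + A.T)

    m, n, P = pat.m, pat.n, pat.Y.shape[0]
    const = (-0.5 * logdet - 0.5 * n * LOG2PI
             - 0.5 * m * (LOG2PI + 2.0 * np.log(th.sd_bsl)))

    b_hat, f_hat, negH = _mode_newton(q0, h, A, th.beta0, th.sd_bsl)
    sign, corr_logdet = np.linalg.slogdet(negH)
    if np.any(sign <= 0):
        return np.full(P, np.nan), b_hat, cf, Yt
    laplace = f_hat + const + 0.5 * m * LOG2PI - 0.5 * corr_logdet

    if method == "laplace":
        ll = laplace
    elif method == "gh":
        if m > 3:
            raise ValueError(
                "Gauss-Hermite backend supports at most 3 lesions per unit")
        nodes, weights = hermgauss(gh_points)
        grids = np.meshgrid(*([nodes] * m), indexing="ij")
        Zg = np.stack([g.ravel() for g in grids], axis=1)       # (K, m)
        logw = np.sum(np.log(weights)[
            np.stack([np.meshgrid(*([np.arange(gh_points)] * m),
                                  indexing="ij")[d].ravel()
                      for d in range(m)], axis=1)], axis=1)     # (K,)
        prec_chol = np.linalg.cholesky(negH)                    # (P, m, m)
        # scale: Sigma = negH^{-1}; b = b_hat + sqrt(2) L z with L L' = Sigma
        L = np.linalg.inv(prec_chol).transpose(0, 2, 1)         # (P, m, m)
        _, logdetL = np.linalg.slogdet(L)
        B = b_hat[:, None, :] + np.sqrt(2.0) * np.einsum(
            "pij,kj->pki", L, Zg)                               # (P, K, m)
        C = np.exp(th.beta0 + B)
        quad = (q0[:, None] - 2.0 * np.sum(C * h[:, None, :], axis=2)
                + np.einsum("pki,ij,pkj->pk", C, A, C))
        prior = np.sum(B * B, axis=2) / (th.sd_bsl ** 2)
        F = -0.5 * quad - 0.5 * prior
        znorm = np.sum(Zg * Zg, axis=1)
        ll = (const + 0.5 * m * np.log(2.0) + logdetL
              + logsumexp(F + znorm[None, :] + logw[None, :], axis=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    if want_mode:
        return ll, b_hat, cf, Yt
    return ll, None, None, None


def _indicator(pat: _Pattern) -> np.ndarray:
    S = np.zeros((pat.n, pat.m))
    ends = np.append(pat.offsets[1:], pat.n)
    for j, (s, e) in enumerate(zip(pat.offsets, ends)):
        S[int(s):int(e), j] = 1.0
    return S


# ---------------------------------------------------------------------------
# public likelihood / fitting API

def marginal_loglik(dataset: CohortDataset, spec: ModelSpec, theta: Theta, *,
                    method: str = "laplace", gh_points: int = 21) -> float:
    """Marginal log-likelihood of all observations under ``theta``.

    Random effects are integrated out: slope effects exactly, baseline
    effects by Laplace approximation (default) or adaptive Gauss-Hermite
    quadrature (``method="gh"``, tensor grid, at most 3 lesions per unit).
    Returns NaN if the inner mode-finding fails.
    """
    for name in spec.sd_names:
        val = getattr(theta, name)
        if val is None or val <= 0:
            raise ValueError(f"{name} must be > 0, got {val}")
    patterns = _build_patterns(dataset, spec)
    total = 0.0
    for pat in patterns:
        ll, *_ = _pattern_loglik(pat, spec, theta, method=method,
                                 gh_points=gh_points)
        if not np.all(np.isfinite(ll)):
            return float("nan")
        total += float(np.sum(ll))
    return total


def _initial_theta(dataset: CohortDataset, spec: ModelSpec,
                   _diagnostics: dict | None = None) -> Theta:
    """Per-lesion OLS on the piecewise design + moment variance estimates."""
    df = dataset.measurements
    rows = []
    pooled = predict_matrix(spec.sp, np.asarray(df["day"], float))
    pooled_beta, *_ = np.linalg.lstsq(pooled, np.asarray(df["diameter_mm"], float),
                                      rcond=None)
    resid_sq = []
    for (pid, lid), grp in df.groupby(["patient_id", "lesion_id"], sort=True):
        t = np.asarray(grp["day"], float)
        y = np.asarray(grp["diameter_mm"], float)
        Xd = predict_matrix(spec.sp, t)
        if np.linalg.matrix_rank(Xd) == 3:
            beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        else:
            beta = pooled_beta.copy()
            if len(y):
                beta[0] = max(float(y[0] - Xd[0, 1:] @ beta[1:]), 0.5)
        resid_sq.extend((y - Xd @ beta) ** 2)
        rows.append((pid, max(float(beta[0]), 0.5), float(beta[1]), float(beta[2])))
    ols = pd.DataFrame(rows, columns=["patient_id", "bsl", "decay", "regrowth"])

    floor = 1e-3
    beta0 = float(np.mean(np.log(ols["bsl"])))
    sd_bsl = max(float(np.std(np.log(ols["bsl"]))), floor)
    kw = dict(beta0=beta0,
              decay=float(np.mean(ols["decay"])),
              regrowth=float(np.mean(ols["regrowth"])),
              sd_bsl=sd_bsl,
              sd_resid=max(float(np.sqrt(np.mean(resid_sq))), floor))
    for term in ("decay", "regrowth"):
        pat_means = ols.groupby("patient_id")[term].transform("mean")
        within = float(np.std(ols[term] - pat_means))
        between = float(np.std(ols.groupby("patient_id")[term].mean()))
        if spec.hierarchy == "patient_lesion" and term in spec.active_patient_terms:
            if term in spec.lesion_terms:
                kw[f"sd_{term}_lesion"] = max(within, floor)
            kw[f"sd_{term}_patient"] = max(between, floor)
        elif term in spec.lesion_terms:
            total = float(np.std(ols[term]))
            kw[f"sd_{term}_lesion"] = max(total, floor)
    if _diagnostics is not None:
        scale = float(np.max(np.abs(dataset.measurements["diameter_mm"]))) or 1.0
        _diagnostics["exact_fit"] = (
            float(np.sqrt(np.mean(resid_sq))) < 1e-8 * scale
            and float(np.std(np.log(ols["bsl"]))) < 1e-8
            and float(ols["decay"].std()) < 1e-8
            and float(ols["regrowth"].std()) < 1e-8)
    return Theta(**kw)


def _eb_tables(patterns, spec: ModelSpec, th: Theta, measurements: pd.DataFrame):
    """Empirical-Bayes per-lesion parameters and per-observation fitted values."""
    eb_rows = []
    fit_idx_all = []
    for pat in patterns:
        ll, b_hat, cf, Yt = _pattern_loglik(pat, spec, th, want_mode=True)
        C = np.exp(th.beta0 + b_hat)                 # (P, m)
        S = _indicator(pat)
        R = Yt - C @ S.T                             # (P, n) residual at mode
        Wr = cho_solve(cf, R.T).T                    # V^{-1} r
        # BLUPs: u = D Z' V^{-1} r
        var_l = np.array([
            (th.sd_decay_lesion or 0.0) ** 2 if "decay" in spec.lesion_terms else 0.0,
            (th.sd_regrowth_lesion or 0.0) ** 2
            if "regrowth" in spec.lesion_terms else 0.0,
        ])
        Ul = (Wr @ pat.Zl) * np.tile(var_l, pat.m)   # (P, 2m)
        if spec.active_patient_terms:
            var_p = np.array([
                (th.sd_decay_patient or 0.0) ** 2
                if "decay" in spec.active_patient_terms else 0.0,
                (th.sd_regrowth_patient or 0.0) ** 2
                if "regrowth" in spec.active_patient_terms else 0.0,
            ])
            Up = (Wr @ pat.Zp) * var_p               # (P, 2)
        else:
            Up = np.zeros((pat.Y.shape[0], 2))
        mu = (pat.X @ np.array([th.decay, th.regrowth]))[None, :] \
            + C @ S.T + Ul @ pat.Zl.T + Up @ pat.Zp.T
        for p, (pid, lids, idx) in enumerate(pat.block_ids):
            for j, lid in enumerate(lids):
                eb_rows.append((
                    pid, lid,
                    float(C[p, j]),
                    th.decay + float(Up[p, 0]) + float(Ul[p, 2 * j]),
                    th.regrowth + float(Up[p, 1]) + float(Ul[p, 2 * j + 1]),
                ))
            fit_idx_all.append((idx, mu[p]))
    eb = pd.DataFrame(eb_rows, columns=[
        "patient_id", "lesion_id", "bsl", "decay", "regrowth"])
    eb["sp"] = spec.sp
    fitted = measurements.copy()
    pos = {ix: k for k, ix in enumerate(measurements.index)}
    vals = np.full(len(measurements), np.nan)
    for idx, muvals in fit_idx_all:
        # idx follows the (patient, lesion, day) sort; map back to input rows
        for i, v in zip(idx, muvals):
            vals[pos[i]] = v
    fitted["fitted_mm"] = vals
    return eb.sort_values(["patient_id", "lesion_id"]).reset_index(drop=True), fitted


def fit(dataset: CohortDataset, spec: ModelSpec,
        init: Theta | None = None) -> FitResult:
    """Maximise the marginal log-likelihood; deterministic given ``init``.

    Variance components are optimised on the log scale (positivity by
    construction); the default initialisation is per-lesion OLS plus moment
    estimates.  Returns ``converged=False`` rather than raising when the
    outer optimiser fails.
    """
    patterns = _build_patterns(dataset, spec)
    diag: dict = {}
    th0 = init if init is not None else _initial_theta(dataset, spec, diag)
    if init is None and diag.get("exact_fit"):
        # the data are reproduced exactly by one common piecewise line: the
        # likelihood increases monotonically as every SD shrinks, so the ML
        # optimum sits on the variance lower bound with the OLS fixed effects
        lb_sd = float(np.exp(_LOG_SD_BOUNDS[0]))
        th_star = Theta(**{
            **{k: getattr(th0, k) for k in ("beta0", "decay", "regrowth")},
            **{name: lb_sd for name in spec.sd_names}})
        ll = sum(float(np.sum(_pattern_loglik(pat, spec, th_star)[0]))
                 for pat in patterns)
        eb, fitted = _eb_tables(patterns, spec, th_star, dataset.measurements)
        return FitResult(
            spec=spec, theta=th_star, log_likelihood=ll, converged=True,
            n_obs=len(dataset.measurements), n_lesions=dataset.n_lesions,
            n_patients=dataset.n_patients, eb_estimates=eb, fitted=fitted,
            loglik_trace=(ll,))
    x0 = th0.pack(spec)
    lb, ub = _LOG_SD_BOUNDS
    bounds = [(None, None)] * 3 + [(lb, ub)] * (len(x0) - 3)
    x0[3:] = np.clip(x0[3:], lb, ub)

    cache: dict[bytes, float] = {}

    def nll(x):
        th = Theta.unpack(x, spec)
        total = 0.0
        for pat in patterns:
            ll, *_ = _pattern_loglik(pat, spec, th)
            if not np.all(np.isfinite(ll)):
                return 1e12
            total += float(np.sum(ll))
        if len(cache) > 64:
            cache.clear()
        cache[x.tobytes()] = -total
        return -total

    trace: list[float] = []

    def record(xk):
        key = np.asarray(xk).tobytes()
        f = cache[key] if key in cache else nll(np.asarray(xk))
        trace.append(-f)

    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   callback=record,
                   options={"maxiter": _MAX_OUTER_ITER, "ftol": _OUTER_FTOL})
    theta = Theta.unpack(res.x, spec)
    ll = -float(res.fun)
    eb, fitted = _eb_tables(patterns, spec, theta, dataset.measurements)
    return FitResult(
        spec=spec, theta=theta, log_likelihood=ll,
        converged=bool(res.success) and np.isfinite(ll),
        n_obs=len(dataset.measurements),
        n_lesions=dataset.n_lesions,
        n_patients=dataset.n_patients,
        eb_estimates=eb, fitted=fitted,
        loglik_trace=tuple(trace),
    )


# ---------------------------------------------------------------------------
# switch-point grid and model comparison

def sp_candidates(visit_days: Sequence[int]) -> tuple[int, ...]:
    """Candidate switch points: midpoints of consecutive on-treatment days.

    Midpoints are rounded half-up to whole days; at least two on-treatment
    (day > 0) visits are required.  E.g. the schedule (0, 42, 84, 147, 210)
    yields (63, 116, 179).
    """
    on = sorted(int(d) for d in visit_days if d > 0)
    if len(on) < 2:
        raise ValueError("need at least 2 on-treatment visit days")
    return tuple(int(np.floor((a + b) / 2.0 + 0.5)) for a, b in zip(on, on[1:]))


def select_sp(dataset: CohortDataset, spec_template: ModelSpec,
              candidates: Sequence[int] | None = None,
              ) -> tuple[int, pd.DataFrame, dict[int, FitResult]]:
    """Profile the log-likelihood over a switch-point grid.

    Fits the model once per candidate (warm-starting each fit from the
    previous candidate's solution), and returns the candidate with the
    highest log-likelihood — ties broken toward the earliest switch point —
    together with the per-candidate table (sp, log-likelihood, AIC,
    convergence) and the individual fits.
    """
    if candidates is None:
        candidates = sp_candidates(dataset.visit_days)
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no switch-point candidates supplied")
    fits: dict[int, FitResult] = {}
    prev: Theta | None = None
    rows = []
    for sp in candidates:
        spec = replace(spec_template, sp=float(sp))
        fr = fit(dataset, spec, init=prev)
        if not fr.converged:
            # retry from scratch before discarding the candidate
            fr = fit(dataset, spec)
        if fr.converged:
            fits[sp] = fr
            prev = fr.theta
        else:
            warnings.warn(f"switch-point candidate {sp} failed to converge; excluded")
        rows.append((sp, fr.log_likelihood, fr.aic, fr.converged))
    table = pd.DataFrame(rows, columns=["sp", "log_likelihood", "aic", "converged"])
    if not fits:
        raise RuntimeError("all switch-point candidate fits failed to converge")
    best = None
    for sp in sorted(fits):
        if best is None or fits[sp].log_likelihood > fits[best].log_likelihood:
            best = sp
    return best, table, fits


@dataclass(frozen=True)
class HierarchyComparison:
    """Log-likelihood comparison of the two hierarchies at a common sp."""

    fit_lesion_only: FitResult
    fit_patient_lesion: FitResult

    @property
    def loglik_difference(self) -> float:
        return (self.fit_patient_lesion.log_likelihood
                - self.fit_lesion_only.log_likelihood)

    @property
    def selected(self) -> str:
        """Model with the higher log-likelihood (AIC is reported, not used)."""
        return ("patient_lesion" if self.loglik_difference > 0 else "lesion_only")

    def as_record(self) -> dict:
        return {
            "sp": self.fit_patient_lesion.sp_used,
            "loglik_lesion_only": self.fit_lesion_only.log_likelihood,
            "loglik_patient_lesion": self.fit_patient_lesion.log_likelihood,
            "loglik_difference": self.loglik_difference,
            "n_params_lesion_only": self.fit_lesion_only.n_params,
            "n_params_patient_lesion": self.fit_patient_lesion.n_params,
            "aic_lesion_only": self.fit_lesion_only.aic,
            "aic_patient_lesion": self.fit_patient_lesion.aic,
            "selected": self.selected,
        }


def compare_hierarchies(dataset: CohortDataset, sp: float) -> HierarchyComparison:
    """Fit both hierarchies at ``sp`` and compare their log-likelihoods.

    The patient-nested model contains the lesion-independent one (set the
    patient-level SDs to zero), so its maximised log-likelihood can only be
    higher up to optimiser tolerance; to respect that nesting numerically
    the patient-nested fit is restarted from the lesion-independent optimum
    whenever its first attempt lands below it.
    """
    counts = dataset.measurements.groupby("patient_id")["lesion_id"].nunique()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 patients with >= 2 lesions to compare hierarchies")
    fr_lo = fit(dataset, ModelSpec(hierarchy="lesion_only", sp=sp))
    fr_pl = fit(dataset, ModelSpec(hierarchy="patient_lesion", sp=sp))
    if fr_pl.log_likelihood < fr_lo.log_likelihood:
        seed_init = replace(fr_lo.theta, sd_decay_patient=1e-4,
                            sd_regrowth_patient=1e-4)
        fr_retry = fit(dataset, ModelSpec(hierarchy="patient_lesion", sp=sp),
                       init=seed_init)
        if fr_retry.log_likelihood > fr_pl.log_likelihood:
            fr_pl = fr_retry
    return HierarchyComparison(fit_lesion_only=fr_lo, fit_patient_lesion=fr_pl)
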
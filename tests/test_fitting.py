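import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from lesionkinetics.data_io import CohortDataset
from lesionkinetics.fitting import (
    ModelSpec,
    Theta,
    compare_hierarchies,
    fit,
    marginal_loglik,
    select_sp,
    sp_candidates,
)
from lesionkinetics.piecewise import predict_matrix
from lesionkinetics.synthetic import SyntheticConfig, generate


def _cohort(rows, visit_days):
    df = pd.DataFrame(rows, columns=["patient_id", "lesion_id", "day", "diameter_mm"])
    return CohortDataset(df, visit_days)


TWO_LESION_ROWS = [
    ("P1", "L1", 0, 30.0), ("P1", "L1", 42, 22.0),
    ("P1", "L1", 84, 18.0), ("P1", "L1", 147, 21.0),
    ("P1", "L2", 0, 15.0), ("P1", "L2", 42, 11.0),
    ("P1", "L2", 84, 9.0), ("P1", "L2", 147, 12.0),
]


def _full_theta(sd_bsl=0.2, **kw):
    base = dict(beta0=float(np.log(20.0)), decay=-0.15, regrowth=0.04,
                sd_bsl=sd_bsl, sd_resid=1.5, sd_decay_lesion=0.04,
                sd_regrowth_lesion=0.01, sd_decay_patient=0.04,
                sd_regrowth_patient=0.01)
    base.update(kw)
    return Theta(**base)


class TestSpCandidates:
    @pytest.mark.parametrize("days, expected", [
        ((0, 42, 84, 147, 210), (63, 116, 179)),
        ((0, 10, 20), (15,)),
        ((0, 42, 84), (63,)),
    ])
    def test_midpoints_rounded_half_up(self, days, expected):
        assert sp_candidates(days) == expected

    def test_requires_two_on_treatment_visits(self):
        with pytest.raises(ValueError):
            sp_candidates((0, 42))


class TestMarginalLoglik:
    def test_degenerate_limit_is_ols_gaussian_loglik(self):
        """As every random-effect SD shrinks to zero, the marginal likelihood
        collapses to the fixed-effect Gaussian likelihood in closed form."""
        ds = _cohort(TWO_LESION_ROWS, (0, 42, 84, 147, 210))
        spec = ModelSpec(hierarchy="patient_lesion", sp=63.0)
        eps = 1e-9
        th = _full_theta(sd_bsl=eps, sd_decay_lesion=eps, sd_regrowth_lesion=eps,
                         sd_decay_patient=eps, sd_regrowth_patient=eps)
        t = np.asarray(
            ds.measurements.sort_values(["lesion_id", "day"])["day"], float)
        y = np.asarray(
            ds.measurements.sort_values(["lesion_id", "day"])["diameter_mm"], float)
        mu = predict_matrix(63.0, t) @ [np.exp(th.beta0), th.decay, th.regrowth]
        closed = (-0.5 * np.sum(((y - mu) / th.sd_resid) ** 2)
                  - len(y) * np.log(th.sd_resid)
                  - 0.5 * len(y) * np.log(2 * np.pi))
        assert marginal_loglik(ds, spec, th) == pytest.approx(closed, abs=1e-8)

    def test_matches_dense_mvn_when_baseline_variance_negligible(self):
        """With a (numerically) degenerate baseline effect the model is a
        linear mixed model; the likelihood must equal the density of the
        explicitly assembled multivariate normal."""
        ds = _cohort(TWO_LESION_ROWS, (0, 42, 84, 147, 210))
        spec = ModelSpec(hierarchy="patient_lesion", sp=63.0)
        th = _full_theta(sd_bsl=1e-7)
        t = np.array([0, 42, 84, 147, 0, 42, 84, 147], float)
        X = predict_matrix(63.0, t)[:, 1:]
        mean = 20.0 + X @ [th.decay, th.regrowth]
        mask1 = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)[:, None]
        V = th.sd_resid ** 2 * np.eye(8)
        for Z in (X * mask1, X * (1 - mask1), X):
            V += (Z * [0.04 ** 2, 0.01 ** 2]) @ Z.T
        y = np.array([r[3] for r in TWO_LESION_ROWS], float)
        expected = multivariate_normal.logpdf(y, mean, V)
        assert marginal_loglik(ds, spec, th) == pytest.approx(expected, abs=1e-6)

    def test_laplace_close_to_quadrature_on_small_unit(self):
        ds = _cohort(TWO_LESION_ROWS, (0, 42, 84, 147, 210))
        spec = ModelSpec(hierarchy="patient_lesion", sp=63.0)
        th = _full_theta(sd_bsl=0.05)
        la = marginal_loglik(ds, spec, th)
        gh = marginal_loglik(ds, spec, th, method="gh", gh_points=31)
        assert la == pytest.approx(gh, abs=1e-3)

    def test_single_lesion_baseline_only_agrees_with_61_point_quadrature(self):
        ds = _cohort([("P1", "L1", 0, 20.0), ("P1", "L1", 42, 14.0)], (0, 42))
        spec = ModelSpec(hierarchy="lesion_only", sp=21.0,
                         lesion_terms=("bsl",), patient_terms=())
        th = Theta(beta0=float(np.log(20.0)), decay=-0.15, regrowth=0.04,
                   sd_bsl=0.02, sd_resid=1.0)
        la = marginal_loglik(ds, spec, th)
        gh = marginal_loglik(ds, spec, th, method="gh", gh_points=61)
        assert la == pytest.approx(gh, abs=1e-4)

    def test_factorises_over_patients(self):
        ds = _cohort(TWO_LESION_ROWS, (0, 42, 84, 147, 210))
        dup = _cohort(TWO_LESION_ROWS
                      + [("P2", l, d, v) for _, l, d, v in TWO_LESION_ROWS],
                      (0, 42, 84, 147, 210))
        spec = ModelSpec(hierarchy="patient_lesion", sp=63.0)
        th = _full_theta()
        assert marginal_loglik(dup, spec, th) == pytest.approx(
            2.0 * marginal_loglik(ds, spec, th), rel=1e-10)

    def test_nonpositive_sd_is_domain_error(self):
        ds = _cohort(TWO_LESION_ROWS, (0, 42, 84, 147, 210))
        spec = ModelSpec(hierarchy="patient_lesion", sp=63.0)
        with pytest.raises(ValueError, match="sd_resid"):
            marginal_loglik(ds, spec, _full_theta(sd_resid=0.0))
        with pytest.raises(ValueError, match="sd_decay_patient"):
            marginal_loglik(ds, spec, _full_theta(sd_decay_patient=None))

    def test_quadrature_refuses_large_units(self):
        rows = [(f"P1", f"L{j}", d, 20.0 - 0.1 * d) for j in range(4)
                for d in (0, 42, 84)]
        ds = _cohort(rows, (0, 42, 84))
        spec = ModelSpec(hierarchy="patient_lesion", sp=63.0)
        with pytest.raises(ValueError, match="at most 3"):
            marginal_loglik(ds, spec, _full_theta(), method="gh")


class TestFit:
    def test_noiseless_zero_variance_recovers_truth(self, noiseless_cohort):
        ds, truth = noiseless_cohort
        cfg = truth.config
        fr = fit(ds, ModelSpec(hierarchy="patient_lesion", sp=cfg.sp_true))
        assert fr.converged
        assert fr.theta.beta0 == pytest.approx(cfg.bsl_log_mean, rel=1e-6)
        assert fr.theta.decay == pytest.approx(cfg.decay_mean, rel=1e-6)
        assert fr.theta.regrowth == pytest.approx(cfg.regrowth_mean, rel=1e-6)

    def test_eb_table_has_one_row_per_lesion(self, default_cohort):
        ds, _ = default_cohort
        small = ds.with_measurements(
            ds.measurements[ds.measurements["patient_id"] < "P0040"])
        fr = fit(small, ModelSpec(hierarchy="patient_lesion", sp=63.0))
        lesions = small.measurements.drop_duplicates(["patient_id", "lesion_id"])
        assert len(fr.eb_estimates) == len(lesions)
        assert fr.fitted["fitted_mm"].notna().all()

    def test_loglik_trace_is_monotone_nondecreasing(self, default_cohort):
        ds, _ = default_cohort
        small = ds.with_measurements(
            ds.measurements[ds.measurements["patient_id"] < "P0040"])
        fr = fit(small, ModelSpec(hierarchy="lesion_only", sp=63.0))
        trace = np.array(fr.loglik_trace)
        assert len(trace) > 1
        assert np.all(np.diff(trace) > -1e-6)

    def test_too_few_distinct_days_is_unidentifiable(self):
        ds = _cohort([("P1", "L1", 0, 20.0), ("P2", "L1", 0, 25.0)], (0,))
        with pytest.raises(ValueError, match="distinct visit days"):
            fit(ds, ModelSpec(hierarchy="lesion_only", sp=63.0))

    def test_shift_equivariance_of_baseline_at_zero_baseline_variance(self):
        """With no baseline heterogeneity the model is linear: adding a
        constant to every diameter moves the mm-scale baseline by that
        constant and leaves the slope estimates unchanged."""
        cfg = SyntheticConfig(n_patients=60, seed=13, bsl_log_sd=0.0,
                              residual_sd=0.8, dropout_at_pd=False)
        ds, _ = generate(cfg)
        spec = ModelSpec(hierarchy="patient_lesion", sp=63.0)
        fr = fit(ds, spec)
        shift = 25.0
        shifted = ds.measurements.assign(
            diameter_mm=ds.measurements["diameter_mm"] + shift)
        fr2 = fit(ds.with_measurements(shifted), spec)
        assert fr2.bsl_pop_mm == pytest.approx(fr.bsl_pop_mm + shift, rel=5e-3)
        assert fr2.theta.decay == pytest.approx(fr.theta.decay, rel=1e-2)
        assert fr2.theta.regrowth == pytest.approx(fr.theta.regrowth, rel=2e-2)


class TestSelectionAndComparison:
    def test_single_candidate_returned_unchanged(self, noiseless_cohort):
        ds, _ = noiseless_cohort
        best, table, fits = select_sp(
            ds, ModelSpec(hierarchy="patient_lesion", sp=63.0), [63])
        assert best == 63
        assert list(table["sp"]) == [63]
        assert 63 in fits

    def test_true_switch_point_wins_on_one_arm(self, default_cohort):
        ds, truth = default_cohort
        best, table, _ = select_sp(
            ds, ModelSpec(hierarchy="patient_lesion", sp=63.0), [63, 116, 179])
        assert best == truth.config.sp_true == 63
        lls = table.set_index("sp")["log_likelihood"]
        assert lls[63] > lls[116] > lls[179]

    def test_patient_hierarchy_wins_when_patients_differ(self, default_cohort):
        ds, _ = default_cohort
        small = ds.with_measurements(
            ds.measurements[ds.measurements["patient_id"] < "P0100"])
        cmp = compare_hierarchies(small, 63.0)
        # nested models: the richer hierarchy can only fit better
        assert cmp.loglik_difference > -1e-4
        assert cmp.selected == "patient_lesion"
        assert cmp.fit_patient_lesion.n_params == 9
        assert cmp.fit_lesion_only.n_params == 7

    def test_comparison_needs_multilesion_patients(self):
        rows = [("P1", "L1", d, 20.0 - 0.1 * d) for d in (0, 42, 84)]
        rows += [("P2", "L1", d, 25.0 - 0.1 * d) for d in (0, 42, 84)]
        ds = _cohort(rows, (0, 42, 84))
        with pytest.raises(ValueError, match="2 lesions"):
            compare_hierarchies(ds, 63.0)
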
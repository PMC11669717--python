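import numpy as np
import pytest

from dosimix.competing_risk import (
    FineGrayFitter,
    brier_curve,
    concordance_index,
    fit_fine_gray,
    integrated_brier,
)


def _simulate_fine_gray(n, beta, p_base=0.55, seed=0):
    """Draw from the classical subdistribution generative model.

    Cause-1 CIF: F1(t|x) = 1 - (1 - p*(1 - exp(-t)))^exp(beta*x); with
    probability 1 - F1(inf|x) the subject gets the competing event (unit
    exponential time).  Inverse-transform sampling on the conditional CIF.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eta = np.exp(beta * x)
    p1 = 1.0 - (1.0 - p_base) ** eta  # P(cause 1 | x)
    cause1 = rng.random(n) < p1
    t = np.empty(n)
    u = rng.random(n)
    # cause 1: solve 1 - (1 - p(1-e^{-t}))^eta = u * p1 for t
    inner = 1.0 - (1.0 - u[cause1] * p1[cause1]) ** (1.0 / eta[cause1])
    t[cause1] = -np.log(1.0 - inner / p_base)
    t[~cause1] = rng.exponential(1.0, size=(~cause1).sum())
    event = np.where(cause1, 1, 2)
    return x.reshape(-1, 1), t, event


class TestFit:
    def test_reduces_to_cox_without_competing_events_or_censoring(self):
        from lifelines import CoxPHFitter
        import pandas as pd

        rng = np.random.default_rng(1)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x))
        fit = fit_fine_gray(x.reshape(-1, 1), t, np.ones(n, dtype=int),
                            standardize=False)
        df = pd.DataFrame({"t": t, "e": 1, "x": x})
        cox = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.coef_[0] == pytest.approx(cox.params_["x"], abs=1e-4)

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(2)
        n = 400
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1.0, size=n)
        event = rng.choice([0, 1, 2], size=n, p=[0.3, 0.4, 0.3])
        fit = fit_fine_gray(x, t, event)
        assert abs(fit.coef_[0]) < 2 * fit.se_[0]

    def test_recovers_planted_beta_within_3_se(self):
        X, t, event = _simulate_fine_gray(500, beta=0.7, seed=3)
        fit = fit_fine_gray(X, t, event, standardize=False)
        assert abs(fit.coef_[0] - 0.7) < 3 * fit.se_[0]
        assert fit.converged_

    def test_requires_failure_events(self):
        with pytest.raises(ValueError):
            fit_fine_gray(np.zeros((5, 1)), np.arange(5.0) + 1,
                          np.full(5, 2))

    def test_baseline_hazard_nondecreasing(self):
        X, t, event = _simulate_fine_gray(200, beta=0.5, seed=4)
        fit = fit_fine_gray(X, t, event)
        assert np.all(np.diff(fit.baseline_cumhaz_) >= 0)


@pytest.fixture(scope="module")
def fitted():
    X, t, event = _simulate_fine_gray(300, beta=0.7, seed=5)
    return fit_fine_gray(X, t, event), X, t, event


class TestCumulativeIncidence:

    def test_zero_at_time_zero(self, fitted):
        fit, X, _, _ = fitted
        cif = fit.predict_cumulative_incidence(X[:5], [0.0])
        np.testing.assert_array_equal(cif, 0.0)

    def test_monotone_in_time(self, fitted):
        fit, X, t, _ = fitted
        times = np.linspace(0, t.max(), 25)
        cif = fit.predict_cumulative_incidence(X[:10], times)
        assert np.all(np.diff(cif, axis=1) >= 0)
        assert np.all((cif >= 0) & (cif <= 1))

    def test_risk_ordering_preserved_at_all_times(self, fitted):
        fit, X, t, _ = fitted
        lo = np.array([[-2.0]])
        hi = np.array([[2.0]])
        times = np.linspace(0.1, t.max(), 20)
        cif_lo = fit.predict_cumulative_incidence(lo, times)[0]
        cif_hi = fit.predict_cumulative_incidence(hi, times)[0]
        sign = np.sign(fit.coef_[0])
        diff = (cif_hi - cif_lo) * sign
        assert np.all(diff >= -1e-12)

    def test_constant_beyond_last_event(self, fitted):
        fit, X, t, _ = fitted
        far = fit.predict_cumulative_incidence(X[:3], [t.max() * 5])
        last = fit.predict_cumulative_incidence(X[:3], [t.max()])
        np.testing.assert_allclose(far, last)


def _brute_force_cindex(risk, time, event):
    usable = conc = 0.0
    n = len(risk)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if time[j] > time[i] or (event[j] == 2 and time[j] <= time[i]):
                usable += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    return conc / usable


class TestConcordance:
    def test_perfect_ordering(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        assert concordance_index(-t, t, event) == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        n = 600
        t = rng.exponential(1, n)
        event = rng.choice([0, 1, 2], n, p=[0.2, 0.5, 0.3])
        c = concordance_index(rng.normal(size=n), t, event)
        assert abs(c - 0.5) < 0.05

    def test_five_case_hand_example(self):
        risk = np.array([2.0, 1.0, 3.0, 0.5, 1.5])
        time = np.array([1.0, 3.0, 2.0, 4.0, 2.5])
        event = np.array([1, 0, 1, 2, 0])
        assert concordance_index(risk, time, event) == pytest.approx(
            _brute_force_cindex(risk, time, event)
        )

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(np.array([1.0]), np.array([2.0]), np.array([1]))


class TestBrier:
    def test_perfect_predictions_zero(self):
        # two groups, no censoring: one fails at t=1, one never (competing)
        X = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        t = np.array([1.0, 1.2, 5.0, 6.0])
        event = np.array([1, 1, 2, 2])
        fit = fit_fine_gray(X, t, event)
        times, b = brier_curve(fit, X, t, event, [2.0, 3.0])
        assert np.all(b < 0.05)

    def test_constant_half_prediction_quarter_uncensored(self):
        rng = np.random.default_rng(7)
        n = 200
        t = np.concatenate([rng.uniform(0, 1, n // 2), rng.uniform(3, 4, n // 2)])
        event = np.concatenate([np.ones(n // 2, int), np.full(n // 2, 2)])
        X = rng.normal(size=(n, 1))

        class ConstantHalf:
            def predict_cumulative_incidence(self, X, times):
                return np.full((len(X), len(np.atleast_1d(times))), 0.5)

        times, b = brier_curve(ConstantHalf(), X, t, event, [2.0])
        assert b[0] == pytest.approx(0.25)

    def test_small_uncensored_matches_direct_mse(self):
        X = np.array([[0.5], [-0.5], [1.0], [-1.0], [0.0]])
        t = np.array([1.0, 4.0, 0.5, 5.0, 2.0])
        event = np.array([1, 1, 1, 2, 2])  # no censoring -> weights 1
        fit = fit_fine_gray(X, t, event)
        eval_t = 2.5
        times, b = brier_curve(fit, X, t, event, [eval_t])
        cif = fit.predict_cumulative_incidence(X, [eval_t])[:, 0]
        y = ((t <= eval_t) & (event == 1)).astype(float)
        assert b[0] == pytest.approx(np.mean((y - cif) ** 2))

    def test_integrated_brier_trapezoid(self):
        times = np.array([1.0, 2.0, 3.0])
        briers = np.array([0.1, 0.2, 0.1])
        assert integrated_brier(times, briers) == pytest.approx(
            np.trapezoid(briers, times) / 2.0
        )

    def test_prevalence_constant_predictor_bounded_quarter(self):
        rng = np.random.default_rng(8)
        n = 300
        t = rng.exponential(2, n)
        event = rng.choice([1, 2], n, p=[0.5, 0.5])

        class ConstantHalf:
            def predict_cumulative_incidence(self, X, times):
                return np.full((len(X), len(np.atleast_1d(times))), 0.5)

        times, b = brier_curve(ConstantHalf(), np.zeros((n, 1)), t, event,
                               np.linspace(0.5, 5, 10))
        assert np.all(b <= 0.25 + 1e-9)
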
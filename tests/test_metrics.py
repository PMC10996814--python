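"""IPCW Brier, IPCW NBLL, event-time concordance and the censoring KM."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter

from icisurv.hazard_net import DiscreteSurvivalPrediction
from icisurv.metrics import (
    brier_ipcw,
    concordance_td,
    default_eval_times,
    evaluate_predictions,
    integrate_over_time,
    km_censoring,
    nbll_ipcw,
)
from icisurv.preprocess import TimeGrid
from oracles import (
    brier_oracle,
    concordance_oracle,
    km_censoring_oracle,
    nbll_oracle,
    random_instance,
)


def _pred(edges, hazards):
    return DiscreteSurvivalPrediction(grid=TimeGrid(edges=np.asarray(edges, float)),
                                      hazards=np.asarray(hazards, float))


class TestKmCensoring:
    def test_no_censoring_gives_unit_g(self):
        G = km_censoring(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))
        assert np.all(G.at(np.array([0.5, 2.5, 3.0])) == 1.0)

    def test_hand_computed_example(self):
        # censorings at t=4 (3 at risk) and t=8 (1 at risk)
        G = km_censoring(np.array([2.0, 4.0, 6.0, 8.0]), np.array([1, 0, 1, 0]))
        assert G.at(np.array([3.9]))[0] == pytest.approx(1.0)
        assert G.at(np.array([4.0]))[0] == pytest.approx(2 / 3)
        assert G.at_left(np.array([4.0]))[0] == pytest.approx(1.0)
        assert G.at(np.array([8.0]))[0] == pytest.approx(0.0)

    def test_matches_lifelines_reference(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            d = rng.uniform(0.5, 50, size=n).round(1)
            e = rng.integers(0, 2, size=n)
            if (e == 0).sum() == 0:
                continue
            G = km_censoring(d, e)
            kmf = KaplanMeierFitter().fit(d, event_observed=1 - e)
            ts = rng.uniform(0, 60, size=10)
            ours = G.at(ts)
            ref = kmf.survival_function_at_times(ts).to_numpy()
            assert np.allclose(ours, ref, atol=1e-12)

    def test_monotone_non_increasing(self, rng):
        d = rng.uniform(0.5, 50, size=30)
        e = rng.integers(0, 2, size=30)
        G = km_censoring(d, e)
        vals = G.at(np.linspace(0, 60, 200))
        assert np.all(np.diff(vals) <= 1e-15)


class TestBrier:
    def test_perfect_forecaster_zero_at_nonevent_grid_times(self):
        edges = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        # events exactly at bin edges; under the (left-open, right-closed]
        # convention the survival step to 0 covers the bin *opening* at the
        # event time, so S(t)=1 for t <= T_i and 0 after
        durations = np.array([10.0, 30.0, 40.0])
        events = np.array([1, 1, 1])
        hazards = np.zeros((3, 4))
        hazards[0, 1] = hazards[1, 3] = 1.0  # last patient dies at the horizon
        pred = _pred(edges, hazards)
        eval_times = np.array([5.0, 15.0, 20.0, 25.0, 35.0])  # no event times
        bs = brier_ipcw(pred, durations, events, eval_times)
        assert np.allclose(bs, 0.0, atol=1e-12)

    def test_constant_half_forecast(self):
        edges = np.array([0.0, 50.0, 100.0])
        pred = _pred(edges, np.full((4, 2), 0.0))
        pred.survival[:] = 0.5
        durations = np.array([20.0, 40.0, 60.0, 80.0])
        events = np.ones(4, dtype=int)
        bs = brier_ipcw(pred, durations, events, np.array([30.0, 70.0]))
        assert np.allclose(bs, 0.25, atol=1e-12)

    def test_matches_bruteforce_oracle_with_censoring(self, rng):
        for _ in range(25):
            edges, hazards, survival, durations, events = random_instance(rng, n=5)
            pred = _pred(edges, hazards)
            ts = rng.uniform(1, 99, size=7)
            ours = brier_ipcw(pred, durations, events, ts)
            ref = brier_oracle(edges, survival, durations, events, ts)
            assert np.allclose(ours, ref, atol=1e-12)

    def test_zero_censoring_reduces_to_plain_brier(self, rng):
        edges, hazards, survival, durations, _ = random_instance(rng, n=20)
        events = np.ones(20, dtype=int)
        pred = _pred(edges, hazards)
        ts = np.linspace(5, 95, 9)
        ipcw = brier_ipcw(pred, durations, events, ts)
        plain = np.array([
            np.mean([
                (0.0 - pred.survival_at([t])[i, 0]) ** 2
                if durations[i] <= t else (1.0 - pred.survival_at([t])[i, 0]) ** 2
                for i in range(20)
            ])
            for t in ts
        ])
        assert np.allclose(ipcw, plain, atol=1e-14)


class TestNbll:
    def test_constant_half_forecast_gives_log_two(self):
        edges = np.array([0.0, 50.0, 100.0])
        pred = _pred(edges, np.full((4, 2), 0.0))
        pred.survival[:] = 0.5
        durations = np.array([20.0, 40.0, 60.0, 80.0])
        events = np.ones(4, dtype=int)
        nb = nbll_ipcw(pred, durations, events, np.array([30.0, 70.0]))
        assert np.allclose(nb, np.log(2), atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            edges, hazards, survival, durations, events = random_instance(rng, n=5)
            pred = _pred(edges, hazards)
            ts = rng.uniform(1, 99, size=7)
            ours = nbll_ipcw(pred, durations, events, ts)
            ref = nbll_oracle(edges, survival, durations, events, ts)
            assert np.allclose(ours, ref, atol=1e-12)


class TestIntegrate:
    def test_constant_curve(self):
        t = np.linspace(10, 90, 20)
        assert integrate_over_time(np.full(20, 0.37), t) == pytest.approx(0.37)

    def test_linear_curve(self):
        t = np.linspace(0, 100, 50)
        assert integrate_over_time(t / 100.0, t) == pytest.approx(0.5, abs=1e-12)

    def test_grid_refinement_stability(self):
        f = lambda t: 0.2 + 0.1 * np.sin(t / 30.0)
        t1 = np.linspace(1, 99, 100)
        t2 = np.linspace(1, 99, 200)
        assert abs(integrate_over_time(f(t1), t1) - integrate_over_time(f(t2), t2)) < 1e-3


class TestConcordance:
    def test_two_patients_correct_order(self):
        edges = np.array([0.0, 50.0, 100.0])
        pred = _pred(edges, np.array([[0.9, 0.9], [0.1, 0.1]]))
        c = concordance_td(pred, np.array([20.0, 80.0]), np.array([1, 1]))
        assert c == 1.0

    def test_identical_predictions_give_half(self):
        edges = np.array([0.0, 50.0, 100.0])
        pred = _pred(edges, np.array([[0.3, 0.3]] * 4))
        c = concordance_td(pred, np.array([10.0, 30.0, 60.0, 90.0]), np.ones(4, int))
        assert c == 0.5

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(25):
            edges, hazards, survival, durations, events = random_instance(rng, n=6)
            if events.sum() == 0:
                continue
            pred = _pred(edges, hazards)
            try:
                ref = concordance_oracle(edges, survival, durations, events)
            except ValueError:
                continue
            assert concordance_td(pred, durations, events) == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_raises(self):
        edges = np.array([0.0, 50.0, 100.0])
        pred = _pred(edges, np.array([[0.3, 0.3]] * 2))
        with pytest.raises(ValueError, match="comparable"):
            concordance_td(pred, np.array([10.0, 30.0]), np.array([0, 1]))

    def test_invariant_under_monotone_transform_while_brier_is_not(self, rng):
        edges, hazards, survival, durations, events = random_instance(rng, n=12)
        events[:6] = 1
        pred = _pred(edges, hazards)
        squared = _pred(edges, 1.0 - (1.0 - hazards) ** 2)  # S' = S**2
        assert np.allclose(squared.survival, pred.survival**2)
        c1 = concordance_td(pred, durations, events)
        c2 = concordance_td(squared, durations, events)
        assert c1 == pytest.approx(c2, abs=1e-12)
        ts = np.linspace(5, 95, 9)
        b1 = brier_ipcw(pred, durations, events, ts)
        b2 = brier_ipcw(squared, durations, events, ts)
        assert not np.allclose(b1, b2)


class TestReport:
    def test_interior_evaluation_grid(self):
        ts = default_eval_times(np.linspace(0, 200, 21))
        assert ts[0] > 0 and ts[-1] < 200 and len(ts) == 100

    def test_full_report_fields(self, rng):
        edges, hazards, survival, durations, events = random_instance(rng, n=15)
        events[:8] = 1
        rep = evaluate_predictions(_pred(edges, hazards), durations, events)
        assert 0 <= rep.c_index_td <= 1
        assert rep.ibs >= 0 and rep.inbll >= 0
        d = rep.to_dict()
        assert set(d["per_time"]) == {"times", "brier", "nbll"}
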
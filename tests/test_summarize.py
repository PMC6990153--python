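import numpy as np
import pytest

from ikrfit.model import summary_curves
from ikrfit.summarize import (
    Curve,
    SummaryError,
    SummarySet,
    act_ss_from_pr3,
    analyse_pr5,
    assemble_summary,
    fit_exponential,
    tau_act_from_pr2,
    tau_inact_from_pr4,
)


@pytest.fixture(scope="module")
def clean_traces(noiseless_cell):
    return {k: noiseless_cell.traces[k] for k in ("Pr2", "Pr3", "Pr4", "Pr5")}


class TestFitExponential:
    def test_noiseless_single_phase_recovery(self):
        t = np.arange(0, 100, 0.1)
        fit = fit_exponential(t, 2.0 * np.exp(-t / 15.0) + 1.0)
        assert fit.tau == pytest.approx(15.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-5)
        assert fit.offset == pytest.approx(1.0, abs=1e-5)

    def test_constant_data_gives_sentinel(self):
        t = np.arange(0, 10, 0.5)
        assert fit_exponential(t, np.full(t.size, 3.0)) is None

    def test_two_phase_recovery(self):
        t = np.arange(0, 300, 0.25)
        y = 3.0 * np.exp(-t / 5.0) + 1.5 * np.exp(-t / 50.0) + 0.3
        fast, slow = fit_exponential(t, y, n_phases=2)
        assert fast.tau == pytest.approx(5.0, rel=1e-3)
        assert slow.tau == pytest.approx(50.0, rel=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1, 2, 3])  # too few samples
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 1, 2], [1, 2, 3, 4])  # non-increasing
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2, 3], [1, 2, 3, 4], n_phases=3)


class TestPr2:
    def test_single_point_at_p1_voltage(self, clean_traces, protocols):
        point = tau_act_from_pr2(clean_traces["Pr2"], protocols["Pr2"])
        assert point is not None
        assert point[0] == 40.0

    def test_close_to_model_time_constant(self, clean_traces, protocols, params):
        _, tau = tau_act_from_pr2(clean_traces["Pr2"], protocols["Pr2"])
        model = summary_curves(params, [40.0])["tau_a"][0]
        assert tau == pytest.approx(model, rel=0.05)

    def test_scale_invariance(self, clean_traces, protocols):
        scaled = [t.with_currents(3.0 * t.currents) for t in clean_traces["Pr2"]]
        _, tau_a = tau_act_from_pr2(clean_traces["Pr2"], protocols["Pr2"])
        _, tau_b = tau_act_from_pr2(scaled, protocols["Pr2"])
        assert tau_a == pytest.approx(tau_b, rel=1e-6)


class TestPr3:
    def test_point_count(self, clean_traces, protocols):
        curve = act_ss_from_pr3(clean_traces["Pr3"], protocols["Pr3"])
        assert len(curve) == 7

    def test_normalization_invariance(self, clean_traces, protocols):
        doubled = [t.with_currents(2.0 * t.currents) for t in clean_traces["Pr3"]]
        a = act_ss_from_pr3(clean_traces["Pr3"], protocols["Pr3"])
        b = act_ss_from_pr3(doubled, protocols["Pr3"])
        assert np.allclose(a.values, b.values, rtol=1e-12)

    def test_monotone_and_saturating(self, clean_traces, protocols):
        curve = act_ss_from_pr3(clean_traces["Pr3"], protocols["Pr3"])
        assert np.all(np.diff(curve.values) >= -1e-12)
        assert curve.values[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all((curve.values >= 0) & (curve.values <= 1))

    def test_zero_tails_fail(self, clean_traces, protocols):
        dead = [t.with_currents(np.zeros_like(t.currents))
                for t in clean_traces["Pr3"]]
        with pytest.raises(SummaryError):
            act_ss_from_pr3(dead, protocols["Pr3"])


class TestPr4:
    def test_point_count_and_voltage_rule(self, clean_traces, protocols):
        curve = tau_inact_from_pr4(clean_traces["Pr4"], protocols["Pr4"])
        assert len(curve) == 9
        assert np.all(curve.voltages >= -40.0)

    def test_close_to_model_time_constants(self, clean_traces, protocols, params):
        curve = tau_inact_from_pr4(clean_traces["Pr4"], protocols["Pr4"])
        model = summary_curves(params, curve.voltages)["tau_r"]
        assert np.all(np.abs(curve.values - model) / model < 0.10)


class TestPr5:
    def test_point_counts(self, clean_traces, protocols, conditions):
        out = analyse_pr5(clean_traces["Pr5"], protocols["Pr5"], conditions.E_K)
        assert len(out["iv"]) == 9
        assert len(out["inact_ss"]) == 8
        assert len(out["tau_act"]) == 8
        assert len(out["tau_inact"]) == 8

    def test_near_reversal_voltage_excluded(self, clean_traces, protocols,
                                            conditions):
        out = analyse_pr5(clean_traces["Pr5"], protocols["Pr5"], conditions.E_K)
        nearest = min(
            protocols["Pr5"].meta["p2_voltages"],
            key=lambda v: abs(v - conditions.E_K),
        )
        assert nearest not in out["inact_ss"].voltages

    def test_inact_ss_scale_invariance(self, clean_traces, protocols, conditions):
        scaled = [t.with_currents(7.0 * t.currents) for t in clean_traces["Pr5"]]
        a = analyse_pr5(clean_traces["Pr5"], protocols["Pr5"], conditions.E_K)
        b = analyse_pr5(scaled, protocols["Pr5"], conditions.E_K)
        assert np.allclose(a["inact_ss"].values, b["inact_ss"].values, rtol=1e-12)

    def test_inact_ss_tracks_model_shape(self, clean_traces, protocols,
                                         conditions, params):
        """The extracted curve approximates but does not equal the model
        steady state (the derivation itself is imperfect); assert a bounded
        discrepancy and the same monotone decreasing shape."""
        out = analyse_pr5(clean_traces["Pr5"], protocols["Pr5"], conditions.E_K)
        curve = out["inact_ss"]
        model = summary_curves(params, curve.voltages)["r_inf"]
        model = model / model.max()
        assert np.max(np.abs(curve.values - model)) < 0.25
        assert np.all(np.diff(curve.values) < 0.05)

    def test_tau_act_close_to_model(self, clean_traces, protocols, conditions,
                                    params):
        out = analyse_pr5(clean_traces["Pr5"], protocols["Pr5"], conditions.E_K)
        curve = out["tau_act"]
        model = summary_curves(params, curve.voltages)["tau_a"]
        assert np.all(np.abs(curve.values - model) / model < 0.05)


class TestAssembleSummary:
    def test_counts(self, clean_traces, protocols, conditions):
        summary = assemble_summary(clean_traces, protocols, conditions.E_K)
        assert summary.counts() == (7, 8, 9, 17, 9)

    def test_deterministic(self, clean_traces, protocols, conditions):
        a = assemble_summary(clean_traces, protocols, conditions.E_K)
        b = assemble_summary(clean_traces, protocols, conditions.E_K)
        for name in ("act_ss", "inact_ss", "tau_act", "tau_inact", "iv"):
            assert np.array_equal(getattr(a, name).values, getattr(b, name).values)

    def test_missing_protocol_rejected(self, clean_traces, protocols, conditions):
        incomplete = {k: v for k, v in clean_traces.items() if k != "Pr4"}
        with pytest.raises(SummaryError):
            assemble_summary(incomplete, protocols, conditions.E_K)

    def test_gain_invariance_of_everything_but_iv(self, clean_traces, protocols,
                                                  conditions):
        scaled = {
            k: [t.with_currents(2.5 * t.currents) for t in v]
            for k, v in clean_traces.items()
        }
        a = assemble_summary(clean_traces, protocols, conditions.E_K)
        b = assemble_summary(scaled, protocols, conditions.E_K)
        for name in ("act_ss", "inact_ss", "tau_act", "tau_inact"):
            assert np.allclose(getattr(a, name).values, getattr(b, name).values,
                               rtol=1e-6)
        assert np.allclose(2.5 * a.iv.values, b.iv.values, rtol=1e-12)

    def test_masked_samples_never_used(self, clean_traces, protocols, conditions):
        corrupted = {}
        for name, traces in clean_traces.items():
            out = []
            for t in traces:
                currents = t.currents.copy()
                currents[~t.mask] = 1e6  # capacitance-spike garbage
                out.append(t.with_currents(currents))
            corrupted[name] = out
        a = assemble_summary(clean_traces, protocols, conditions.E_K)
        b = assemble_summary(corrupted, protocols, conditions.E_K)
        for name in ("act_ss", "inact_ss", "tau_act", "tau_inact", "iv"):
            assert np.array_equal(getattr(a, name).values, getattr(b, name).values)

    def test_csv_round_trip(self, tmp_path, clean_traces, protocols, conditions):
        summary = assemble_summary(clean_traces, protocols, conditions.E_K)
        path = tmp_path / "summary.csv"
        summary.save(path)
        back = SummarySet.load(path)
        for name in ("act_ss", "inact_ss", "tau_act", "tau_inact", "iv"):
            assert np.array_equal(
                getattr(summary, name).values, getattr(back, name).values
            )

    def test_noisy_counts_stable(self, noisy_cell):
        assert noisy_cell.summary.counts() == (7, 8, 9, 17, 9)


class TestCurve:
    def test_sorted_by_voltage(self):
        c = Curve([0.0, -40.0, -20.0], [3.0, 1.0, 2.0])
        assert np.array_equal(c.voltages, [-40.0, -20.0, 0.0])
        assert np.array_equal(c.values, [1.0, 2.0, 3.0])

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            Curve([0.0, 1.0], [1.0])
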
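"""Simulation/ensemble drivers, pacing, steady-state detection, grids."""

import json

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ionstep import (InvalidArgumentError, RunPlan, StimulusProtocol, Trace,
                     parameter_grid, run_ensemble, run_simulation,
                     steady_state_check)
from ionstep.metrics import rrms

from conftest import make_block


class TestStimulusProtocol:
    def test_single_pulse(self):
        stim = StimulusProtocol(amplitude=-8.0, pulse_duration=0.5)
        assert stim.current(0.0) == -8.0
        assert stim.current(0.5) == -8.0
        assert stim.current(0.51) == 0.0
        assert stim.current(-0.1) == 0.0

    def test_periodic_pacing(self):
        stim = StimulusProtocol(amplitude=5.0, pulse_duration=2.0,
                                period=1000.0, start_time=10.0)
        assert stim.current(11.0) == 5.0
        assert stim.current(500.0) == 0.0
        assert stim.current(1011.0) == 5.0  # next beat

    def test_duration_must_fit_period(self):
        with pytest.raises(InvalidArgumentError):
            StimulusProtocol(amplitude=1.0, pulse_duration=3.0, period=2.0)

    def test_as_parameters_feeds_models(self, synth3):
        stim = StimulusProtocol(amplitude=3.0, pulse_duration=1.0, period=500.0)
        m = synth3.with_parameters(**stim.as_parameters())
        assert m.parameters["stim_period"] == 500.0


class TestRunSimulation:
    def test_zero_steps_records_only_t0(self, fhn, fhn_block):
        before = fhn_block.unpack()
        plan = RunPlan(dt=0.1, n_steps=0)
        _, trace = run_simulation(fhn, fhn_block, plan)
        assert trace.times.shape == (1,)
        assert trace.times[0] == 0.0
        np.testing.assert_array_equal(fhn_block.unpack(), before)

    def test_determinism_bit_identical(self, synth3):
        plan = RunPlan(dt=0.05, n_steps=200, scheme="rl")
        traces = []
        for _ in range(2):
            blk = make_block(synth3, 5, jitter=0.01, seed=9)
            _, tr = run_simulation(synth3, blk, plan)
            traces.append(tr)
        for var in traces[0].data:
            np.testing.assert_array_equal(traces[0].data[var], traces[1].data[var])

    def test_fhn_pulse_trajectory_matches_adaptive_oracle(self, fhn):
        """FE at dt=1e-3 over 3000 steps: the -8 pulse drives v below -1.5
        and the state relaxes back toward rest, tracking the adaptive
        reference to first-order accuracy."""
        p = fhn.parameters

        def rhs(t, s):
            return fhn.rhs(t, np.asarray(s), p)
        sol_on = solve_ivp(rhs, [0, 0.5], [0, 0], rtol=1e-11, atol=1e-13)
        free = lambda t, s: fhn.rhs(10.0, np.asarray(s), p)
        sol_off = solve_ivp(free, [0.5, 3.0], sol_on.y[:, -1],
                            rtol=1e-11, atol=1e-13)

        blk = make_block(fhn, 1)
        plan = RunPlan(dt=1e-3, n_steps=3000, scheme="fe", record_stride=10)
        _, trace = run_simulation(fhn, blk, plan)
        v = trace.series("v")
        assert v.min() < -1.5              # pulse trough
        assert abs(v[-1] - sol_off.y[0, -1]) < 5e-3   # O(dt) global error
        assert v.max() < 0.25              # no runaway excursion

    def test_record_stride_and_vars(self, fhn):
        blk = make_block(fhn, 2)
        plan = RunPlan(dt=0.01, n_steps=100, record_stride=10, record_vars=("v",))
        _, trace = run_simulation(fhn, blk, plan)
        assert set(trace.data) == {"v"}
        assert trace.times.shape == (11,)
        np.testing.assert_allclose(np.diff(trace.times), 0.1, rtol=1e-12)

    def test_unknown_record_var_rejected(self, fhn):
        with pytest.raises(InvalidArgumentError):
            run_simulation(fhn, make_block(fhn, 1),
                           RunPlan(dt=0.1, n_steps=1, record_vars=("bogus",)))


class TestRunEnsemble:
    def _param_table(self, model, n_cells, seed=0):
        rng = np.random.default_rng(seed)
        return {"g0": model.parameters["g0"] * rng.uniform(0.5, 1.5, n_cells)}

    @pytest.mark.parametrize("scheme", ["fe", "rl", "grl1"])
    def test_loop_structures_agree(self, synth3, scheme):
        table = self._param_table(synth3, 10)
        plan = dict(dt=0.05, n_steps=300, scheme=scheme, record_vars=("v",))
        results = {}
        for loop in ("time-cell", "cell-time", "cell-time-cell"):
            _, tr = run_ensemble(synth3, table, None,
                                 RunPlan(loop_structure=loop, batch_size=8, **plan))
            results[loop] = tr.data["v"]
        ref = results["time-cell"]
        for loop in ("cell-time", "cell-time-cell"):
            assert rrms(results[loop].ravel(), ref.ravel()) <= 1e-13

    def test_batch_size_transparent(self, synth3):
        table = self._param_table(synth3, 20)
        ref = None
        for b in (8, 16, 32, 64):
            plan = RunPlan(dt=0.05, n_steps=100, scheme="rl",
                           loop_structure="cell-time-cell", batch_size=b,
                           record_vars=("v",))
            _, tr = run_ensemble(synth3, table, None, plan)
            if ref is None:
                ref = tr.data["v"]
            else:
                np.testing.assert_array_equal(tr.data["v"], ref)

    def test_single_cell_degenerate(self, synth3):
        table = self._param_table(synth3, 1)
        outs = []
        for loop in ("time-cell", "cell-time", "cell-time-cell"):
            plan = RunPlan(dt=0.05, n_steps=50, scheme="rl",
                           loop_structure=loop, batch_size=8)
            final, tr = run_ensemble(synth3, table, None, plan)
            outs.append((final.unpack(), tr.data["v"]))
        for fin, v in outs[1:]:
            np.testing.assert_array_equal(fin, outs[0][0])
            np.testing.assert_array_equal(v, outs[0][1])

    def test_row_count_mismatch_rejected(self, synth3):
        table = self._param_table(synth3, 4)
        init = np.tile(synth3.default_initial_state, (5, 1))
        with pytest.raises(InvalidArgumentError):
            run_ensemble(synth3, table, init, RunPlan(dt=0.1, n_steps=1))

    def test_unknown_parameter_rejected(self, synth3):
        with pytest.raises(InvalidArgumentError):
            run_ensemble(synth3, {"nope": np.ones(3)}, None,
                         RunPlan(dt=0.1, n_steps=1))


class TestPaddingSafety:
    def test_fuzzed_pad_lanes_do_not_leak(self, synth5):
        """Arbitrary finite garbage in the SoA padding must leave every
        live-cell output bit-identical."""
        plan = RunPlan(dt=0.05, n_steps=200, scheme="rl")
        ref_blk = make_block(synth5, 11, jitter=0.01, seed=2)   # pads to 16
        fuzz_blk = ref_blk.copy()
        rng = np.random.default_rng(8)
        view = fuzz_blk.active_view()
        view[:, fuzz_blk.n_cells:] = rng.uniform(-5, 5,
                                                 (synth5.n_states,
                                                  view.shape[1] - fuzz_blk.n_cells))
        _, tr_ref = run_simulation(synth5, ref_blk, plan)
        _, tr_fuzz = run_simulation(synth5, fuzz_blk, plan)
        for var in tr_ref.data:
            np.testing.assert_array_equal(tr_fuzz.data[var], tr_ref.data[var])
        np.testing.assert_array_equal(fuzz_blk.unpack(), ref_blk.unpack())


def _mk_trace(times, v):
    plan = RunPlan(dt=times[1] - times[0], n_steps=len(times) - 1)
    return Trace(np.asarray(times, float), {"v": np.asarray(v, float)}, plan)


class TestSteadyStateCheck:
    def test_exactly_periodic_is_steady(self):
        t = np.arange(40) * 0.25
        one_period = np.sin(2 * np.pi * np.arange(20) / 20.0)
        v = np.tile(one_period, 2)[:, None]
        steady, dev = steady_state_check(_mk_trace(t, v), period=5.0,
                                         tolerance=1e-12)
        assert steady and dev == 0.0

    def test_scaled_period_deviation(self):
        # second period = first * (1 + delta): RRMS deviation equals delta
        t = np.arange(40) * 0.25
        base = 1.0 + 0.5 * np.sin(2 * np.pi * t[:20] / 5.0)
        v = np.concatenate([base, base * 1.001])[:, None]
        steady, dev = steady_state_check(_mk_trace(t, v), period=5.0,
                                         tolerance=1e-4)
        assert not steady
        np.testing.assert_allclose(dev, 1e-3, rtol=1e-9)

    def test_short_trace_rejected(self):
        t = np.arange(30) * 0.25   # 1.5 periods of 5.0
        v = np.zeros((30, 1))
        with pytest.raises(InvalidArgumentError):
            steady_state_check(_mk_trace(t, v), period=5.0, tolerance=1e-3)

    def test_incommensurate_period_rejected(self):
        t = np.arange(40) * 0.25
        v = np.ones((40, 1))
        with pytest.raises(InvalidArgumentError):
            steady_state_check(_mk_trace(t, v), period=5.1, tolerance=1e-3)

    def test_paced_synthetic_model_approaches_steady_state(self, synth3):
        """Two beats of 1 Hz pacing: the deviation between consecutive
        periods is small once the gates have relaxed."""
        stim_period = synth3.parameters["stim_period"]  # 1000 ms
        plan = RunPlan(dt=0.5, n_steps=6000, scheme="rl", record_stride=10,
                       record_vars=("v",))
        _, trace = run_simulation(synth3, make_block(synth3, 1), plan)
        steady, dev = steady_state_check(trace, period=stim_period,
                                         tolerance=1e-2)
        assert steady, dev


class TestParameterGrid:
    @pytest.mark.parametrize("sizes,total", [((2, 3), 6), ((5, 12), 60), ((3,), 3)])
    def test_row_counts(self, sizes, total):
        grid = {f"p{i}": list(range(n)) for i, n in enumerate(sizes)}
        assert len(parameter_grid(grid)) == total

    def test_last_parameter_varies_fastest(self):
        df = parameter_grid({"a": [1, 2], "b": [10, 20, 30]})
        np.testing.assert_array_equal(df["b"].to_numpy()[:3], [10, 20, 30])
        np.testing.assert_array_equal(df["a"].to_numpy()[:3], [1, 1, 1])

    def test_empty_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            parameter_grid({"a": []})


class TestRunPlan:
    def test_json_and_toml_configs(self, tmp_path):
        cfg = {"dt": 0.01, "n_steps": 50, "scheme": "rl", "layout": "aos",
               "loop_structure": "cell-time", "record_stride": 5}
        jp = tmp_path / "run.json"
        jp.write_text(json.dumps(cfg))
        tp = tmp_path / "run.toml"
        tp.write_text("\n".join(f'{k} = "{v}"' if isinstance(v, str) else f"{k} = {v}"
                                for k, v in cfg.items()))
        for path in (jp, tp):
            plan = RunPlan.from_file(path)
            assert plan.scheme == "rl"
            assert plan.layout.value == "aos"
            assert plan.record_stride == 5

    def test_validation(self):
        with pytest.raises(InvalidArgumentError):
            RunPlan(dt=-1.0, n_steps=1)
        with pytest.raises(InvalidArgumentError):
            RunPlan(dt=0.1, n_steps=1, batch_size=12, lane_width=8)
        with pytest.raises(InvalidArgumentError):
            RunPlan(dt=0.1, n_steps=1, scheme="fe", lut=True)

    def test_roundtrip_dict(self):
        plan = RunPlan(dt=0.1, n_steps=5, scheme="grl1", record_vars=("v",))
        assert RunPlan.from_dict(plan.to_dict()) == plan


def test_trace_csv(tmp_path, fhn):
    blk = make_block(fhn, 3)
    _, trace = run_simulation(fhn, blk, RunPlan(dt=0.01, n_steps=10))
    path = tmp_path / "trace.csv"
    trace.write_csv(path)
    import pandas as pd
    df = pd.read_csv(path)
    assert list(df.columns)[0] == "t"
    assert "v[0]" in df.columns and "w[2]" in df.columns
    assert len(df) == 11
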
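"""Dispatch loop scheduling, workflow stage ordering, metrics, shutdown."""

import json
from pathlib import Path

import pytest

from simbatch.core import SimSet, SimState, parse_simspec, summarize
from simbatch.engine import (STAGES, EngineConfig, SessionAbort,
                             SessionMetrics, dump_config, load_config,
                             run_from_simset, run_session, shutdown, stage)
from simbatch.fixtures import make_local_machineset
from simbatch.provenance import parse_log
from simbatch.simulators import (SimulatorDescriptor, register_simtype)
from simbatch.payloads import payload_path


def config(tmp_path, machines, sim_type="sine01", **overrides):
    defaults = dict(
        session_name="t",
        sim_type=sim_type,
        root=str(tmp_path / "sessions"),
        machines=machines,
        poll_interval=0.02,
        wall_time=60.0,
    )
    defaults.update(overrides)
    return EngineConfig(**defaults)


def noop_simset(n, prefix="s"):
    return parse_simspec(
        "\n".join(f"{prefix}{i:02d}" for i in range(1, n + 1)), "noop")


def sine_simset(n):
    return parse_simspec(
        "\n".join(f"s{i:02d}\t{1 + i % 3}\t0.05" for i in range(1, n + 1)),
        "sine")


def read_log(session):
    return parse_log(
        (session.session_dir / "log" / "activity.log").read_text())


def assignments(events):
    """(sim_id, simulator_id) pairs in log order."""
    out = []
    for e in events:
        if e.stage_name == "FetchParameterVector" and \
                "-> simulator " in e.detail:
            out.append((e.sim_id, e.detail.rsplit("-> simulator ", 1)[1]))
    return out


def replay_fcfs(events):
    """Brute-force scheduling oracle: replays the log and checks that every
    assignment went to the lowest-index AVAILABLE simulator at that moment."""
    pool_order = [e.detail.split(":")[0].split()[-1] for e in events
                  if e.stage_name == "SimulatorVerify"
                  and e.detail.endswith("AVAILABLE")]
    available = list(pool_order)
    for e in events:
        if e.stage_name == "FetchParameterVector" and \
                "-> simulator " in e.detail:
            got = e.detail.rsplit("-> simulator ", 1)[1]
            expected = min(available, key=pool_order.index)
            assert got == expected, (e.sim_id, got, expected)
            available.remove(got)
        elif e.stage_name == "SimulatorReset" and \
                e.detail.endswith("reset, AVAILABLE"):
            available.append(e.detail.split()[1])
    return pool_order


class TestFCFS:
    def test_first_dispatch_fills_pool_in_order(self, tmp_path,
                                                local_machines):
        # 20 blocking no-op runs on a 2+5 pool: the first seven go, in
        # SimSet order, to M11, M12 then M21..M25
        cfg = config(tmp_path, local_machines, sim_type="noop01",
                     simulator_options={"delay": "0.4"})
        session = run_from_simset(cfg, noop_simset(20))
        pairs = assignments(read_log(session))
        assert [p[0] for p in pairs[:7]] == \
            [f"s{i:02d}" for i in range(1, 8)]
        assert [p[1] for p in pairs[:7]] == \
            ["M11", "M12", "M21", "M22", "M23", "M24", "M25"]
        assert summarize(session.result)["n_complete"] == 20

    def test_every_assignment_matches_replay_oracle(self, tmp_path,
                                                    local_machines):
        cfg = config(tmp_path, local_machines, sim_type="noop01",
                     simulator_options={"delay": "0.1"})
        session = run_from_simset(cfg, noop_simset(20))
        events = read_log(session)
        pool_order = replay_fcfs(events)
        assert pool_order == ["M11", "M12", "M21", "M22", "M23",
                              "M24", "M25"]
        assert len(assignments(events)) == 20

    def test_pool_of_one_is_strictly_serial(self, tmp_path):
        machines = make_local_machineset(tmp_path / "m", counts=(1,))
        cfg = config(tmp_path, machines, sim_type="noop01")
        session = run_from_simset(cfg, noop_simset(5))
        events = read_log(session)
        pairs = assignments(events)
        assert pairs == [(f"s{i:02d}", "M11") for i in range(1, 6)]
        # serial: each download precedes the next fetch
        order = [(e.stage_name, e.sim_id) for e in events
                 if e.stage_name in ("FetchParameterVector",
                                     "ResultDownload")]
        expected = []
        for i in range(1, 6):
            expected += [("FetchParameterVector", f"s{i:02d}"),
                         ("ResultDownload", f"s{i:02d}")]
        assert order == expected


class TestWorkflow:
    def test_twenty_two_stage_catalogue(self):
        assert len(STAGES) == 22
        assert [s.index for s in STAGES] == list(range(1, 23))
        assert len({s.name for s in STAGES}) == 22
        assert sorted({s.abstract_group for s in STAGES}) == \
            list(range(1, 10))
        assert stage("PreRunModelProcessingHost").abstract_group == 6

    def test_session_logs_all_22_stage_names(self, run_sine_session):
        session = run_sine_session()
        names = {e.stage_name for e in read_log(session)}
        assert names == {s.name for s in STAGES}

    def test_per_simulation_stage_indices_strictly_increase(
            self, run_sine_session):
        session = run_sine_session()
        per_sim = {}
        for e in read_log(session):
            if e.sim_id is not None:
                per_sim.setdefault(e.sim_id, []).append(e.stage_index)
        assert set(per_sim) == {"s1", "s2", "s3"}
        for sim_id, indices in per_sim.items():
            assert indices == sorted(indices), sim_id
            assert len(indices) == len(set(indices)), sim_id
            assert indices[0] == 9 and indices[-1] == 22

    def test_conservation_and_terminality(self, tmp_path, local_machines):
        cfg = config(tmp_path, local_machines)
        session = run_from_simset(cfg, sine_simset(9))
        counts = summarize(session.result)
        assert counts["n_total"] == 9
        assert counts["n_complete"] + counts["n_failed"] == 9
        assert all(s.state.terminal for s in session.simset)

    def test_empty_simset(self, tmp_path, local_machines):
        cfg = config(tmp_path, local_machines)
        session = run_from_simset(cfg, SimSet(name="empty"))
        assert summarize(session.result) == \
            {"n_total": 0, "n_complete": 0, "n_failed": 0}
        assert session.metrics.simset_time == 0.0


class TestEquivalence:
    def test_serial_equals_parallel_byte_for_byte(self, tmp_path):
        outputs = {}
        for label, counts in (("serial", (1,)), ("parallel", (2, 5))):
            machines = make_local_machineset(tmp_path / label, counts=counts)
            cfg = config(tmp_path / label, machines)
            session = run_from_simset(cfg, sine_simset(12))
            assert summarize(session.result)["n_complete"] == 12
            outputs[label] = {
                r.sim_id: {name: (Path(r.result_location) / name).read_bytes()
                           for name in ("sine.csv", "sine.svg", "SUCCESS")}
                for r in session.result.records}
        assert outputs["serial"] == outputs["parallel"]


class TestMetrics:
    def test_overhead_is_session_minus_simset(self):
        m = SessionMetrics.from_times(3950.0, 3741.0)
        assert m.overhead == 209.0
        m = SessionMetrics.from_times(1408.0, 1242.0)
        assert m.overhead == 166.0

    def test_mean_overhead_per_simulator(self):
        m = SessionMetrics.from_times(1000.0, 959.0,
                                      mean_execution_time=780.0,
                                      pool_size=12)
        assert m.simset_overhead == 179.0
        assert m.mean_overhead_per_simulator == 15

    def test_invariant_enforced(self):
        with pytest.raises(ValueError, match="overhead"):
            SessionMetrics(session_time=10.0, simset_time=3.0, overhead=5.0)

    def test_live_session_metrics_consistent(self, run_sine_session):
        session = run_sine_session()
        m = session.metrics
        assert m.session_time >= m.simset_time >= 0
        assert abs(m.overhead - (m.session_time - m.simset_time)) < 1e-9
        assert set(m.per_simulation_times) == {"s1", "s2", "s3"}
        assert all(v >= 0 for v in m.per_simulation_times.values())


class TestFailureHandling:
    def test_bad_arity_isolated_from_good_runs(self, run_sine_session):
        session = run_sine_session("g1\t1\t0.1\nbad\t1\ng2\t2\t0.1\n")
        by_id = {r.sim_id: r for r in session.result.records}
        assert by_id["g1"].success and by_id["g2"].success
        assert not by_id["bad"].success
        assert "arity" in by_id["bad"].failure_reason
        # the downloaded result dir keeps the remote FAIL sentinel content
        fail_file = Path(by_id["bad"].result_location, "FAIL")
        assert "arity" in fail_file.read_text()

    def test_all_builds_failing_aborts_session(self, tmp_path,
                                               local_machines):
        def _factory(options):
            return SimulatorDescriptor(
                sim_type="brokenbuild01", version="0",
                entry_point="noop_entry.py",
                payload_files=(str(payload_path("noop_entry.py")),),
                build_command="echo no compiler here && false",
                n_free_params=0)

        register_simtype("brokenbuild01", _factory)
        cfg = config(tmp_path, local_machines, sim_type="brokenbuild01")
        with pytest.raises(SessionAbort, match="no compiler here"):
            run_from_simset(cfg, noop_simset(2))

    def test_retire_threshold_then_no_available_simulator(self, tmp_path):
        machines = make_local_machineset(tmp_path / "m", counts=(1,))
        cfg = config(tmp_path, machines, retire_threshold=2)
        simset = parse_simspec("b1\t1\nb2\t1\nb3\t1\nb4\t1\n", "bad")
        session = run_from_simset(cfg, simset)
        counts = summarize(session.result)
        assert counts == {"n_total": 4, "n_complete": 0, "n_failed": 4}
        events = read_log(session)
        assert any("RETIRED after 2 consecutive failures" in e.detail
                   for e in events if e.stage_name == "SimulatorReset")
        by_id = {s.sim_id: s for s in session.simset}
        assert by_id["b3"].failure_reason == "no available simulator"
        assert by_id["b4"].failure_reason == "no available simulator"

    def test_success_resets_consecutive_failure_count(self, tmp_path):
        machines = make_local_machineset(tmp_path / "m", counts=(1,))
        cfg = config(tmp_path, machines, retire_threshold=2)
        simset = parse_simspec("b1\t1\ng1\t1\t0.05\nb2\t1\ng2\t1\t0.05\n",
                               "mix")
        session = run_from_simset(cfg, simset)
        assert summarize(session.result) == \
            {"n_total": 4, "n_complete": 2, "n_failed": 2}


class TestDryRun:
    def test_dry_run_submits_nothing(self, tmp_path, local_machines):
        cfg = config(tmp_path, local_machines, dry_run=True)
        session = run_from_simset(cfg, sine_simset(3))
        assert summarize(session.result)["n_failed"] == 3
        assert all(s.failure_reason == "dry-run (not executed)"
                   for s in session.simset)
        details = [e.detail for e in read_log(session)
                   if e.stage_name == "JobSubmission"]
        assert all(d.startswith("dry-run: ") for d in details)
        # nothing executed anywhere under the machine work dirs
        for m in local_machines.entries:
            assert not list(Path(m.work_dir).rglob("SUCCESS"))


class TestShutdownAndConfig:
    def test_shutdown_idempotent_and_report_complete(self,
                                                     run_sine_session):
        session = run_sine_session()
        report_path = shutdown(session)  # second call: run already shut down
        assert report_path == shutdown(session)
        report = json.loads(report_path.read_text())
        assert report["n_total"] == 3 and report["n_complete"] == 3
        assert report["aborted"] is False
        assert report["metrics"]["overhead"] == pytest.approx(
            session.metrics.overhead)
        assert (session.session_dir / "reports" / "result.csv").is_file()
        # remote run dirs were cleaned
        for inst in session.pool:
            assert not Path(inst.run_dir).exists()

    def test_run_session_from_simspec_file(self, tmp_path, local_machines):
        spec = tmp_path / "sweep.txt"
        spec.write_text("a\t1\t0.05\nb\t2\t0.05\n")
        cfg = config(tmp_path, local_machines)
        session = run_session(cfg, spec)
        assert summarize(session.result)["n_complete"] == 2
        snapshots = list((session.session_dir / "snapshots").iterdir())
        assert any(p.name.startswith("sweep") for p in snapshots)

    def test_config_round_trip(self, tmp_path, local_machines):
        cfg = config(tmp_path, local_machines, sim_type="noop01",
                     simulator_options={"delay": "0.5"},
                     notify_file="notify.jsonl",
                     notify_events=("SESSION_START", "SESSION_END"))
        path = tmp_path / "session.cfg"
        path.write_text(dump_config(cfg))
        back = load_config(path)
        assert back.sim_type == "noop01"
        assert back.simulator_options["delay"] == "0.5"
        assert back.notify_events == ("SESSION_START", "SESSION_END")
        assert [m.name for m in back.machines.entries] == \
            [m.name for m in cfg.machines.entries]
        assert back.machines.capacity == 7

    def test_missing_config_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_config(tmp_path / "nope.cfg")
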
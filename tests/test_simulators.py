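"""Simulator lifecycle, model-file assembly, and XML channel editing."""

import subprocess
import sys
from pathlib import Path

import pytest
from hypothesis import given
from hypothesis import strategies as st
from lxml import etree

from simbatch.core import InputParameterVector, Simulation, SimState
from simbatch.fixtures import (make_broken_channel_fixture,
                               make_channel_fixture,
                               make_model_template_fixture)
from simbatch.machines import LocalTransport, MachineConfig
from simbatch.simulators import (CHANNEL_FREE_PARAMS, ChannelEditError,
                                 ModelProcessingError, SimulatorState,
                                 assemble_template, build_run_command,
                                 channel_param_names, construct_simulator,
                                 download_results, edit_channel_xml,
                                 make_descriptor, prerun_model_processing,
                                 read_channel_param,
                                 render_channel_to_simcore_input,
                                 reset_simulator)
from simbatch.payloads import payload_path


@pytest.fixture
def machine(tmp_path):
    return MachineConfig("generic_unix", 2, str(tmp_path / "work"),
                         name="M1")


@pytest.fixture
def sine_desc():
    return make_descriptor("sine01")


class TestConstructSimulator:
    def test_payload_present_and_available(self, machine, sine_desc):
        t = LocalTransport()
        inst = construct_simulator(sine_desc, machine, t, slot=1)
        assert inst.state is SimulatorState.AVAILABLE
        assert (Path(inst.install_dir) / "sine_entry.py").is_file()
        assert (Path(inst.install_dir) / "static_params.json").is_file()

    def test_failing_build_retires_with_log(self, machine, tmp_path):
        desc = make_descriptor("sine01")
        desc = type(desc)(**{**desc.__dict__,
                             "build_command": "echo broken build && false"})
        inst = construct_simulator(desc, machine, LocalTransport(), slot=1)
        assert inst.state is SimulatorState.RETIRED
        assert "broken build" in inst.build_log

    def test_two_instances_get_distinct_install_dirs(self, machine,
                                                     sine_desc):
        t = LocalTransport()
        a = construct_simulator(sine_desc, machine, t, slot=1)
        b = construct_simulator(sine_desc, machine, t, slot=2)
        assert a.install_dir != b.install_dir
        assert a.simulator_id == "M11" and b.simulator_id == "M12"


class TestPrerunModelProcessing:
    def test_kh_values_land_in_their_sections(self, tmp_path):
        template = tmp_path / "model.hoc.tmpl"
        template.write_text(make_model_template_fixture())
        desc = make_descriptor("khmodel01", {"template": str(template)})
        ipv = InputParameterVector("k1", ("0.11", "0.22", "0.33"))
        files = prerun_model_processing(desc, ipv, tmp_path / "ws")
        assert [f.name for f in files] == ["purkinje.hoc"]
        text = files[0].read_text()
        # independent string-position oracle: each density appears in its
        # own section block, in soma/smooth/spiny order
        soma = text.index("soma {")
        smooth = text.index('forsec "smooth"')
        spiny = text.index('forsec "spiny"')
        assert soma < text.index("0.11") < smooth
        assert smooth < text.index("0.22") < spiny
        assert spiny < text.index("0.33")
        assert "{kh_" not in text  # all placeholders consumed

    def test_no_model_files_is_a_no_op(self, tmp_path, sine_desc):
        ipv = InputParameterVector("s1", ("1", "1"))
        assert prerun_model_processing(sine_desc, ipv, tmp_path / "ws") == []
        assert not (tmp_path / "ws").exists()

    def test_missing_placeholder_named(self, tmp_path):
        template = tmp_path / "bad.tmpl"
        template.write_text("value = {missing}\n")
        desc = make_descriptor("khmodel01", {"template": str(template)})
        ipv = InputParameterVector("k1", ("1", "2", "3"))
        with pytest.raises(ModelProcessingError, match="missing"):
            prerun_model_processing(desc, ipv, tmp_path / "ws")

    def test_arity_mismatch_rejected(self, tmp_path):
        template = tmp_path / "model.tmpl"
        template.write_text(make_model_template_fixture())
        desc = make_descriptor("khmodel01", {"template": str(template)})
        with pytest.raises(ModelProcessingError, match="expects 3"):
            prerun_model_processing(desc, InputParameterVector("k1", ("1",)),
                                    tmp_path / "ws")

    def test_literal_brace_escaping(self):
        assert assemble_template("a {{x}} {y}", {"y": "2"}) == "a {x} 2"


def canonical(tree) -> bytes:
    return etree.tostring(
        tree.getroot() if hasattr(tree, "getroot") else tree, method="c14n")


@pytest.fixture
def channel_doc():
    return etree.ElementTree(
        etree.fromstring(make_channel_fixture(seed=7).encode()))


EIGHT = {name: f"{i + 1}.5" for i, name in enumerate(CHANNEL_FREE_PARAMS)}


class TestEditChannelXml:
    def test_all_eight_assignments_read_back_exactly(self, channel_doc):
        edited = edit_channel_xml(channel_doc, EIGHT)
        for name, value in EIGHT.items():
            assert read_channel_param(edited, name) == value

    def test_fixture_exposes_exactly_eight_slots(self, channel_doc):
        assert sorted(channel_param_names(channel_doc)) == \
            sorted(CHANNEL_FREE_PARAMS)

    def test_empty_assignments_is_canonical_identity(self, channel_doc):
        assert canonical(edit_channel_xml(channel_doc, {})) == \
            canonical(channel_doc)

    def test_unaffected_content_unchanged(self, channel_doc):
        edited = edit_channel_xml(channel_doc, {"mAlphaA": "9"})
        leak = edited.getroot().find("leak")
        assert leak.get("conductance") == \
            channel_doc.getroot().find("leak").get("conductance")

    def test_unknown_parameter_rejected(self, channel_doc):
        with pytest.raises(ChannelEditError, match="zzz"):
            edit_channel_xml(channel_doc, {"zzz": "1"})

    def test_declared_but_absent_from_document(self):
        broken = etree.ElementTree(
            etree.fromstring(make_broken_channel_fixture(seed=7).encode()))
        with pytest.raises(ChannelEditError, match="absent"):
            edit_channel_xml(broken, {"hAlphaA": "1"})

    def test_idempotent(self, channel_doc):
        once = edit_channel_xml(channel_doc, EIGHT)
        twice = edit_channel_xml(once, EIGHT)
        assert canonical(once) == canonical(twice)

    @given(st.integers(1, 7))
    def test_commutes_across_disjoint_parameter_sets(self, channel_doc, k):
        names = list(CHANNEL_FREE_PARAMS)
        first = {n: EIGHT[n] for n in names[:k]}
        second = {n: EIGHT[n] for n in names[k:]}
        ab = edit_channel_xml(edit_channel_xml(channel_doc, first), second)
        ba = edit_channel_xml(edit_channel_xml(channel_doc, second), first)
        assert canonical(ab) == canonical(ba)


class TestRenderChannel:
    TEMPLATE = ("alpha_m = {mAlphaA} / {mAlphak}\n"
                "beta_m = {mBetaA} / {mBetak}\n"
                "alpha_h = {hAlphaA} / {hAlphak}\n"
                "beta_h = {hBetaA} / {hBetak}\n")

    def test_values_match_direct_substitution_oracle(self, channel_doc):
        edited = edit_channel_xml(channel_doc, {"mAlphaA": "X"})
        rendered = render_channel_to_simcore_input(edited, self.TEMPLATE)
        # oracle: substitute by regex straight off the XML text
        values = {n: read_channel_param(edited, n)
                  for n in CHANNEL_FREE_PARAMS}
        expected = self.TEMPLATE
        for n, v in values.items():
            expected = expected.replace("{" + n + "}", v)
        assert rendered == expected
        assert "X" in rendered.splitlines()[0]

    def test_deterministic(self, channel_doc):
        a = render_channel_to_simcore_input(channel_doc, self.TEMPLATE)
        b = render_channel_to_simcore_input(channel_doc, self.TEMPLATE)
        assert a == b

    def test_template_requiring_absent_field_rejected(self, channel_doc):
        with pytest.raises(ModelProcessingError, match="nAlphaA"):
            render_channel_to_simcore_input(channel_doc, "{nAlphaA}")

    def test_pluggable_transform_hook(self, channel_doc):
        out = render_channel_to_simcore_input(
            channel_doc, "tmpl", transform=lambda doc, t: f"external:{t}")
        assert out == "external:tmpl"


class TestChannelHook:
    def test_prerun_writes_edited_xml_and_mod(self, tmp_path):
        channel = tmp_path / "naf.xml"
        channel.write_text(make_channel_fixture(seed=3))
        desc = make_descriptor("channel01", {"channel": str(channel)})
        ipv = InputParameterVector("c1", tuple(EIGHT[n]
                                               for n in CHANNEL_FREE_PARAMS))
        files = prerun_model_processing(desc, ipv, tmp_path / "ws")
        assert sorted(f.name for f in files) == ["channel.xml", "naf.mod"]
        mod_text = (tmp_path / "ws" / "naf.mod").read_text()
        for value in EIGHT.values():
            assert value in mod_text


def run_entry(entry: str, args: list[str], cwd: Path):
    return subprocess.run([sys.executable, str(payload_path(entry)), *args],
                          cwd=cwd, capture_output=True, text=True)


class TestSineEntryPoint:
    def read_samples(self, run_dir):
        lines = (run_dir / "sine.csv").read_text().splitlines()
        assert lines[0] == "t,value"
        return [tuple(map(float, ln.split(","))) for ln in lines[1:]]

    def test_one_hz_one_second_at_default_rate(self, tmp_path):
        run_entry("sine_entry.py", ["1", "1"], tmp_path)
        assert (tmp_path / "SUCCESS").exists()
        samples = self.read_samples(tmp_path)
        assert len(samples) == 1000
        at_quarter = dict(samples)[0.25]
        assert abs(at_quarter - 1.0) <= 1e-9
        assert (tmp_path / "sine.svg").read_text().startswith("<svg")

    def test_zero_frequency_all_samples_zero(self, tmp_path):
        run_entry("sine_entry.py", ["0", "1"], tmp_path)
        assert all(v == 0.0 for _, v in self.read_samples(tmp_path))

    def test_wrong_arity_writes_fail_sentinel(self, tmp_path):
        proc = run_entry("sine_entry.py", ["1"], tmp_path)
        assert proc.returncode != 0
        assert (tmp_path / "FAIL").read_text().strip() == "arity"
        assert not (tmp_path / "SUCCESS").exists()


class TestDownloadAndReset:
    def test_download_collision_same_second_distinct_dirs(
            self, machine, sine_desc, tmp_path, frozen_clock):
        t = LocalTransport()
        inst = construct_simulator(sine_desc, machine, t, slot=1)
        Path(inst.run_dir, "out.txt").write_text("x")
        session_dir = tmp_path / "session"
        dirs = []
        for sim_id in ("a", "b"):
            sim = Simulation(ipv=InputParameterVector(sim_id))
            dirs.append(download_results(inst, sim, t, session_dir,
                                         clock=frozen_clock))
        assert dirs[0] != dirs[1]
        # same sim finishing twice in the same second also stays unique
        sim = Simulation(ipv=InputParameterVector("a"))
        again = download_results(inst, sim, t, session_dir,
                                 clock=frozen_clock)
        assert again != dirs[0] and again.name.startswith("a_")

    def test_download_copies_all_run_files(self, machine, sine_desc,
                                           tmp_path):
        t = LocalTransport()
        inst = construct_simulator(sine_desc, machine, t, slot=1)
        for name in ("r.csv", "SUCCESS", "stdout.txt"):
            Path(inst.run_dir, name).write_text(name)
        sim = Simulation(ipv=InputParameterVector("a"))
        rd = download_results(inst, sim, t, tmp_path / "session")
        assert sorted(p.name for p in rd.iterdir()) == \
            ["SUCCESS", "r.csv", "stdout.txt"]
        assert sim.result_dir == str(rd)

    def test_reset_empties_run_dir_keeps_install(self, machine, sine_desc):
        t = LocalTransport()
        inst = construct_simulator(sine_desc, machine, t, slot=1)
        Path(inst.run_dir, "junk.txt").write_text("x")
        inst.state = SimulatorState.BUSY
        reset_simulator(inst, t)
        assert inst.state is SimulatorState.AVAILABLE
        assert list(Path(inst.run_dir).iterdir()) == []
        assert (Path(inst.install_dir) / "sine_entry.py").is_file()
        reset_simulator(inst, t)  # idempotent
        assert inst.state is SimulatorState.AVAILABLE

    def test_reset_retired_instance_rejected(self, machine, sine_desc):
        t = LocalTransport()
        inst = construct_simulator(sine_desc, machine, t, slot=1)
        inst.state = SimulatorState.RETIRED
        with pytest.raises(ValueError, match="retired"):
            reset_simulator(inst, t)


class TestRunCommand:
    def test_quotes_params(self, machine, sine_desc):
        inst = construct_simulator(sine_desc, machine, LocalTransport(),
                                   slot=1)
        cmd = build_run_command(inst, InputParameterVector("a", ("1", "a b")))
        assert cmd.endswith("1 'a b'")
        assert "sine_entry.py" in cmd
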
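"""Schema round-trips, SBML export, reporting, and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from inteinctrl import (
    PRESET_IDS,
    SchemaError,
    build_preset,
    build_regulated,
    export_sbml,
    load_network,
    network_to_dict,
    report,
    rpa_verdict,
    save_network,
    setpoint_sweep,
    simulate_to_steady,
    validate_rules,
)
from inteinctrl.cli import main as cli_main

SBML_NS = "{http://www.sbml.org/sbml/level3/version2/core}"
MATHML_NS = "{http://www.w3.org/1998/Math/MathML}"


@pytest.mark.parametrize("fmt", ["yaml", "json"])
@pytest.mark.parametrize("pid", PRESET_IDS)
def test_schema_round_trip(pid, fmt, tmp_path):
    net = build_preset(pid).network
    reg = build_regulated(2)
    path = tmp_path / f"{pid}.{fmt}"
    save_network(net, path, regulated=reg)
    net2, reg2 = load_network(path)
    assert network_to_dict(net, reg) == network_to_dict(net2, reg2)
    assert validate_rules(net2).theorem1_eligible


def test_schema_version_checked(tmp_path):
    doc = network_to_dict(build_preset("zf").network)
    doc["schema_version"] = 99
    p = tmp_path / "m.yaml"
    p.write_text(yaml.safe_dump(doc))
    with pytest.raises(SchemaError, match="schema_version"):
        load_network(p)


def test_negative_rate_rejected(tmp_path):
    doc = network_to_dict(build_preset("zf").network)
    doc["reactions"][0]["rates"]["eta"] = -1.0
    p = tmp_path / "m.yaml"
    p.write_text(yaml.safe_dump(doc))
    with pytest.raises(SchemaError):
        load_network(p)


def test_duplicate_species_rejected(tmp_path):
    doc = network_to_dict(build_preset("zf").network)
    doc["species"].append(dict(doc["species"][0]))
    doc["mu"].append(0.0)
    doc["theta"].append(0.0)
    p = tmp_path / "m.yaml"
    p.write_text(yaml.safe_dump(doc))
    with pytest.raises(SchemaError, match="unique"):
        load_network(p)


def test_unknown_reaction_type_rejected(tmp_path):
    doc = network_to_dict(build_preset("zf").network)
    doc["reactions"][0]["rtype"] = "wormhole"
    p = tmp_path / "m.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(SchemaError):
        load_network(p)


# -- SBML ------------------------------------------------------------------


def test_sbml_export_structure(tmp_path):
    """Export re-parsed by an independent XML stack carries all species and
    one kinetic law per reaction."""
    from lxml import etree

    net = build_preset("aif").network
    reg = build_regulated(1)
    path = tmp_path / "aif.xml"
    export_sbml(net, reg, path)
    root = etree.parse(str(path)).getroot()
    assert root.tag == SBML_NS + "sbml"
    species = root.findall(f".//{SBML_NS}species")
    assert len(species) == net.M + reg.L  # 2 controller + 1 plant
    reactions = root.findall(f".//{SBML_NS}reaction")
    assert len(reactions) >= 4
    for r in reactions:
        assert r.findall(f".//{SBML_NS}kineticLaw")
        assert r.findall(f".//{MATHML_NS}math")


@pytest.mark.parametrize("pid", ["zf", "tetr", "inactive_intein"])
def test_sbml_round_trip_species_count(pid, tmp_path):
    from lxml import etree

    net = build_preset(pid).network
    reg = build_regulated(2)
    path = tmp_path / "m.xml"
    export_sbml(net, reg, path)
    root = etree.parse(str(path)).getroot()
    ids = [s.get("id") for s in root.findall(f".//{SBML_NS}species")]
    assert ids == net.species_names + ["X1", "X2"]


# -- reporting -------------------------------------------------------------


def test_report_empty_input():
    text, payload = report({})
    assert text == "" and payload == {}


def test_report_single_run_numbers_in_machine_twin(plant1):
    res = simulate_to_steady(build_preset("zf").network, plant1, t_max=2000)
    text, payload = report(res)
    ss = payload["simulation"]["steady_state"]
    assert f"{ss:.6g}" in text
    assert payload["simulation"]["converged"] is True


def test_report_sweep_contains_disturbance_error(plant1):
    df = setpoint_sweep(build_preset("zf").network, plant1, [5.0, 10.0])
    text, payload = report(df)
    assert "disturbance error" in text
    assert payload["sweep"]["disturbance_error"] == df.attrs["disturbance_error"]


def test_report_rule_and_charge(presets):
    obj = {"rules": validate_rules(presets["zf"]), "rpa": rpa_verdict(presets["zf"])}
    text, payload = report(obj)
    assert "setpoint = 10" in text
    assert payload["rpa.charge_report"]["setpoint"] == 10.0


# -- CLI -------------------------------------------------------------------


@pytest.fixture(scope="module")
def zf_model(tmp_path_factory):
    path = tmp_path_factory.mktemp("cli") / "zf.yaml"
    runner = CliRunner()
    res = runner.invoke(cli_main, ["preset", "zf", "--out", str(path)])
    assert res.exit_code == 0, res.output
    return path


def test_cli_check(zf_model):
    runner = CliRunner()
    res = runner.invoke(cli_main, ["check", str(zf_model), "--json"])
    assert res.exit_code == 0, res.output
    payload = json.loads(res.output)
    assert payload["rpa.charge_report"]["setpoint"] == 10.0


def test_cli_reduce(zf_model, tmp_path):
    out = tmp_path / "red.json"
    runner = CliRunner()
    res = runner.invoke(cli_main, ["reduce", str(zf_model), "--out", str(out)])
    assert res.exit_code == 0, res.output
    doc = json.loads(out.read_text())
    assert doc["reducible"] and doc["n_states"] == 3


def test_cli_simulate_and_outputs(zf_model, tmp_path):
    csv = tmp_path / "traj.csv"
    blob = tmp_path / "metrics.json"
    runner = CliRunner()
    res = runner.invoke(
        cli_main,
        ["simulate", str(zf_model), "--t-end", "50", "--out-csv", str(csv), "--out-json", str(blob)],
    )
    assert res.exit_code == 0, res.output
    header = csv.read_text().splitlines()[0]
    assert header.startswith("time,Z1,Z2,Z3,X1")
    doc = json.loads(blob.read_text())
    assert doc["run.simulation"]["converged"]


def test_cli_sweep(zf_model):
    runner = CliRunner()
    res = runner.invoke(cli_main, ["sweep", str(zf_model), "--mu1", "5,10", "--disturb", "2"])
    assert res.exit_code == 0, res.output
    assert "disturbance error" in res.output


def test_cli_ssa(zf_model):
    runner = CliRunner()
    res = runner.invoke(cli_main, ["ssa", str(zf_model), "--seed", "1", "--paths", "2", "--t-end", "30"])
    assert res.exit_code == 0, res.output
    payload = json.loads(res.output)
    assert payload["theoretical_setpoint"] == 10.0


def test_cli_export_sbml(zf_model, tmp_path):
    out = tmp_path / "zf.xml"
    runner = CliRunner()
    res = runner.invoke(cli_main, ["export-sbml", str(zf_model), "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert out.read_text().startswith("<?xml")


def test_cli_check_rejects_invalid_model(tmp_path):
    bad = tmp_path / "bad.yaml"
    doc = network_to_dict(build_preset("zf").network)
    doc["theta"] = [0.0, 0.0, 0.0]
    bad.write_text(yaml.safe_dump(doc))
    runner = CliRunner()
    res = runner.invoke(cli_main, ["check", str(bad)])
    assert res.exit_code == 2
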
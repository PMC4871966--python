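"""Presets, the scenario runner, the random-scenario generator, config
serialization, and the CLI surface."""

import json
import math

import numpy as np
import pytest
from click.testing import CliRunner

import tumordde as td
from tumordde.cli import main as cli_main
from tumordde.config import dump_config, load_config


EXPECTED_PARAMS = {
    # name: (sigma_tilde, schedule kind, lam stats (bar, max, min), x0s)
    "fig2": (0.0, "constant", (4.0, 4.0, 4.0), (2.0,)),
    "fig3": (0.0, "constant", (5.5, 5.5, 5.5), (2.0,)),
    "fig4": (1.0, "sinusoidal", (1.0, 2.0, 0.0), (2.0,)),
    "fig5": (1.0, "sinusoidal", (5.0, 6.0, 4.0), (2.0,)),
    "fig6": (3.0, "sinusoidal", (1.5, 2.5, 0.5), (2.6,)),
    "fig7": (1.5, "sinusoidal", (1.5, 2.5, 0.5), (2.0, 20.0, 50.0)),
    "fig8": (3.0, "sinusoidal", (1.5, 2.5, 0.5), (2.0, 3.0, 5.0)),
}


@pytest.mark.parametrize("name", sorted(EXPECTED_PARAMS))
def test_preset_matches_captioned_configuration(name):
    sc = td.preset(name)
    sigma_tilde, kind, stats, x0s = EXPECTED_PARAMS[name]
    assert sc.params.sigma_inf == 5.0
    assert sc.params.tau == 1.0
    assert sc.params.sigma_tilde == sigma_tilde
    assert sc.schedule.kind == kind
    assert td.lam_stats(sc.schedule) == pytest.approx(stats)
    assert sc.histories == x0s
    if kind == "sinusoidal":
        assert sc.schedule.omega == pytest.approx(2.0 * math.pi)


def test_unknown_preset_lists_choices():
    with pytest.raises(ValueError, match="fig1"):
        td.preset("fig99")


def test_fig1_equilibrium_curve_scenario():
    report = td.run_scenario(td.preset("fig1"))
    assert report["passed"]
    xs = report["curve"]["x_s"]
    assert all(a > b for a, b in zip(xs, xs[1:]))


def test_fig2_scenario_converges_to_stationary_state():
    report = td.run_scenario(td.preset("fig2"), dt=0.02)
    assert report["passed"]
    assert abs(report["final_values"][0] - report["x_s"]) <= 1e-4


def test_fig3_scenario_extinct():
    report = td.run_scenario(td.preset("fig3"), dt=0.02)
    assert report["passed"]
    assert report["final_values"][0] <= 1e-3
    assert report["classification"] == "extinct"


def test_fig8_multi_history_orbit_agreement(tmp_path):
    report = td.run_scenario(td.preset("fig8"), dt=0.02,
                             out_dir=str(tmp_path))
    assert report["passed"]
    assert report["pairwise_orbit_mismatch"] <= 1e-4
    assert (tmp_path / "fig8_orbit.csv").exists()


class TestRandomScenario:
    def test_deterministic(self):
        a = td.random_scenario(123, "persistent")
        b = td.random_scenario(123, "persistent")
        assert a.params == b.params
        assert a.schedule.to_dict() == b.schedule.to_dict()
        assert a.histories == b.histories

    @pytest.mark.parametrize("regime", ["extinct", "persistent",
                                        "indeterminate"])
    def test_regime_inequality_by_construction(self, regime):
        for seed in range(5):
            sc = td.random_scenario(seed, regime)
            thr = sc.params.threshold
            mn, mx = sc.schedule.lam_min, sc.schedule.lam_max
            if regime == "extinct":
                assert mn >= thr
            elif regime == "persistent":
                assert mx < thr
            else:
                assert mn < thr <= mx

    def test_round_trip_through_serialization(self):
        sc = td.random_scenario(7, "indeterminate")
        back = td.ScenarioPreset.from_dict(sc.to_dict())
        assert back.params == sc.params
        ts = np.linspace(0.0, sc.schedule.omega, 64)
        np.testing.assert_array_equal(back.schedule.lam(ts),
                                      sc.schedule.lam(ts))
        assert back.histories == sc.histories

    def test_invalid_regime(self):
        with pytest.raises(ValueError):
            td.random_scenario(0, "chaotic")


def _write_config(path, sc, x0):
    dump_config(path, sc.params, sc.schedule, x0=x0,
                solver_opts={"dt": 0.02, "t_end": 50.0})


def test_config_round_trip(tmp_path):
    sc = td.preset("fig6")
    for fname in ("conf.yaml", "conf.json"):
        path = tmp_path / fname
        _write_config(path, sc, 2.6)
        params, schedule, history, opts = load_config(path)
        assert params == sc.params
        assert schedule.to_dict() == sc.schedule.to_dict()
        assert history.x0(0.0) == 2.6
        assert opts == {"dt": 0.02, "t_end": 50.0}


class TestCli:
    def test_classify_command(self, tmp_path):
        sc = td.preset("fig6")
        conf = tmp_path / "c.yaml"
        _write_config(conf, sc, 2.6)
        result = CliRunner().invoke(cli_main, ["classify", "--config",
                                               str(conf)])
        assert result.exit_code == 0, result.output
        out = json.loads(result.output)
        assert out["regime"] == "indeterminate"
        assert out["conjecture_periodic"] is True

    def test_simulate_and_equilibrium_commands(self, tmp_path):
        sc = td.preset("fig2")
        conf = tmp_path / "c.yaml"
        _write_config(conf, sc, 2.0)
        runner = CliRunner()
        res = runner.invoke(cli_main, ["simulate", "--config", str(conf),
                                       "--out", str(tmp_path / "run")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "run.csv").exists()
        res = runner.invoke(cli_main, ["equilibrium", "--config", str(conf),
                                       "--lam0", "4.0"])
        assert res.exit_code == 0
        out = json.loads(res.output)
        assert out["exists"] is True
        assert out["x_s"] == pytest.approx(8.5156335689, rel=1e-6)

    def test_envelope_command(self, tmp_path):
        sc = td.preset("fig7")
        conf = tmp_path / "c.yaml"
        _write_config(conf, sc, 2.0)
        res = CliRunner().invoke(cli_main, ["envelope", "--config",
                                            str(conf)])
        assert res.exit_code == 0
        out = json.loads(res.output)
        assert out["exists"] and out["x1"] < out["x2"]
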
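"""Scenario presets, synthetic fixtures, sensitivity sweeps, config
round-trip and the CLI surface."""

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import crevsim as cs
from crevsim.cli import main as cli_main
from crevsim.errors import InputError


class TestFixtureGenerator:
    def test_triangle_waveform_algebra(self):
        p = cs.generate_fixture_profile("triangle", period=0.27, amplitude=0.015)
        assert p.c_max == pytest.approx(0.015)
        # inclusive endpoint repeats the peak, so the mean is zero only up
        # to one sample's weight (A / n)
        assert abs(p.heights.mean()) <= 0.015 / p.heights.size + 1e-12
        assert p.heights.min() == pytest.approx(-0.015, rel=1e-2)
        assert p.heights[0] == pytest.approx(0.015)  # peak-first

    def test_sine_waveform_algebra(self):
        p = cs.generate_fixture_profile("sine", period=0.27, amplitude=0.010)
        assert p.c_max == pytest.approx(0.010)
        assert abs(p.heights.mean()) <= 0.010 / p.heights.size + 1e-12

    def test_jittered_kind_is_seed_deterministic(self):
        a = cs.generate_fixture_profile("jittered", seed=7, length=1.0)
        b = cs.generate_fixture_profile("jittered", seed=7, length=1.0)
        c = cs.generate_fixture_profile("jittered", seed=8, length=1.0)
        assert np.array_equal(a.heights, b.heights)
        assert not np.array_equal(a.heights, c.heights)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            cs.generate_fixture_profile("sawtooth")
        with pytest.raises(InputError):
            cs.generate_fixture_profile("triangle", amplitude=0.0)
        with pytest.raises(InputError):
            cs.generate_fixture_profile("triangle", period=-1.0)


class TestPresetRuns:
    @pytest.mark.parametrize(
        "name",
        [
            "Ti6Al4V_NaCl_pH2.3",
            "Ti6Al4V_NaCl_pH5.6",
            "CoCrMo_NaCl_pH2.3",
            "CoCrMo_NaCl_pH5.6",
        ],
    )
    def test_biomedical_alloys_predict_no_crevice_corrosion(self, name):
        sol = cs.run_scenario(cs.get_preset(name))
        assert not sol.sustainable
        assert np.all(sol.zone == "passive")
        assert np.all(sol.potential > sol.material.e_pass)

    def test_fecr_predicts_sustained_crevice_corrosion(self):
        sol = cs.run_scenario(cs.get_preset("FeCr_H2SO4"))
        assert sol.sustainable
        assert sol.e_pass_crossing_mm < sol.e_corr_crossing_mm

    def test_e_out_override_limited_to_characterised_values(self):
        s = cs.get_preset("CoCrMo_NaCl_pH2.3", e_out=-0.1)
        assert s.material.e_out == -0.1
        with pytest.raises(InputError):
            cs.get_preset("CoCrMo_NaCl_pH2.3", e_out=1.2)
        with pytest.raises(InputError):
            cs.get_preset("NoSuchAlloy")

    def test_run_is_deterministic_byte_identical(self, tmp_path):
        paths = []
        for k in range(2):
            sol = cs.run_scenario(cs.get_preset("FeCr_H2SO4"))
            path = tmp_path / f"run{k}.csv"
            sol.to_csv(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]


class TestSweeps:
    def test_smaller_mismatch_angle_raises_drop_everywhere(self):
        base = cs.get_preset("CoCrMo_NaCl_pH2.3")
        result = cs.sweep_mismatch_angle(base, [0.02, 0.01, 0.005])
        drops = [s.material.e_out - s.potential for s in result.solutions]
        assert np.all(drops[1][1:] > drops[0][1:])
        assert np.all(drops[2][1:] > drops[1][1:])
        maxima = [s["max_drop_mV"] for s in result.summaries]
        assert maxima[0] < maxima[1] < maxima[2]

    def test_smoother_surface_raises_drop_everywhere(self):
        base = cs.get_preset("CoCrMo_NaCl_pH2.3")
        result = cs.sweep_roughness_scale(base, [1.0, 0.2])
        drop_rough = base.material.e_out - result.solutions[0].potential
        drop_smooth = base.material.e_out - result.solutions[1].potential
        assert np.all(drop_smooth[1:] > drop_rough[1:])

    def test_unit_scale_reproduces_base_run(self):
        base = cs.get_preset("CoCrMo_NaCl_pH2.3")
        result = cs.sweep_roughness_scale(base, [1.0])
        ref = cs.run_scenario(base)
        assert np.allclose(result.solutions[0].potential, ref.potential, atol=1e-15)

    def test_single_angle_equals_run_scenario(self):
        base = cs.get_preset("CoCrMo_NaCl_pH2.3")
        result = cs.sweep_mismatch_angle(base, [0.02])
        ref = cs.run_scenario(base)
        assert np.array_equal(result.solutions[0].potential, ref.potential)

    def test_invalid_sweep_values_rejected(self):
        base = cs.get_preset("CoCrMo_NaCl_pH2.3")
        with pytest.raises(InputError):
            cs.sweep_mismatch_angle(base, [0.02, 0.02])
        with pytest.raises(InputError):
            cs.sweep_mismatch_angle(base, [0.02, -0.01])
        with pytest.raises(InputError):
            cs.sweep_roughness_scale(base, [0.0])

    def test_sweep_table_preserves_order(self):
        base = cs.get_preset("CoCrMo_NaCl_pH2.3")
        result = cs.sweep_mismatch_angle(base, [0.02, 0.005, 0.01])
        df = result.to_dataframe()
        assert list(df["alpha_deg"]) == [0.02, 0.005, 0.01]


class TestConfigRoundTrip:
    @pytest.mark.parametrize("name", sorted(cs.SCENARIO_PRESETS))
    def test_presets_round_trip_losslessly(self, name, tmp_path):
        scenario = cs.get_preset(name)
        path = tmp_path / "scenario.yaml"
        cs.save_scenario(scenario, path)
        loaded = cs.load_scenario(path)
        assert loaded == scenario

    def test_resistivity_override_key(self, tmp_path):
        config = yaml.safe_load(
            """
label: custom
geometry: {alpha_deg: 0.02}
profile: {kind: triangle}
electrolyte: {resistivity_ohm_mm: 350.0, ph: 1.5}
material: {name: FeCr, e_pass_V: -0.37, i_pass_mA_cm2: 1.8, e_corr_V: -0.5, e_out_V: 0.5}
"""
        )
        scenario = cs.scenarios.scenario_from_config(config)
        assert scenario.electrolyte.rho == pytest.approx(350.0)

    def test_missing_key_reported(self):
        with pytest.raises(InputError):
            cs.scenarios.scenario_from_config({"label": "x"})


class TestProfileFileInput:
    def test_profile_file_feeds_the_pipeline(self, tmp_path):
        # a 4-sample period written in micrometres, three noisy repeats
        rng = np.random.default_rng(0)
        period = np.array([12.0, 2.0, -8.0, -2.0])
        trace = np.tile(period, 3) + rng.normal(0, 0.1, 12)
        pos_um = np.arange(12) * 1.0
        lines = ["# units: um", "# period_mm: 0.004"]
        lines += [f"{p:.6f} {h:.6f}" for p, h in zip(pos_um, trace)]
        path = tmp_path / "profile.txt"
        path.write_text("\n".join(lines) + "\n")

        profile = cs.read_profile(path)
        assert profile.period == pytest.approx(0.004)
        assert profile.dx == pytest.approx(1e-3)

        geometry = cs.CreviceGeometry(alpha_deg=0.02, length=1.0)
        spec = cs.ProfileSpec(kind="file", path=str(path), period_mm=0.004)
        scenario = cs.Scenario(
            label="file_case",
            geometry=geometry,
            profile=spec,
            electrolyte=cs.Electrolyte.from_resistivity(350.0, ph=1.5),
            material=cs.MaterialElectrochem(
                "FeCr", e_pass=-0.37, i_pass=1.8, e_corr=-0.5, e_out=0.5
            ),
        )
        sol = cs.run_scenario(scenario)
        assert sol.x.size == 1001
        assert sol.potential[0] == 0.5

    def test_malformed_rows_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0 1 2\n")
        with pytest.raises(InputError):
            cs.read_profile(path)


class TestCli:
    def test_run_preset_writes_outputs(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["run", "--preset", "Ti6Al4V_NaCl_pH5.6", "--out", str(tmp_path)],
        )
        assert result.exit_code == 0, result.output
        assert "crevice corrosion sustainable: no" in result.output
        assert (tmp_path / "Ti6Al4V_NaCl_pH5.6.csv").exists()
        assert (tmp_path / "Ti6Al4V_NaCl_pH5.6_summary.json").exists()

    def test_faraday_command_prints_worked_numbers(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "faraday",
                "--volume-cm3", "5e-3",
                "--conc-m", "0.1",
                "--current-ma-cm2", "0.5",
                "--area-cm2", "5",
            ],
        )
        assert result.exit_code == 0, result.output
        assert "inventory_mol      5e-07" in result.output
        assert "depletion_time_s   19.2" in result.output  # exact-flux time

    def test_sweep_command_emits_json(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "sweep",
                "--param", "angle",
                "--values", "0.02,0.01",
                "--preset", "CoCrMo_NaCl_pH2.3",
            ],
        )
        assert result.exit_code == 0, result.output
        assert '"alpha_deg"' in result.output

    def test_tafel_command(self, tmp_path):
        e = np.linspace(-0.95, -0.05, 181)
        i = 0.5 * (10 ** ((e + 0.5) / 0.06) - 10 ** (-(e + 0.5) / 0.12))
        path = tmp_path / "curve.txt"
        path.write_text(
            "\n".join(f"{a:.6f} {b:.8g}" for a, b in zip(e, i)) + "\n"
        )
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "tafel",
                "--curve", str(path),
                "--anodic-window", "-0.2,-0.05",
                "--cathodic-window", "-0.95,-0.8",
            ],
        )
        assert result.exit_code == 0, result.output
        assert "e_corr_V           -0.5" in result.output

    def test_run_requires_exactly_one_source(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["run"])
        assert result.exit_code != 0
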
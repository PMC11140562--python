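"""End-to-end experiment runner, report writing, file I/O and CLI."""

import json

import numpy as np
import pytest

import phantomiq as pq
from phantomiq.config import load_config
from phantomiq.experiment import ExperimentConfig, run_experiment, write_report
from phantomiq.io import read_volume, write_truth_geometry, write_volume
from phantomiq.noise import ROISpec
from phantomiq.recon import reference_presets


def small_config(seed=0, presets=("HIR", "DLR")):
    """A reduced-z configuration for fast end-to-end runs."""
    all_presets = reference_presets()
    return ExperimentConfig(
        z_extent_mm=16.0,
        presets={k: all_presets[k] for k in presets},
        repeats=2,
        seed=seed,
        roi=ROISpec((0.0, 0.0, 0.0), (40.0, 40.0, 10.0)),
        esf_z_range=(-6.0, 6.0),
    )


@pytest.fixture(scope="module")
def small_result():
    return run_experiment(small_config())


class TestRunExperiment:
    def test_summary_has_one_entry_per_preset(self, small_result):
        s = small_result.summary()
        assert set(s["presets"]) == {"HIR", "DLR"}
        assert s["dose"]["effective_dose_msv"] == pytest.approx(0.83)

    def test_noise_sd_reaches_preset_target(self, small_result):
        for name, r in small_result.presets.items():
            assert r.noise_sd == pytest.approx(r.preset.noise_sd_target, rel=0.03)

    def test_model_mean_ct_is_average_of_preset_readings(self, small_result):
        means = [r.mean_ct for r in small_result.presets.values()]
        assert small_result.model_mean_ct == pytest.approx(np.mean(means))

    def test_deterministic_under_master_seed(self, tmp_path):
        a = run_experiment(small_config(seed=5, presets=("HIR",)))
        b = run_experiment(small_config(seed=5, presets=("HIR",)))
        pa = tmp_path / "a"
        pb = tmp_path / "b"
        write_report(a, pa, plots=False)
        write_report(b, pb, plots=False)
        assert (pa / "summary.json").read_bytes() == (pb / "summary.json").read_bytes()
        assert (pa / "vessel_profile_metrics.csv").read_bytes() == (
            pb / "vessel_profile_metrics.csv"
        ).read_bytes()

    def test_unknown_vessel_label_rejected_before_compute(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="unknown vessel"):
            ExperimentConfig(
                z_extent_mm=16.0,
                presets=cfg.presets,
                sites=(pq.ProfileSite("no-such-vessel", 8.0),),
                roi=cfg.roi,
            )

    def test_report_files_written(self, small_result, tmp_path):
        written = write_report(small_result, tmp_path, plots=True)
        for key in ("summary", "vessel_table", "lumen_table", "log"):
            assert written[key].exists()
        summary = json.loads(written["summary"].read_text())
        assert "presets" in summary and "model" in summary
        log = json.loads(written["log"].read_text())
        assert log["seed"] == 0
        # every preset has traceable curve CSVs next to the tables
        for name in small_result.presets:
            assert (tmp_path / f"nps_{name}.csv").exists()
            assert (tmp_path / f"mtf_xy_{name}.csv").exists()
            assert (tmp_path / f"profile_normal-3.2_{name}.csv").exists()
        assert (tmp_path / "nps.png").exists()


class TestVolumeIO:
    def test_nifti_round_trip(self, tmp_path, small_grid, rng):
        v = pq.VoxelVolume(rng.normal(0, 30, small_grid.shape).astype(np.float32),
                           small_grid)
        path = write_volume(v, tmp_path / "vol.nii.gz")
        back = read_volume(path)
        assert np.allclose(back.values, v.values)
        assert back.grid.spacing == pytest.approx(v.grid.spacing)
        assert back.grid.origin == pytest.approx(v.grid.origin)

    def test_metaimage_round_trip(self, tmp_path, small_grid, rng):
        v = pq.VoxelVolume(rng.normal(0, 30, small_grid.shape).astype(np.float32),
                           small_grid)
        path = write_volume(v, tmp_path / "vol.mha")
        back = read_volume(path)
        assert np.allclose(back.values, v.values)
        assert back.grid.spacing == pytest.approx(v.grid.spacing)

    def test_unknown_format_rejected(self, tmp_path, small_grid):
        v = pq.VoxelVolume(np.zeros(small_grid.shape, np.float32), small_grid)
        with pytest.raises(ValueError):
            write_volume(v, tmp_path / "vol.npy")

    def test_truth_geometry_json(self, tmp_path, mini_phantom):
        *_, truth = mini_phantom
        path = write_truth_geometry(truth, tmp_path / "truth.json")
        data = json.loads(path.read_text())
        assert data["materials"]["contrast_hu"] == 424.0
        labels = {v["label"] for v in data["vessels"]}
        assert "normal-3.2" in labels
        v = next(x for x in data["vessels"] if x["label"] == "normal-3.2")
        assert v["true_diameter"][0] == pytest.approx(3.2)


class TestConfig:
    def test_defaults(self):
        cfg = load_config(None)
        assert cfg.repeats == 3
        assert set(cfg.presets) == {"HIR", "DLR", "SR-DLR"}
        assert cfg.roi.size == (40.0, 40.0, 25.0)

    def test_toml_overrides(self, tmp_path):
        p = tmp_path / "cfg.toml"
        p.write_text(
            """
            seed = 9
            repeats = 2
            z_extent_mm = 16.0

            [roi]
            center = [0.0, 0.0, 0.0]
            size = [40.0, 40.0, 10.0]

            [dose]
            ctdivol = 5.0

            [[presets]]
            name = "HIR"
            noise_sd_target = 25.0
            """
        )
        cfg = load_config(p)
        assert cfg.seed == 9
        assert cfg.repeats == 2
        assert cfg.presets["HIR"].noise_sd_target == 25.0
        assert cfg.presets["DLR"].noise_sd_target == 19.0
        assert cfg.dose.ctdivol == 5.0
        cfg2 = load_config(p, seed=123)
        assert cfg2.seed == 123

    def test_unknown_preset_rejected(self, tmp_path):
        p = tmp_path / "cfg.toml"
        p.write_text('[[presets]]\nname = "FBP"\n')
        with pytest.raises(ValueError, match="FBP"):
            load_config(p)


class TestCLI:
    def test_measure_noise_command(self, tmp_path, rng):
        from click.testing import CliRunner

        from phantomiq.cli import main

        g = pq.Grid.centered((96, 96, 64), (0.625, 0.625, 0.5))
        paths = []
        for i in range(2):
            v = pq.VoxelVolume(
                (424 + rng.normal(0, 13.1, g.shape)).astype(np.float32), g
            )
            paths.append(str(write_volume(v, tmp_path / f"rep{i}.nii.gz")))
        out = tmp_path / "noise.json"
        res = CliRunner().invoke(
            main, ["measure-noise", *paths, "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        data = json.loads(out.read_text())
        assert data["noise_sd_hu"] == pytest.approx(13.1, rel=0.05)
        assert data["mean_ct_hu"] == pytest.approx(424.0, abs=1.0)

    def test_help(self):
        from click.testing import CliRunner

        from phantomiq.cli import main

        res = CliRunner().invoke(main, ["--help"])
        assert res.exit_code == 0
        for cmd in ("generate-phantom", "emulate", "measure-noise", "measure-mtf",
                    "measure-profile", "report", "run-all"):
            assert cmd in res.output
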
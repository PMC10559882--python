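import json
from dataclasses import replace

import numpy as np
import pytest

from btsforecast.cnn_lstm import CnnLstmSpec
from btsforecast.ensemble import (
    EnsembleWeights,
    PipelineConfig,
    baseline_arima,
    baseline_persistence,
    config_from_yaml,
    fuse_ar_channels,
    learn_weights,
    run_pipeline,
    weighted_fuse,
)
from btsforecast.pso import PsoConfig
from btsforecast.sequence_io import SyntheticSpec


class TestWeightedFuse:
    def test_degenerate_weights(self):
        a, b = np.array([2.0]), np.array([4.0])
        np.testing.assert_array_equal(weighted_fuse(a, b, EnsembleWeights(1.0, 0.0)), a)
        np.testing.assert_array_equal(weighted_fuse(a, b, EnsembleWeights(0.0, 1.0)), b)

    def test_average(self):
        out = weighted_fuse([2.0], [4.0], EnsembleWeights(0.5, 0.5))
        np.testing.assert_array_equal(out, [3.0])

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            weighted_fuse([1.0], [1.0, 2.0], EnsembleWeights(0.5, 0.5))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(-0.1, 1.1)
        with pytest.raises(ValueError):
            EnsembleWeights(0.5, 0.6)


class TestLearnWeights:
    def test_perfect_component_gets_full_weight(self, rng):
        y = rng.uniform(1, 2, 50)
        w = learn_weights(y, y + rng.normal(size=50), y)
        assert w.w_ar == 1.0

    def test_symmetric_bias_splits_evenly(self, rng):
        y = rng.uniform(1, 2, 50)
        w = learn_weights(y + 1.0, y - 1.0, y)
        assert w.w_ar == pytest.approx(0.5)

    def test_fused_mse_not_worse_than_components(self, rng):
        y = rng.uniform(1, 2, 80)
        a = y + rng.normal(size=80) * 0.3
        b = y + rng.normal(size=80) * 0.2
        w = learn_weights(a, b, y)
        fused = weighted_fuse(a, b, w)
        mse = lambda p: float(np.mean((p - y) ** 2))
        assert mse(fused) <= min(mse(a), mse(b)) + 1e-12

    def test_identical_components_warn(self, rng):
        y = rng.uniform(1, 2, 20)
        a = y + 0.1
        with pytest.warns(UserWarning):
            w = learn_weights(a, a.copy(), y)
        assert w.w_ar == 0.5

    def test_mape_criterion(self, rng):
        y = rng.uniform(1, 2, 50)
        w = learn_weights(y, y + 0.5, y, criterion="mape")
        assert w.w_ar == 1.0


def test_fuse_ar_channels_inverse_mape_weighting():
    fc = {"a": np.array([1.0, 1.0]), "b": np.array([3.0, 3.0])}
    # channel a twice as accurate -> weight 2/3
    out = fuse_ar_channels(fc, {"a": 1.0, "b": 2.0})
    np.testing.assert_allclose(out, (2 / 3) * fc["a"] + (1 / 3) * fc["b"])


class TestBaselines:
    def test_persistence_shifts_by_one(self):
        out = baseline_persistence([1.0, 2.0], [3.0, 4.0])
        np.testing.assert_array_equal(out, [2.0, 3.0])

    def test_arima_baseline_runs(self, rng):
        x = np.cumsum(rng.normal(size=130)) * 0.05 + 5
        pred = baseline_arima(x[:100], x[100:])
        assert pred.shape == (30,) and np.isfinite(pred).all()


def fast_config(**kw):
    defaults = dict(
        synthetic=(SyntheticSpec(length=3000, seed=0),),
        seed=0,
        window_len=30,
        arfima_pso=PsoConfig(swarm_size=3, iterations=2),
        arfima_bounds=((0, 2), (-0.3, 0.3), (0, 1)),
        cnn_spec=CnnLstmSpec(n_epochs=30, n_hidden=6, n_kernels=4, kernel_width=2),
        cnn_pso=PsoConfig(swarm_size=3, iterations=2),
        cnn_bounds=((10, 50), (4, 8), (-2.5, -1.0)),
        sapt_patience=2,
        sapt_max_epochs=10,
    )
    defaults.update(kw)
    return PipelineConfig(**defaults)


class TestPipeline:
    @pytest.fixture(scope="class")
    def report(self):
        return run_pipeline(fast_config())

    def test_finite_metrics(self, report):
        rep = next(iter(report["sequences"].values()))
        assert "error" not in rep
        for split in ("validation", "test"):
            assert np.isfinite(rep[split]["mape"]) and np.isfinite(rep[split]["r2"])

    def test_weights_convex(self, report):
        rep = next(iter(report["sequences"].values()))
        w = rep["weights"]
        assert 0 <= w["w_ar"] <= 1 and abs(w["w_ar"] + w["w_lstm"] - 1) < 1e-9

    def test_manifest_records_reproducibility_info(self, report):
        rep = next(iter(report["sequences"].values()))
        assert rep["seed"] == 0
        assert rep["normalization"]["mode"] == "minmax"
        assert rep["cnn_lstm"]["spec"]["n_epochs"] > 0
        assert rep["arfima"]["orders"]

    def test_byte_identical_reports_under_same_seed(self, tmp_path):
        cfg1 = fast_config(outdir=str(tmp_path / "r1"))
        cfg2 = fast_config(outdir=str(tmp_path / "r2"))
        run_pipeline(cfg1)
        run_pipeline(cfg2)
        assert (tmp_path / "r1" / "report.json").read_bytes() == (
            tmp_path / "r2" / "report.json"
        ).read_bytes()
        assert (tmp_path / "r1" / "report.csv").read_text().startswith("sequence,")

    def test_ablation_model_names(self):
        assert fast_config().model_name == "SaPt-CNN-LSTM-AR-EA"
        assert fast_config(disable_ar=True).model_name == "SaPt-CNN-LSTM-EA"
        assert fast_config(disable_sapt=True).model_name == "CNN-LSTM-AR-EA"
        assert fast_config(disable_cnn=True).model_name == "SaPt-LSTM-AR-EA"
        assert fast_config(disable_tuning=True).model_name == "SaPt-CNN-LSTM-AR"

    def test_ar_ablation_runs_lstm_only(self):
        rep = run_pipeline(fast_config(disable_ar=True))
        r = next(iter(rep["sequences"].values()))
        assert r["model"] == "SaPt-CNN-LSTM-EA"
        assert r["weights"] == {"w_ar": 0.0, "w_lstm": 1.0}
        assert r["arfima"] is None

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline(PipelineConfig())


def test_config_yaml_round_trip(tmp_path):
    cfg_yaml = tmp_path / "cfg.yaml"
    cfg_yaml.write_text(
        "synthetic:\n"
        "  - {length: 3000, seed: 1}\n"
        "window_len: 30\n"
        "lookback: 6\n"
        "arfima_pso: {swarm_size: 3, iterations: 2}\n"
        "cnn_spec: {n_epochs: 20, n_hidden: 4, n_kernels: 4}\n"
        "disable_tuning: true\n"
    )
    cfg = config_from_yaml(cfg_yaml)
    assert cfg.window_len == 30 and cfg.lookback == 6
    assert cfg.synthetic[0].length == 3000
    assert cfg.arfima_pso.swarm_size == 3
    assert cfg.cnn_spec.n_epochs == 20
    assert cfg.disable_tuning


def test_cli_synth_and_encode(tmp_path):
    from click.testing import CliRunner

    from btsforecast.cli import main

    runner = CliRunner()
    fa = tmp_path / "s.fa"
    res = runner.invoke(main, ["synth", "--length", "300", "--seed", "3", "--out", str(fa)])
    assert res.exit_code == 0, res.output
    out = tmp_path / "enc.csv"
    res = runner.invoke(main, ["encode", "--fasta", str(fa), "--encoding", "z", "--out", str(out)])
    assert res.exit_code == 0, res.output
    assert out.read_text().count("\n") == 301
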
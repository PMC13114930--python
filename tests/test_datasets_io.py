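"""Dataset containers, delimited-text round trips, and experiment dispatch."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mmib.cli import main as cli_main
from mmib.datasets import LongitudinalDataset, MultimodalDataset
from mmib.io import (
    ExperimentConfig,
    read_multimodal_csv,
    run_experiment,
    write_multimodal_csv,
)


@pytest.fixture()
def toy_dataset(rng):
    return MultimodalDataset(
        {"a": rng.standard_normal((12, 3)), "b": rng.standard_normal((12, 2))},
        labels=np.array([0, 1] * 6),
        metadata={"sample_ids": [f"s{i}" for i in range(12)]},
    )


class TestMultimodalDataset:
    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            MultimodalDataset(
                {"a": rng.standard_normal((5, 2)), "b": rng.standard_normal((4, 2))},
                labels=np.zeros(5, int),
            )

    def test_non_finite_rejected(self):
        x = np.ones((4, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            MultimodalDataset({"a": x}, labels=np.zeros(4, int))

    def test_subset_matrix_order_and_unknown_name(self, toy_dataset):
        m = toy_dataset.subset_matrix(["b", "a"])
        assert m.shape == (12, 5)
        assert np.array_equal(m[:, :2], toy_dataset.modalities["b"])
        with pytest.raises(KeyError):
            toy_dataset.subset_matrix(["c"])

    def test_stratified_split_covers_classes(self, toy_dataset):
        d = toy_dataset.with_split(0.25, seed=0)
        train, test = d.train_test()
        assert set(np.unique(test.labels)) == {0, 1}
        assert train.n_samples + test.n_samples == 12


class TestLongitudinal:
    def test_nonincreasing_visits_rejected(self):
        df = pd.DataFrame(
            {"subject": [0, 0], "visit": [1, 1], "m": [0.0, 1.0], "target": [0.0, 1.0]}
        )
        with pytest.raises(ValueError):
            LongitudinalDataset(df, ["m"])

    def test_pairs_never_cross_subjects(self):
        df = pd.DataFrame(
            {
                "subject": [0, 0, 1, 1],
                "visit": [0, 1, 0, 1],
                "m": [1.0, 2.0, 3.0, 4.0],
                "target": [0.0, 1.0, 0.0, 1.0],
            }
        )
        pairs = LongitudinalDataset(df, ["m"]).consecutive_pairs(["m"])
        assert len(pairs) == 2
        assert pairs["m_lag1"].tolist() == [1.0, 3.0]


class TestCSVRoundTrip:
    def test_write_then_read_identical(self, toy_dataset, tmp_path):
        paths = write_multimodal_csv(toy_dataset, tmp_path)
        data = read_multimodal_csv(
            {"a": paths["a"], "b": paths["b"]}, paths["labels"]
        )
        for name in ("a", "b"):
            assert np.allclose(data.modalities[name], toy_dataset.modalities[name])
        assert np.array_equal(data.labels, toy_dataset.labels)

    def test_missing_id_dropped(self, toy_dataset, tmp_path):
        paths = write_multimodal_csv(toy_dataset, tmp_path)
        df = pd.read_csv(paths["a"]).iloc[1:]  # drop s0 from one modality
        df.to_csv(paths["a"], index=False)
        data = read_multimodal_csv({"a": paths["a"], "b": paths["b"]}, paths["labels"])
        assert data.n_samples == 11
        assert "s0" not in data.metadata["sample_ids"]

    def test_shuffled_rows_join_invariant(self, toy_dataset, tmp_path, rng):
        paths = write_multimodal_csv(toy_dataset, tmp_path)
        df = pd.read_csv(paths["b"]).sample(frac=1.0, random_state=3)
        df.to_csv(paths["b"], index=False)
        data = read_multimodal_csv({"a": paths["a"], "b": paths["b"]}, paths["labels"])
        assert np.allclose(data.modalities["b"], toy_dataset.modalities["b"])

    def test_duplicate_ids_rejected(self, toy_dataset, tmp_path):
        paths = write_multimodal_csv(toy_dataset, tmp_path)
        df = pd.read_csv(paths["a"])
        pd.concat([df, df.iloc[[0]]]).to_csv(paths["a"], index=False)
        with pytest.raises(ValueError):
            read_multimodal_csv({"a": paths["a"]}, paths["labels"])

    def test_empty_intersection_rejected(self, toy_dataset, tmp_path):
        paths = write_multimodal_csv(toy_dataset, tmp_path)
        df = pd.read_csv(paths["a"])
        df.iloc[:, 0] = [f"other{i}" for i in range(len(df))]
        df.to_csv(paths["a"], index=False)
        with pytest.raises(ValueError):
            read_multimodal_csv({"a": paths["a"]}, paths["labels"])


class TestRunExperiment:
    def test_unknown_task_rejected_before_compute(self):
        with pytest.raises(ValueError):
            ExperimentConfig(task="hallucinate")

    def test_simulate_is_byte_identical_across_runs(self, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        for out in (out1, out2):
            run_experiment(
                ExperimentConfig(
                    task="simulate", out_dir=str(out), seed=7,
                    options={"n": 100},
                )
            )
        for f in sorted(out1.glob("*.csv")):
            assert f.read_bytes() == (out2 / f.name).read_bytes()

    def test_decompose_report_schema(self, tmp_path):
        rec = run_experiment(
            ExperimentConfig(
                task="decompose", out_dir=str(tmp_path), seed=0,
                generator="latent_class",
                options={"n": 400, "n_folds": 3, "probe_hidden": 16},
            )
        )
        assert set(rec.tables) == {"subset_mi", "synergy"}
        subsets = set(rec.tables["subset_mi"]["subset"])
        assert {"m1", "m2", "m3", "m1+m2+m3"} <= subsets
        report = json.loads((tmp_path / "report.json").read_text())
        assert report["seeds"]["global"] == 0

    def test_sweep_report_sorted_points(self, tmp_path):
        rec = run_experiment(
            ExperimentConfig(
                task="sweep", out_dir=str(tmp_path), seed=1,
                options={
                    "n": 300, "lambda_grid": [0.1, 0.001],
                    "epochs": 5, "hidden_units": 16, "latent_dim": 4,
                },
            )
        )
        lams = rec.tables["info_plane"]["lam"].tolist()
        assert lams == sorted(lams) and len(lams) == 2

    def test_report_round_trips_exactly(self, tmp_path):
        rec = run_experiment(
            ExperimentConfig(
                task="sweep", out_dir=str(tmp_path), seed=1,
                options={
                    "n": 300, "lambda_grid": [0.01],
                    "epochs": 4, "hidden_units": 16, "latent_dim": 4,
                },
            )
        )
        report = json.loads((tmp_path / "report.json").read_text())
        reread = pd.read_csv(tmp_path / "info_plane.csv")
        for col in reread.columns:
            orig = rec.tables["info_plane"][col].tolist()
            assert np.allclose(reread[col].tolist(), orig, atol=1e-12) or (
                report["tables"]["info_plane"][col] == orig
            )


def test_cli_simulate_smoke(tmp_path):
    runner = CliRunner()
    result = runner.invoke(
        cli_main,
        ["simulate", "--seed", "3", "--out", str(tmp_path), "-o", "n=80"],
    )
    assert result.exit_code == 0, result.output
    assert (tmp_path / "labels.csv").exists()
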
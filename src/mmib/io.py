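"""Readers, writers, and the experiment runner behind the CLI.

Data interchange is plain delimited text: one CSV per modality (first
column = sample id, remaining columns numeric features), one labels CSV,
and long-format CSV for longitudinal records.  Every experiment writes its
result tables as CSV plus a machine-readable ``report.json`` that echoes
the configuration and all seeds used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import LongitudinalDataset, MultimodalDataset

log = logging.getLogger("mmib")

TASKS = (
    "simulate",
    "decompose",
    "sweep",
    "robustness",
    "diagnose",
    "uncertainty",
    "temporal",
)


def read_multimodal_csv(
    paths: dict[str, str | Path], labels_path: str | Path
) -> MultimodalDataset:
    """Load per-modality feature CSVs aligned on sample id.

    Rows are inner-joined on the id column across all files; row order
    follows the labels file.  Dropped ids are logged.
    """
    labels_df = pd.read_csv(labels_path)
    id_col = labels_df.columns[0]
    if labels_df[id_col].duplicated().any():
        raise ValueError("duplicate sample ids in labels file")
    frames = {}
    common = set(labels_df[id_col])
    for name, path in paths.items():
        df = pd.read_csv(path)
        if df.iloc[:, 0].duplicated().any():
            raise ValueError(f"duplicate sample ids in modality {name!r}")
        df = df.set_index(df.columns[0])
        if not all(np.issubdtype(t, np.number) for t in df.dtypes):
            raise ValueError(f"non-numeric feature cells in modality {name!r}")
        frames[name] = df
        common &= set(df.index)
    if not common:
        raise ValueError("empty sample-id intersection across files")
    dropped = sorted(set(labels_df[id_col]) - common)
    if dropped:
        log.info("dropping %d sample ids absent from some modality: %s",
                 len(dropped), dropped[:10])
    labels_df = labels_df[labels_df[id_col].isin(common)]
    order = labels_df[id_col].to_numpy()
    modalities = {name: df.loc[order].to_numpy(dtype=float) for name, df in frames.items()}
    labels_raw = labels_df.iloc[:, 1].to_numpy()
    classes = {c: i for i, c in enumerate(pd.unique(labels_raw))}
    labels = np.array([classes[c] for c in labels_raw])
    split = None
    if "split" in labels_df.columns:
        split = labels_df["split"].astype(str).str.lower().eq("test").to_numpy()
    return MultimodalDataset(
        modalities, labels, split,
        metadata={"sample_ids": list(order), "classes": {str(k): v for k, v in classes.items()}},
    )


def write_multimodal_csv(
    data: MultimodalDataset, out_dir: str | Path, prefix: str = "modality"
) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ids = data.metadata.get("sample_ids", list(range(data.n_samples)))
    written = {}
    for name, x in data.modalities.items():
        df = pd.DataFrame(x, columns=[f"f{j}" for j in range(x.shape[1])])
        df.insert(0, "sample_id", ids)
        p = out_dir / f"{prefix}_{name}.csv"
        df.to_csv(p, index=False)
        written[name] = p
    lab = pd.DataFrame({"sample_id": ids, "label": data.labels})
    if data.split is not None:
        lab["split"] = np.where(data.split, "test", "train")
    lab_path = out_dir / "labels.csv"
    lab.to_csv(lab_path, index=False)
    written["labels"] = lab_path
    return written


def read_longitudinal_csv(
    path: str | Path, modality_columns: list[str], target_column: str = "target"
) -> LongitudinalDataset:
    return LongitudinalDataset(pd.read_csv(path), modality_columns, target_column)


@dataclass
class ExperimentConfig:
    """Flat experiment description consumed by :func:`run_experiment`."""

    task: str
    out_dir: str = "mmib_out"
    seed: int = 0
    generator: str = "latent_class"  # for simulate / generator-backed tasks
    data_paths: dict = field(default_factory=dict)  # modality -> csv path
    labels_path: str | None = None
    options: dict = field(default_factory=dict)  # task-specific knobs

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; choose from {TASKS}")


@dataclass
class ReportRecord:
    task: str
    config: dict
    tables: dict[str, pd.DataFrame]
    seeds: dict
    version: str = __version__

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "task": self.task,
            "config": self.config,
            "seeds": self.seeds,
            "version": self.version,
            "tables": {},
        }
        for name, df in self.tables.items():
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            payload["tables"][name] = df.to_dict(orient="list")
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(payload, indent=2, default=float))
        return report_path


def _load_or_generate(cfg: ExperimentConfig) -> MultimodalDataset:
    from .synthgen import (
        InteractionGenConfig,
        LatentClassGenConfig,
        gen_interaction,
        gen_latent_class,
    )

    if cfg.data_paths:
        if cfg.labels_path is None:
            raise ValueError("labels_path required with data_paths")
        data = read_multimodal_csv(cfg.data_paths, cfg.labels_path)
        if data.split is None:
            data = data.with_split(0.3, seed=cfg.seed)
        return data
    opts = cfg.options
    if cfg.generator == "latent_class":
        return gen_latent_class(
            LatentClassGenConfig(
                n=int(opts.get("n", 2000)), seed=cfg.seed
            )
        )
    if cfg.generator == "interaction":
        data = gen_interaction(
            InteractionGenConfig(
                n=int(opts.get("n", 5000)),
                alpha=float(opts.get("alpha", 0.0)),
                seed=cfg.seed,
            )
        )
        return data.with_split(0.3, seed=cfg.seed)
    raise ValueError(f"unknown generator {cfg.generator!r}")


def run_experiment(cfg: ExperimentConfig) -> ReportRecord:
    """Dispatch to the named task; writes tables + report.json to out_dir."""
    from .vmib import VMIBConfig

    seeds = {"global": cfg.seed}
    tables: dict[str, pd.DataFrame] = {}
    opts = cfg.options
    vmib_kwargs = {
        k: opts[k]
        for k in ("latent_dim", "hidden_units", "epochs", "batch_size",
                  "lambda_compress", "dropout_rate", "learning_rate", "predictor_hidden")
        if k in opts
    }

    if cfg.task == "simulate":
        if cfg.generator == "coupled_ar":
            from .synthgen import CoupledARGenConfig, gen_coupled_ar

            long_data = gen_coupled_ar(CoupledARGenConfig(seed=cfg.seed))
            tables["records"] = long_data.records
        else:
            data = _load_or_generate(cfg)
            write_multimodal_csv(data, cfg.out_dir)
            tables["summary"] = pd.DataFrame(
                {
                    "modality": data.modality_names,
                    "dim": [data.dims[n] for n in data.modality_names],
                    "n_samples": data.n_samples,
                }
            )
    elif cfg.task == "decompose":
        from .mi_estimation import ProbeProtocol, decompose_information

        data = _load_or_generate(cfg)
        protocol = ProbeProtocol(
            n_folds=int(opts.get("n_folds", 5)),
            hidden_units=int(opts.get("probe_hidden", 256)),
        )
        decomp = decompose_information(data, protocol=protocol, seed=cfg.seed)
        tables["subset_mi"] = pd.DataFrame(
            [
                {
                    "subset": "+".join(k),
                    "mi_nats": est.value,
                    "std": est.std,
                    "pct_of_entropy": 100 * est.value / decomp.label_entropy,
                    "estimator": est.estimator,
                }
                for k, est in decomp.subset_mi.items()
            ]
        )
        tables["synergy"] = pd.DataFrame(
            [
                {"pair": f"{a}+{b}", "synergy_nats": s, "redundancy_nats": -s}
                for (a, b), s in decomp.pairwise_synergy.items()
            ]
        )
    elif cfg.task == "sweep":
        from .vmib import information_plane_sweep

        data = _load_or_generate(cfg)
        grid = [float(x) for x in opts.get("lambda_grid", [1e-4, 1e-3, 1e-2, 1e-1, 1.0])]
        points = information_plane_sweep(data, VMIBConfig(seed=cfg.seed, **vmib_kwargs), grid)
        tables["info_plane"] = pd.DataFrame([asdict(p) for p in points])
        seeds["per_lambda"] = {str(p.lam): p.seed for p in points}
    elif cfg.task == "robustness":
        from .mi_estimation import ProbeProtocol, decompose_information
        from .robustness import (
            RobustnessConfig,
            evaluate_ablation_grid,
            train_robust_vmib,
        )

        data = _load_or_generate(cfg)
        protocol = ProbeProtocol(
            n_folds=int(opts.get("n_folds", 5)),
            hidden_units=int(opts.get("probe_hidden", 64)),
        )
        decomp = decompose_information(data, protocol=protocol, seed=cfg.seed)
        rows = []
        for strategy in ("standard", "dropout", "consistency"):
            model = train_robust_vmib(
                data,
                VMIBConfig(seed=cfg.seed, **vmib_kwargs),
                RobustnessConfig(strategy=strategy),
            )
            for r in evaluate_ablation_grid(model, data, decomp):
                rows.append(
                    {
                        "strategy": strategy,
                        "observed": "+".join(r.observed_subset),
                        "imiss_nats": r.imiss,
                        "auc": r.auc,
                        "accuracy": r.accuracy,
                    }
                )
        tables["ablation_grid"] = pd.DataFrame(rows)
    elif cfg.task == "diagnose":
        from .diagnostics import predictive_gap_profile
        from .vmib import train_vmib

        data = _load_or_generate(cfg)

        def factory(d, seed):
            return train_vmib(d, VMIBConfig(seed=seed, **vmib_kwargs))

        seed_list = [cfg.seed + i for i in range(int(opts.get("n_seeds", 3)))]
        profile = predictive_gap_profile(factory, data, seed_list)
        tables["gaps"] = pd.DataFrame(
            [{"modality": m, "gap": g} for m, g in profile.gaps.items()]
        )
        tables["balance"] = pd.DataFrame(
            [{"balance_index": profile.balance, "auc_full": profile.auc_full,
              "n_seeds": profile.n_seeds}]
        )
        seeds["per_model"] = seed_list
    elif cfg.task == "uncertainty":
        from .uncertainty import deferral_curve
        from .vmib import train_vmib

        data = _load_or_generate(cfg)
        model = train_vmib(data, VMIBConfig(seed=cfg.seed, **vmib_kwargs))
        _, test_set = data.train_test()
        curve = deferral_curve(
            model.predict_proba(test_set), test_set.labels, seed=cfg.seed
        )
        tables["deferral"] = pd.DataFrame(
            {
                "coverage": curve.coverages,
                "accuracy_retained": curve.accuracy_retained,
                "accuracy_random": curve.accuracy_random,
                "entropy_threshold": curve.entropy_threshold,
            }
        )
    elif cfg.task == "temporal":
        from .synthgen import CoupledARGenConfig, gen_coupled_ar
        from .temporal import estimate_transfer_entropy, sequential_ladder

        if cfg.data_paths:
            long_data = read_longitudinal_csv(
                list(cfg.data_paths.values())[0],
                opts["modality_columns"],
                opts.get("target_column", "target"),
            )
        else:
            long_data = gen_coupled_ar(CoupledARGenConfig(seed=cfg.seed))
        te_rows = [
            asdict(estimate_transfer_entropy(long_data, m, seed=cfg.seed))
            for m in long_data.modality_columns
        ]
        tables["transfer_entropy"] = pd.DataFrame(te_rows)
        steps = sequential_ladder(long_data, seed=cfg.seed)
        tables["ladder"] = pd.DataFrame(
            [{"features": "+".join(s.features), "auc": s.auc, "auc_std": s.auc_std}
             for s in steps]
        )
    record = ReportRecord(
        task=cfg.task, config=asdict(cfg), tables=tables, seeds=seeds
    )
    record.write(cfg.out_dir)
    return record
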
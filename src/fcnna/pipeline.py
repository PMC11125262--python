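"""Pipeline orchestration: config-driven synth -> preprocess -> (optional
channel selection) -> train -> evaluate, with a run manifest and report
rendering.

A YAML/JSON config drives the stages; every artifact path and resolved
configuration is recorded in a manifest that suffices to re-run the pipeline
deterministically.  All randomness derives from one root seed split per
stage.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attention import CBAMConfig
from .errors import ConfigurationError
from .ga import Chromosome, GAConfig, make_model_fitness, run_ga, top_candidates
from .model import ConvBranchConfig, ModelConfig
from .montage import from_user_indices
from .preprocessing import (FilterSpec, WindowSpec, bandpass_filter,
                            select_channels, window_trialset)
from .synthetic import SyntheticSpec, generate_dataset, load_dataset
from .training import TrainConfig, run_split, within_subject_split, \
    cross_subject_split


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    artifacts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)

    def save(self, path) -> None:
        for name, p in self.artifacts.items():
            if not Path(p).exists():
                raise ConfigurationError(
                    f"artifact {name} missing at manifest write time: {p}")
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))

    @classmethod
    def load(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _versions() -> dict:
    import scipy
    import sklearn
    return {"python": platform.python_version(), "numpy": np.__version__,
            "scipy": scipy.__version__, "sklearn": sklearn.__version__}


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} did not parse to a mapping")
    return cfg


def _model_config(cfg: dict, C: int, T: int, N: int) -> ModelConfig:
    m = cfg.get("model", {})
    def branch(key, default):
        d = dict(default.__dict__)
        d.update(m.get(key, {}))
        return ConvBranchConfig(**d)
    from .model import default_branch_a, default_branch_b
    return ModelConfig(
        C=C, T=T, N=N,
        branch_a=branch("branch_a", default_branch_a()),
        branch_b=branch("branch_b", default_branch_b()),
        cbam=CBAMConfig(**m.get("cbam", {})))


def run_pipeline(config_path, out_dir=None) -> RunManifest:
    """Execute the configured stages in order; returns the saved manifest."""
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("out_dir", "fcnna_run"))
    out.mkdir(parents=True, exist_ok=True)
    root_seed = int(cfg.get("seed", 0))
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(
                       ("synth", "select", "train"),
                       np.random.SeedSequence(root_seed).spawn(3))}
    manifest = RunManifest(config=cfg, seeds=stage_seeds,
                           versions=_versions())
    timings = manifest.timings

    def stage(name):
        timings[name] = {"start": time.time()}
        return name

    def done(name):
        timings[name]["seconds"] = time.time() - timings[name].pop("start")

    # --- data ------------------------------------------------------
    stage("data")
    try:
        if "synth" in cfg:
            spec = SyntheticSpec(**{**cfg["synth"], "seed": stage_seeds["synth"]})
            dataset = generate_dataset(spec)
            cue_onset = spec.cue_onset
        elif "data_dir" in cfg:
            dataset = load_dataset(cfg["data_dir"])
            cue_onset = float(cfg.get("cue_onset", 2.0))
        else:
            raise ConfigurationError("config needs a 'synth' or 'data_dir' "
                                     "section")
    except Exception as exc:
        raise ConfigurationError(f"stage 'data' failed: {exc}") from exc
    done("data")

    # --- preprocessing --------------------------------------------
    stage("preprocess")
    pp = cfg.get("preprocess", {})
    window = WindowSpec(pre_cue=pp.get("pre_cue", 0.5),
                        post_cue=pp.get("post_cue", 4.0))
    filt = FilterSpec(low_hz=pp.get("low_hz", 0.25),
                      high_hz=pp.get("high_hz", 50.0),
                      order=pp.get("order", 3))
    dataset = {k: bandpass_filter(window_trialset(ts, cue_onset, window), filt)
               for k, ts in dataset.items()}
    done("preprocess")

    any_ts = next(iter(dataset.values()))
    n_classes = int(max(ts.labels.max() for ts in dataset.values()))
    train_cfg = TrainConfig(**{**cfg.get("train", {}).get("optimizer", {}),
                               "seed": stage_seeds["train"]})

    # --- channel selection ----------------------------------------
    selection = cfg.get("channel_selection", {})
    chromosome = None
    if selection.get("channels"):
        chromosome = Chromosome(tuple(
            from_user_indices(selection["channels"])))
    elif selection.get("enabled"):
        stage("select")
        ga_cfg = GAConfig(**{**selection.get("ga", {}),
                             "seed": stage_seeds["select"]})
        universe = list(range(any_ts.n_channels))
        test_subject = selection.get(
            "test_subject", sorted({s for s, _ in dataset})[0])
        fit_cfg = TrainConfig(**{**cfg.get("train", {}).get("optimizer", {}),
                                 "epochs": ga_cfg.fitness_epochs,
                                 "seed": stage_seeds["select"]})
        fitness = make_model_fitness(
            dataset, test_subject,
            lambda n_ch: _model_config(cfg, n_ch, any_ts.n_samples, n_classes),
            fit_cfg)
        records = run_ga(fitness, universe, ga_cfg)
        chromosome = top_candidates(records, k=1)[0]
        records_path = out / "ga_records.json"
        records_path.write_text(json.dumps([
            {"channels": r.chromosome.to_user(), "fitness": r.fitness,
             **r.context} for r in records], indent=2))
        manifest.artifacts["ga_records"] = str(records_path)
        done("select")

    if chromosome is not None:
        dataset = {k: select_channels(ts, chromosome)
                   for k, ts in dataset.items()}
        any_ts = next(iter(dataset.values()))

    # --- train + evaluate -----------------------------------------
    stage("train")
    strategy = cfg.get("train", {}).get("strategy", "within")
    subjects = sorted({s for s, _ in dataset})
    reports = {}
    for subj in cfg.get("train", {}).get("subjects", subjects):
        plan = within_subject_split(dataset, subj) if strategy == "within" \
            else cross_subject_split(dataset, subj)
        model_cfg = _model_config(cfg, any_ts.n_channels, any_ts.n_samples,
                                  n_classes)
        _, report, _ = run_split(dataset, plan, model_cfg, train_cfg,
                                 model_seed=stage_seeds["train"])
        reports[subj] = report
    done("train")

    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(
        {str(s): r.to_dict() for s, r in reports.items()}, indent=2))
    manifest.artifacts["metrics"] = str(metrics_path)
    if chromosome is not None:
        chan_path = out / "channels.json"
        chan_path.write_text(json.dumps(
            {"channels": chromosome.to_user(),
             "names": [any_ts.channel_names[i] for i in
                       range(any_ts.n_channels)]}, indent=2))
        manifest.artifacts["channels"] = str(chan_path)
    manifest_path = out / "manifest.json"
    manifest.save(manifest_path)
    return manifest


def render_reports(manifest: RunManifest, out_dir=None, plots=True):
    """Per-subject metric tables (CSV with an AVG row), confusion matrices,
    ROC points and optional PNG plots from a completed manifest."""
    if "metrics" not in manifest.artifacts:
        raise ConfigurationError("manifest lists no 'metrics' artifact")
    metrics_path = Path(manifest.artifacts["metrics"])
    if not metrics_path.exists():
        raise ConfigurationError(f"missing artifact: {metrics_path}")
    out = Path(out_dir or metrics_path.parent)
    out.mkdir(parents=True, exist_ok=True)
    metrics = json.loads(metrics_path.read_text())

    rows = []
    for subj, rep in metrics.items():
        rows.append({
            "subject": subj,
            "accuracy": rep["accuracy"],
            "kappa": rep["kappa"],
            "macro_auc": rep["macro_auc"],
        })
        cm = np.array(rep["confusion"])
        pd.DataFrame(cm).to_csv(out / f"confusion_subject{subj}.csv",
                                index=False)
    table = pd.DataFrame(rows)
    avg = table.drop(columns="subject").mean(numeric_only=True)
    table = pd.concat(
        [table, pd.DataFrame([{"subject": "AVG", **avg.to_dict()}])],
        ignore_index=True)
    table_path = out / "metrics_table.csv"
    table.to_csv(table_path, index=False)
    written = {"metrics_table": str(table_path)}

    if plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for subj, rep in metrics.items():
            fig, ax = plt.subplots(figsize=(4, 3.5))
            ax.imshow(np.array(rep["confusion"]), cmap="Blues")
            ax.set_xlabel("predicted")
            ax.set_ylabel("true")
            ax.set_title(f"subject {subj}")
            fig.tight_layout()
            p = out / f"confusion_subject{subj}.png"
            fig.savefig(p, dpi=100)
            plt.close(fig)
            written[f"confusion_plot_{subj}"] = str(p)
    return written
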
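"""Stage orchestration: run the analysis end-to-end from one config.

A :class:`PipelineConfig` (flat YAML, one section per stage) drives the
stages

    simulate -> metrics -> tensor -> decompose | select | splithalf |
                                     bootstrap | pca | plot

in dependency order.  Every stage writes its artifact into the output
directory and the run manifest records stage configs, seeds and a
SHA-256 content hash per artifact, so a rerun with the same config and
seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import MetricConfig, compute_metric_table
from .parafac import als_fit, max_offdiag_congruence
from .pca import components_needed, pca_on_tensor
from .selection import select_components
from .simulate import (
    Assembly,
    ExperimentSimConfig,
    planted_truth,
    simulate_experiment,
)
from .spike_data import read_dataset, write_dataset
from .tensor import SynchronyTensor, build_tensor, center_tensor, subset_tensor
from .validation import residual_bootstrap, split_half

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("spikefac")

STAGES = (
    "simulate",
    "metrics",
    "tensor",
    "decompose",
    "select",
    "splithalf",
    "bootstrap",
    "pca",
    "plot",
)

_UPSTREAM = {
    "simulate": (),
    "metrics": ("dataset",),
    "tensor": ("metric_table",),
    "decompose": ("tensor",),
    "select": ("tensor",),
    "splithalf": ("tensor",),
    "bootstrap": ("model",),
    "pca": ("tensor",),
    "plot": ("model",),
}


@dataclasses.dataclass
class PipelineConfig:
    """All stage configurations plus the global seed.

    Sections (dicts) are passed to the respective stage; unknown keys
    are rejected when the stage config dataclass is built.
    """

    seed: int = 0
    simulate: dict = dataclasses.field(default_factory=dict)
    metrics: dict = dataclasses.field(default_factory=dict)
    tensor: dict = dataclasses.field(default_factory=dict)
    decompose: dict = dataclasses.field(default_factory=dict)
    select: dict = dataclasses.field(default_factory=dict)
    splithalf: dict = dataclasses.field(default_factory=dict)
    bootstrap: dict = dataclasses.field(default_factory=dict)
    pca: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _hash_tree(path: Path) -> str:
    if path.is_file():
        return _sha256(path)
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(path).as_posix().encode())
            h.update(_sha256(p).encode())
    return h.hexdigest()


def _sim_config(section: dict) -> ExperimentSimConfig:
    section = dict(section)
    if "assemblies" in section and section["assemblies"] is not None:
        section["assemblies"] = tuple(
            Assembly(
                channels=tuple(a["channels"]),
                rate_hz=a["rate_hz"],
                stimulus_weights=tuple(a["stimulus_weights"]),
                phase_multipliers=tuple(a.get("phase_multipliers", (1, 0.3, 1))),
            )
            for a in section["assemblies"]
        )
    for key in ("dead_channels", "epoch_rate_factors", "osc_channels"):
        if key in section and section[key] is not None:
            section[key] = tuple(section[key])
    return ExperimentSimConfig(**section)


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % 2**31


def run_pipeline(
    config: PipelineConfig,
    stages: Sequence[str],
    out_dir: str | Path,
) -> dict[str, Any]:
    """Execute the requested stages in dependency order.

    Returns the manifest (also written to ``out_dir/manifest.json``).
    Stages not requested must have their upstream artifacts already on
    disk in ``out_dir``; a missing artifact raises with its name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]  # dependency order

    paths = {
        "dataset": out / "dataset",
        "truth": out / "truth.json",
        "metric_table": out / "metrics.tsv",
        "tensor": out / "tensor",
        "model": out / "model",
        "select": out / "selection.tsv",
        "splithalf": out / "splithalf.tsv",
        "bootstrap": out / "bootstrap.tsv",
        "pca": out / "pca.tsv",
        "plot": out / "loadings.png",
    }
    artifacts: dict[str, str] = {}
    decisions = {
        "bin_convention": "half-open [k*delta,(k+1)*delta), 0-based",
        "jitter_kernel": "homogeneous, binned resolution, zero-padded edges",
        "oscsync_band_bins": "round(f*N*delta), conjugate bins included",
        "centering": "sequential single-mode centering; no scaling",
        "normalization": "unit-norm B/C columns, sign-fixed, ordered by ||a_f||",
    }

    def require(name: str) -> Path:
        p = paths[name]
        if not p.exists():
            raise FileNotFoundError(
                f"missing upstream artifact {name!r} (expected at {p}); "
                "run the producing stage first"
            )
        return p

    for stage in stages:
        log.info("running stage %s", stage)
        seed = _stage_seed(config.seed, stage)
        if stage == "simulate":
            cfg = _sim_config(config.simulate)
            dataset = simulate_experiment(cfg, seed=seed)
            write_dataset(dataset, paths["dataset"])
            paths["truth"].write_text(json.dumps(planted_truth(cfg), indent=1))
            artifacts["dataset"] = _hash_tree(paths["dataset"])
            artifacts["truth"] = _sha256(paths["truth"])
        elif stage == "metrics":
            dataset = read_dataset(require("dataset"))
            section = dict(config.metrics)
            bin_width = section.pop("bin_width", 0.002)
            max_lag = section.pop("max_lag", 50)
            t_jitter = section.pop("t_jitter", 0.006)
            window = section.pop("window", None)
            table = compute_metric_table(
                dataset,
                MetricConfig(**section),
                bin_width=bin_width,
                max_lag=max_lag,
                t_jitter=t_jitter,
                window=tuple(window) if window is not None else None,
            )
            table.to_csv(paths["metric_table"], sep="\t", index=False,
                         float_format="%.12g")
            artifacts["metric_table"] = _sha256(paths["metric_table"])
        elif stage == "tensor":
            table = pd.read_csv(require("metric_table"), sep="\t",
                                dtype={"pair": str})
            section = dict(config.tensor)
            metric = section.pop("metric", "kappa_sync")
            modes = tuple(section.pop("center_modes", (1, 2, 3)))
            pair_subset = section.pop("pairs", None)
            if section:
                raise ValueError(f"unknown tensor options: {sorted(section)}")
            t = build_tensor(table, metric=metric)
            if pair_subset is not None:
                t = subset_tensor(t, list(pair_subset))
            if modes:
                t = center_tensor(t, modes)
            t.save(paths["tensor"])
            artifacts["tensor"] = _hash_tree(paths["tensor"])
        elif stage == "decompose":
            t = SynchronyTensor.load(require("tensor"))
            section = dict(config.decompose)
            F = section.pop("n_components", 3)
            model = als_fit(t, F, seed=seed, **section)
            _write_model(model, t, paths["model"])
            artifacts["model"] = _hash_tree(paths["model"])
        elif stage == "select":
            t = SynchronyTensor.load(require("tensor"))
            report = select_components(t, seed=seed, **config.select)
            report.to_frame().to_csv(paths["select"], sep="\t", index=False)
            artifacts["select"] = _sha256(paths["select"])
            decisions["selection_rationale"] = report.rationale
        elif stage == "splithalf":
            t = SynchronyTensor.load(require("tensor"))
            section = dict(config.splithalf)
            F = section.pop("n_components", 3)
            res = split_half(t, F, seed=seed, **section)
            pd.DataFrame(
                {
                    "component": np.arange(1, F + 1),
                    "matched_component": res.permutation + 1,
                    "congruence": res.component_scores,
                }
            ).to_csv(paths["splithalf"], sep="\t", index=False)
            artifacts["splithalf"] = _sha256(paths["splithalf"])
            decisions["splithalf_explained_variance_pct"] = [
                res.explained_variance_odd,
                res.explained_variance_even,
            ]
        elif stage == "bootstrap":
            t = SynchronyTensor.load(require("tensor"))
            model = _read_model(require("model"))
            section = dict(config.bootstrap)
            res = residual_bootstrap(t, model, seed=seed, **section)
            pd.DataFrame(
                {
                    "replicate": np.arange(1, res.scores_empirical.size + 1),
                    "score_empirical": res.scores_empirical,
                    "score_gaussian": res.scores_gaussian,
                }
            ).to_csv(paths["bootstrap"], sep="\t", index=False)
            artifacts["bootstrap"] = _sha256(paths["bootstrap"])
        elif stage == "pca":
            t = SynchronyTensor.load(require("tensor"))
            section = dict(config.pca)
            mode = section.pop("mode", 3)
            threshold = section.pop("threshold_pct", 70.0)
            if section:
                raise ValueError(f"unknown pca options: {sorted(section)}")
            model = pca_on_tensor(t, mode=mode)
            pd.DataFrame(
                {
                    "component": np.arange(1, model.rank + 1),
                    "variance_pct": model.explained_variance_pct,
                    "cumulative_pct": model.cumulative_variance_pct,
                }
            ).to_csv(paths["pca"], sep="\t", index=False)
            artifacts["pca"] = _sha256(paths["pca"])
            decisions["pca_components_for_threshold"] = components_needed(
                model, threshold
            )
        elif stage == "plot":
            from .plotting import plot_loadings

            model = _read_model(require("model"))
            fig = plot_loadings(model)
            fig.savefig(paths["plot"], dpi=120)
            artifacts["plot"] = _sha256(paths["plot"])

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(stages),
        "config": dataclasses.asdict(config),
        "artifacts": artifacts,
        "decisions": decisions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _write_model(model, tensor: SynchronyTensor, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for attr, labels, name in (
        ("A", tensor.pairs, "pair"),
        ("B", tensor.stimuli, "stimulus"),
        ("C", tensor.repetitions, "repetition"),
    ):
        M = getattr(model, attr)
        df = pd.DataFrame(
            M, columns=[f"component_{f + 1}" for f in range(M.shape[1])]
        )
        df.insert(0, name, list(labels))
        df.to_csv(path / f"loadings_{name}.tsv", sep="\t", index=False,
                  float_format="%.12g")
    (path / "model.json").write_text(
        json.dumps(
            {
                "n_components": model.n_components,
                "explained_variance_pct": model.explained_variance_pct,
                "iterations": model.iterations,
                "converged": bool(model.converged),
                "seed": model.seed,
                "max_offdiag_congruence": max_offdiag_congruence(model),
            },
            indent=1,
        )
    )


def _read_model(path: Path):
    from .parafac import ParafacModel

    meta = json.loads((path / "model.json").read_text())
    mats = {}
    for name, attr in (("pair", "A"), ("stimulus", "B"), ("repetition", "C")):
        df = pd.read_csv(path / f"loadings_{name}.tsv", sep="\t")
        mats[attr] = df.iloc[:, 1:].to_numpy(float)
    model = ParafacModel(
        mats["A"], mats["B"], mats["C"], meta["n_components"],
        explained_variance_pct=meta["explained_variance_pct"],
        iterations=meta["iterations"], converged=meta["converged"],
        seed=meta["seed"],
    )
    return model
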
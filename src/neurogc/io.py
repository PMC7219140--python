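"""File formats, run configuration and the reproducible-run orchestrator.

Text formats
------------
* series CSV/TSV — header row of channel labels, one row per time sample.
* ``.npz`` — the binary twin: arrays ``series`` (channels×samples),
  ``labels`` and optionally ``fs``.
* truth TSV — columns source, target, lag, form, coefficient (1-based
  channels; negative lag marks a forward dependency).
* matrix CSV — labeled square GC matrix, row = source, column = target.
* edges TSV — columns source, target, score, null_q, detected.

``run_experiment`` executes the simulate → estimate → detect chain for a
grid of models × estimators and writes a manifest (config, seeds,
versions, outputs) from which every output is re-derivable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gc_core import (
    DetectionConfig,
    DetectionResult,
    GCConfig,
    GCMatrix,
    detect_edges,
    estimate,
)
from .neural_models import PredictorConfig
from .simulators import DependencySpec, NoiseSpec, SimulatedDataset, StreamPolicy, simulate

__all__ = [
    "read_series",
    "write_series",
    "write_truth",
    "read_truth",
    "write_matrix",
    "read_matrix",
    "write_edges",
    "RunConfig",
    "run_experiment",
    "stage_seed",
]


# --------------------------------------------------------------------------
# series I/O
# --------------------------------------------------------------------------

def read_series(path: str | Path, fs: float | None = None):
    """Load a channels×samples matrix with labels.

    CSV/TSV files carry a header row of channel labels and one row per time
    sample; ``.npz`` files carry ``series``/``labels``/``fs`` arrays.
    Ragged or non-numeric rows raise ``ValueError`` naming the offending
    line.

    Returns ``(series, labels, fs)``; ``fs`` is None unless given or stored.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            series = np.asarray(z["series"], dtype=float)
            labels = [str(x) for x in z["labels"]]
            fs_file = float(z["fs"]) if "fs" in z.files else None
        return series, labels, fs if fs is not None else fs_file
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    labels = [c.strip() for c in lines[0].split(sep)]
    if any(_is_number(c) for c in labels):
        raise ValueError(f"{path}: missing header row of channel labels")
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if len(cells) != len(labels):
            raise ValueError(
                f"{path}: ragged row at line {ln} "
                f"({len(cells)} cells, expected {len(labels)})"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric cell at line {ln}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float).T, labels, fs


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_series(path: str | Path, series: np.ndarray,
                 labels: list[str], fs: float | None = None) -> None:
    """Write a channels×samples matrix (format chosen by extension)."""
    path = Path(path)
    series = np.asarray(series, dtype=float)
    if series.shape[0] != len(labels):
        raise ValueError("label count does not match channel count")
    if path.suffix == ".npz":
        payload = {"series": series, "labels": np.array(labels)}
        if fs is not None:
            payload["fs"] = np.float64(fs)
        np.savez(path, **payload)
        return
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    df = pd.DataFrame(series.T, columns=labels)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_truth(path: str | Path, dataset: SimulatedDataset) -> None:
    """Ground-truth dependency table (1-based channels)."""
    rows = sorted(dataset.ground_truth)
    df = pd.DataFrame(
        [{"source": d.source, "target": d.target, "lag": d.lag,
          "form": d.form, "coefficient": d.coefficient} for d in rows]
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> frozenset[DependencySpec]:
    df = pd.read_csv(path, sep="\t")
    return frozenset(
        DependencySpec(int(r.source), int(r.target), int(r.lag),
                       str(r.form), float(r.coefficient))
        for r in df.itertuples()
    )


def write_matrix(path: str | Path, matrix: GCMatrix) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.channel_labels,
                      columns=matrix.channel_labels)
    df.to_csv(path, float_format="%.8g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_edges(path: str | Path, det: DetectionResult) -> None:
    labels = det.scores.channel_labels
    n = len(labels)
    rows = []
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            rows.append({
                "source": labels[s], "target": labels[t],
                "score": det.scores.values[s, t],
                "null_q": det.null_quantiles[s, t],
                "detected": (s + 1, t + 1) in det.edges,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

def _from_dict(cls, data: dict):
    """Strict dataclass construction: unknown keys are errors."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"valid keys: {sorted(known)}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if isinstance(value, dict) and ftype in (
            "PredictorConfig", "DetectionConfig", "NoiseSpec",
        ):
            sub = {"PredictorConfig": PredictorConfig,
                   "DetectionConfig": DetectionConfig,
                   "NoiseSpec": NoiseSpec}[ftype]
            value = _from_dict(sub, value)
        kwargs[name] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment grid.

    Round-trips losslessly through YAML; unknown keys in a config file are
    rejected so typos in hyperparameter names cannot pass silently.
    """

    seed: int = 0
    out_dir: str = "runs/experiment"
    models: list[str] = field(default_factory=lambda: ["A", "B", "C"])
    estimators: list[str] = field(default_factory=lambda: ["bilstm_gc", "rnn_gc", "nn_gc"])
    length: int | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    input_path: str | None = None  # real-recording mode: skip the simulators
    fs: float | None = None
    model_order: int = 5
    model_order_c: int = 7  # lag window of the flattened-input engines, model C
    n_trials: int = 10
    restriction: str | None = None
    holdout_fraction: float = 0.2
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    detect: bool = True
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if not self.estimators:
            raise ValueError("estimators list must not be empty")
        if not self.models and self.input_path is None:
            raise ValueError("need either models to simulate or an input_path")

    def gc_config(self, model_id: str, estimator: str) -> GCConfig:
        order = self.model_order_c if model_id == "C" else self.model_order
        return GCConfig(
            estimator=estimator, model_order=order,
            predictor=self.predictor, n_trials=self.n_trials,
            restriction=self.restriction, detection=self.detection,
            holdout_fraction=self.holdout_fraction,
        )

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise"]["stream_policy"] = self.noise.stream_policy.value
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if isinstance(data.get("noise"), dict):
            noise = dict(data["noise"])
            if "stream_policy" in noise:
                noise["stream_policy"] = StreamPolicy(noise["stream_policy"])
            data["noise"] = _from_dict(NoiseSpec, noise)
        return _from_dict(cls, data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})


def stage_seed(root_seed: int, stage: str) -> int:
    """Named, reproducible substream seed (< 2^31) for one pipeline stage."""
    return int(np.random.SeedSequence(
        [root_seed, zlib.crc32(stage.encode())]
    ).generate_state(1)[0] % (2**31 - 1))


# --------------------------------------------------------------------------
# orchestrator
# --------------------------------------------------------------------------

def run_experiment(config: RunConfig) -> dict:
    """Execute the configured simulate → estimate → detect grid.

    Writes, per (model, estimator): the averaged GC matrix and (optionally)
    the detected edge list; plus the simulated series, ground truth and a
    ``manifest.json`` carrying the config, its hash, all derived seeds and
    the package version.  Identical config + seed reproduces identical
    outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "neurogc",
        "version": __version__,
        "config": config.to_dict(),
        "seeds": {},
        "outputs": [],
    }
    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()

    if config.input_path is not None:
        series, labels, _ = read_series(config.input_path, fs=config.fs)
        sources = [("input", series, labels)]
    else:
        sources = []
        for model_id in config.models:
            sim_seed = stage_seed(config.seed, f"simulate/{model_id}")
            manifest["seeds"][f"simulate/{model_id}"] = sim_seed
            ds = simulate(model_id, config.length, seed=sim_seed, noise=config.noise)
            spath = out / f"series_{model_id}.csv"
            write_series(spath, ds.series, ds.channel_labels)
            tpath = out / f"truth_{model_id}.tsv"
            write_truth(tpath, ds)
            manifest["outputs"] += [spath.name, tpath.name]
            sources.append((model_id, ds.series, ds.channel_labels))

    for model_id, series, labels in sources:
        for est in config.estimators:
            stage = f"estimate/{model_id}/{est}"
            seed = stage_seed(config.seed, stage)
            manifest["seeds"][stage] = seed
            gc_cfg = config.gc_config(model_id, est)
            try:
                result = estimate(series, gc_cfg, seed=seed, channel_labels=labels)
                mpath = out / f"gc_{model_id}_{est}.csv"
                write_matrix(mpath, result.matrix)
                manifest["outputs"].append(mpath.name)
                if config.detect:
                    dstage = f"detect/{model_id}/{est}"
                    dseed = stage_seed(config.seed, dstage)
                    manifest["seeds"][dstage] = dseed
                    det = detect_edges(None, series, gc_cfg, seed=dseed, result=result)
                    epath = out / f"edges_{model_id}_{est}.tsv"
                    write_edges(epath, det)
                    manifest["outputs"].append(epath.name)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
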
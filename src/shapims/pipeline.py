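"""Configuration-driven orchestration of the discovery workflow.

``run_discovery`` executes the full chain for one class — load (or
generate), label, balance, split, train, evaluate, explain, rank, map,
report — and writes every artifact plus a run log to the output directory.
``run_multiclass`` repeats it one-vs-all for several classes.

The pipeline refuses to write a marker ranking when the classifier's
held-out balanced accuracy falls below a configurable floor (default
0.8): an explanation is only as good as its underlying model, so a weak
model yields a warning artifact instead of a candidate list.

All artifacts are deterministic functions of the config and master seed;
stage seeds are derived via :func:`shapims.model.stage_seeds`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

from . import boosting, phantom as phantom_mod, shap_maps
from .boosting import TrainingConfig
from .ims_data import load_dataset, load_mask, write_dataset, write_mask
from .model import MarkerDiscovery

__all__ = ["PipelineConfig", "QualityFloorError", "run_discovery",
           "run_multiclass"]


class QualityFloorError(RuntimeError):
    """Held-out balanced accuracy below the configured floor."""


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for a discovery run.

    Exactly one of ``dataset_bundle`` (with ``mask_paths``) or
    ``phantom_config`` must be provided. ``class_names`` selects the
    one-vs-all targets (for a phantom, region names).
    """

    class_names: tuple[str, ...]
    dataset_bundle: str | None = None
    mask_paths: tuple[str, ...] = ()
    phantom_config: phantom_mod.PhantomConfig | None = None
    training: TrainingConfig = field(default_factory=TrainingConfig)
    eta: float = 0.5
    pos_fraction: float = 0.25
    test_fraction: float = 0.25
    explanation_scope: str = "all_pixels"
    top_k: int = 10
    direction_threshold: float = 0.3
    quality_floor: float = 0.8
    seed: int = 0
    output_dir: str = "discovery_out"

    def __post_init__(self) -> None:
        if (self.dataset_bundle is None) == (self.phantom_config is None):
            raise ValueError(
                "provide exactly one of dataset_bundle or phantom_config")
        if not self.class_names:
            raise ValueError("at least one class name is required")
        for f in ("eta", "pos_fraction", "test_fraction"):
            v = getattr(self, f)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{f} must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path, *, seed: int | None = None,
                  output_dir: str | None = None) -> "PipelineConfig":
        """Read the flat ``key = value`` config file format.

        Training keys use a ``train.`` prefix (e.g. ``train.n_trees``);
        ``phantom`` points at a phantom config file; ``masks`` and
        ``classes`` are comma-separated.
        """
        path = Path(path)
        kv: dict[str, str] = {}
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            kv[key] = val

        train_kwargs = {}
        for f in dc_fields(TrainingConfig):
            key = f"train.{f.name}"
            if key in kv:
                caster = float if f.type == "float" else int
                train_kwargs[f.name] = caster(kv.pop(key))

        pc = None
        if "phantom" in kv:
            ph_path = kv.pop("phantom")
            if not Path(ph_path).is_absolute():
                ph_path = path.parent / ph_path
            pc = phantom_mod.config_from_text(Path(ph_path).read_text())

        def split_list(key):
            return tuple(s.strip() for s in kv.pop(key, "").split(",")
                         if s.strip())

        kwargs: dict = {
            "class_names": split_list("classes"),
            "dataset_bundle": kv.pop("dataset", None),
            "mask_paths": split_list("masks"),
            "phantom_config": pc,
            "training": TrainingConfig(**train_kwargs),
        }
        for f in ("eta", "pos_fraction", "test_fraction",
                  "direction_threshold", "quality_floor"):
            if f in kv:
                kwargs[f] = float(kv.pop(f))
        for f in ("top_k", "seed"):
            if f in kv:
                kwargs[f] = int(kv.pop(f))
        for f in ("explanation_scope", "output_dir"):
            if f in kv:
                kwargs[f] = kv.pop(f)
        if kv:
            raise ValueError(f"unknown config keys: {sorted(kv)}")
        if seed is not None:
            kwargs["seed"] = seed
        if output_dir is not None:
            kwargs["output_dir"] = output_dir
        return cls(**kwargs)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _load_inputs(cfg: PipelineConfig):
    """Resolve dataset + per-class masks from bundle or phantom."""
    if cfg.phantom_config is not None:
        ds, masks, gt = phantom_mod.generate_phantom(cfg.phantom_config)
        return ds, masks, gt
    ds = load_dataset(cfg.dataset_bundle)
    masks = {}
    for mp in cfg.mask_paths:
        mask = load_mask(mp, ds)
        masks[mask.class_name] = mask
    return ds, masks, None


def run_discovery(cfg: PipelineConfig,
                  class_name: str | None = None) -> dict:
    """Execute the full discovery chain for one class; return a manifest."""
    class_name = class_name or cfg.class_names[0]
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        ds, masks, _ = _load_inputs(cfg)
        if class_name not in masks:
            raise KeyError(f"no mask for class {class_name!r}")
    except Exception as exc:
        raise type(exc)(f"[load] {exc}") from exc

    model = MarkerDiscovery(
        ds, masks[class_name], training_config=cfg.training, eta=cfg.eta,
        pos_fraction=cfg.pos_fraction, test_fraction=cfg.test_fraction,
        explanation_scope=cfg.explanation_scope,
        direction_threshold=cfg.direction_threshold,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(seed=cfg.seed)

    manifest: dict = {"class": class_name, "seed": cfg.seed,
                      "output_dir": str(outdir), "files": {}}
    metrics_path = outdir / "metrics.json"
    _json_dump(res.metrics.to_dict(), metrics_path)
    manifest["files"]["metrics"] = str(metrics_path)

    log = {
        "class": class_name,
        "dataset": {"name": ds.name, "n_pixels": ds.n_pixels,
                    "n_features": ds.n_features},
        "n_train": len(res.train), "n_test": len(res.test),
        "train_pos_fraction": res.train.n_pos / len(res.train),
        "master_seed": cfg.seed,
        "training": {f.name: getattr(cfg.training, f.name)
                     for f in dc_fields(TrainingConfig)},
        "eta": cfg.eta, "pos_fraction": cfg.pos_fraction,
        "test_fraction": cfg.test_fraction,
        "explanation_scope": cfg.explanation_scope,
        "direction_threshold": cfg.direction_threshold,
        "quality_floor": cfg.quality_floor,
        "top_k": cfg.top_k,
    }
    _json_dump(log, outdir / "run_log.json")
    manifest["files"]["run_log"] = str(outdir / "run_log.json")

    pred_path = outdir / "prediction_map.png"
    shap_maps.render_diverging(res.prediction_image(), pred_path)
    manifest["files"]["prediction_map"] = str(pred_path)

    ba = res.metrics.balanced_accuracy
    if ba is None or ba < cfg.quality_floor:
        warn_path = outdir / "quality_warning.json"
        _json_dump({
            "balanced_accuracy": ba,
            "quality_floor": cfg.quality_floor,
            "message": "held-out balanced accuracy below the quality floor;"
                       " marker ranking withheld because an explanation is"
                       " only as good as its underlying model",
        }, warn_path)
        manifest["files"]["quality_warning"] = str(warn_path)
        manifest["status"] = "quality_floor_not_met"
        _json_dump(manifest, outdir / "manifest.json")
        return manifest

    manifest["files"]["ranking"] = str(res.ranking.to_csv(outdir / "ranking.csv"))
    manifest["files"]["shapley_matrix"] = str(
        res.shapley_matrix.to_csv(outdir / "shapley_matrix.csv"))
    topk = res.report_topk(min(cfg.top_k, ds.n_features), outdir / "topk")
    manifest["files"]["topk_summary"] = topk["summary"]
    manifest["topk"] = topk["rows"]
    manifest["metrics"] = res.metrics.to_dict()
    manifest["local_accuracy_max_deviation"] = res.local_accuracy()[
        "max_deviation"]
    manifest["status"] = "ok"
    _json_dump(manifest, outdir / "manifest.json")
    return manifest


def run_multiclass(cfg: PipelineConfig) -> dict[str, dict]:
    """Independent one-vs-all runs for every configured class."""
    if len(cfg.class_names) < 2:
        raise ValueError("run_multiclass needs at least two classes")
    manifests = {}
    base = Path(cfg.output_dir)
    for name in cfg.class_names:
        sub = PipelineConfig(**{
            **{f.name: getattr(cfg, f.name) for f in dc_fields(PipelineConfig)},
            "output_dir": str(base / name),
        })
        try:
            manifests[name] = run_discovery(sub, class_name=name)
        except Exception as exc:  # isolation: one failure must not corrupt others
            manifests[name] = {"class": name, "status": "error",
                               "error": str(exc)}
    return manifests


def write_phantom_bundle(cfg: phantom_mod.PhantomConfig,
                         outdir: str | Path) -> dict:
    """Generate a phantom and write its bundle, masks and ground truth."""
    outdir = Path(outdir)
    ds, masks, gt = phantom_mod.generate_phantom(cfg)
    write_dataset(ds, outdir)
    files = {"bundle": str(outdir)}
    for name, mask in masks.items():
        files[f"mask_{name}"] = str(write_mask(mask, ds, outdir))
    gt_path = outdir / "ground_truth_markers.csv"
    gt.markers.to_csv(gt_path, index=False)
    files["ground_truth"] = str(gt_path)
    (outdir / "phantom_config.txt").write_text(
        phantom_mod.config_to_text(cfg))
    files["config"] = str(outdir / "phantom_config.txt")
    return files
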
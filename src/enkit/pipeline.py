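"""End-to-end reproducible pipeline and run provenance.

``run_pipeline`` executes simulate → stratified split → paired training
(EnK off/on) → evaluation → Grad-CAM → overlay, placing every artifact
under one run directory together with a manifest sufficient to
re-execute the run exactly.  The manifest is written (status
``running``) before any heavy computation; a failed run leaves it
marked ``failed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .errors import ConfigurationError
from .interpret import default_target_layer, diff_map, gradcam, overlay
from .models import EnKConfig, ModelSpec
from .simulate import generate, preset, save_epochs
from .train_eval import TrainConfig, compare_enk, derive_seed, stratified_split

log = logging.getLogger("enkit.pipeline")

MANIFEST_VERSION = 1


@dataclass
class RunManifest:
    command: str
    config: dict
    seeds: dict
    input_hashes: dict
    package_version: str
    started: str
    outputs: list[str] = field(default_factory=list)
    finished: str = ""
    status: str = "running"
    manifest_version: int = MANIFEST_VERSION

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig, config_path: str | Path | None = None,
                 overwrite: bool = False) -> Path:
    """Execute the full paired with/without-EnK experiment; returns the
    run directory.  Raises on any failure (manifest left ``failed``)."""
    out = Path(cfg.out)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ConfigurationError(
            f"run directory {out} is not empty; pass overwrite=True "
            f"(--overwrite) to reuse it")
    out.mkdir(parents=True, exist_ok=True)

    seeds = {
        "master": cfg.seed,
        "simulate": derive_seed(cfg.seed, "simulate"),
        "split": derive_seed(cfg.seed, "split"),
        "init": derive_seed(cfg.seed, "init"),
    }
    input_hashes = {}
    if config_path is not None and Path(config_path).exists():
        input_hashes[str(config_path)] = _sha256(Path(config_path))
    manifest = RunManifest(
        command=" ".join(sys.argv), config=cfg.model_dump(mode="json"),
        seeds=seeds, input_hashes=input_hashes,
        package_version=__version__, started=_now())
    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)

    try:
        # 1. simulate -----------------------------------------------------
        ds = cfg.dataset
        sspec = preset(ds.preset, seed=seeds["simulate"],
                       n_epochs_per_class=ds.n_epochs_per_class,
                       n_channels=ds.n_channels, n_samples=ds.n_samples)
        es = generate(sspec)
        epochs_path = out / "epochs.h5"
        save_epochs(es, epochs_path)
        log.info("simulated %d epochs (%s)", es.n_epochs, ds.preset)

        # 2. paired training ---------------------------------------------
        tcfg = TrainConfig(
            max_epochs=cfg.train.max_epochs, batch_size=cfg.train.batch_size,
            dropout=cfg.train.dropout, learning_rate=cfg.train.learning_rate,
            patience=cfg.train.patience, split=cfg.train.split, seed=cfg.seed)
        mspec = ModelSpec(
            architecture=cfg.model.architecture, n_channels=es.n_channels,
            n_samples=es.n_samples, n_classes=es.n_classes,
            enk_config=EnKConfig(l=cfg.model.enk.l, m=cfg.model.enk.m,
                                 shared_affine=cfg.model.enk.shared_affine),
            dropout_rate=cfg.train.dropout, scale=cfg.model.scale)
        comparison, models = compare_enk(mspec, es, tcfg, return_models=True)

        for enk, arm in ((False, "off"), (True, "on")):
            rep = comparison.on if enk else comparison.off
            (out / f"report_{arm}.json").write_text(
                json.dumps(rep.to_dict(), indent=2))
            hist = comparison.history_on if enk else comparison.history_off
            hist.to_csv(out / f"history_{arm}.csv")
            models[enk].save(out / f"checkpoint_{arm}")
        (out / "comparison.json").write_text(json.dumps({
            "delta_mse": comparison.delta_mse,
            "delta_f1": comparison.delta_f1,
            "mse": {"off": comparison.off.mse, "on": comparison.on.mse},
            "f1": {"off": comparison.off.f1, "on": comparison.on.f1},
        }, indent=2))
        log.info("EnK off/on F1 %.3f / %.3f, MSE %.3f / %.3f",
                 comparison.off.f1, comparison.on.f1,
                 comparison.off.mse, comparison.on.mse)

        # 3. interpretability --------------------------------------------
        _, _, te = stratified_split(es, tcfg.split, seed=seeds["split"])
        target = cfg.gradcam.target_class
        if cfg.gradcam.epoch_index is not None:
            ei = cfg.gradcam.epoch_index
        else:
            hits = np.flatnonzero(te.labels == target)
            ei = int(hits[0]) if len(hits) else 0
        epoch = te.data[ei]
        ref = f"test[{ei}]"
        maps = {}
        for enk, arm in ((False, "off"), (True, "on")):
            cam = gradcam(models[enk], epoch, target_class=target,
                          target_layer=default_target_layer(models[enk]),
                          input_ref=ref)
            overlay(cam, epoch, out / f"overlay_{arm}.png",
                    sampling_rate=es.sampling_rate,
                    channel_names=es.channel_names)
            maps[arm] = cam
        if maps["on"].heat.shape == maps["off"].heat.shape:
            dm = diff_map(maps["on"], maps["off"])
            np.savez(out / "gradcam_maps.npz", off=maps["off"].heat,
                     on=maps["on"].heat, diff=dm)
        else:  # different target-layer extents; store unpaired maps
            np.savez(out / "gradcam_maps.npz", off=maps["off"].heat,
                     on=maps["on"].heat)

        manifest.outputs = sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
            and p != manifest_path)
        manifest.status = "success"
        manifest.finished = _now()
        manifest.write(manifest_path)
        return out
    except Exception:
        manifest.status = "failed"
        manifest.finished = _now()
        manifest.write(manifest_path)
        raise
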
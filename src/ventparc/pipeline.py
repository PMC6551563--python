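"""Training, prediction and evaluation orchestration.

The training protocol: every epoch the original images are left-right
flipped to double the set, rotate+deform variants are drawn fresh on top
(6N items for N originals at two copies per image), and the network is
optimized over the shuffled list with Adam at batch size one, minimizing the
mean-Dice loss.  Everything is reproducible from the config seed: weight
init, per-epoch augmentation draws, item order and dropout all derive from
it deterministically.

Two shipped presets: ``desk`` (small phantoms, depth-3 network — runs on a
laptop CPU in minutes) and ``paper_scale`` (192x256x192 volumes, depth-4,
150 epochs — requires accelerator-class hardware and is provided as
configuration only).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _autograd as ag
from .augment import AugmentSpec, epoch_augment
from .metrics import evaluate, one_hot
from .network import NetworkSpec, VParNet, build_vparnet, load_checkpoint, save_checkpoint
from .volumes import (BrainMask, IntensityVolume, LabelVolume, crop_to_brain,
                      uncrop)

__all__ = ["TrainConfig", "TrainLog", "train", "predict", "evaluate_cohort",
           "run_ablation", "ABLATION_VARIANTS", "desk_config", "paper_scale_config"]


@dataclass
class TrainConfig:
    """Everything that determines a training run."""

    network: NetworkSpec = field(default_factory=NetworkSpec)
    augment: AugmentSpec = field(default_factory=AugmentSpec)
    step_size: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-7
    epochs: int = 150
    batch_size: int = 1
    loss_epsilon: float = 1e-3
    copies_per_image: int = 2
    augment_enabled: bool = True
    seed: int = 0
    checkpoint_every: int = 0          # 0 = only the final checkpoint
    select_best_validation: bool = False
    loss_includes_background: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if min(self.step_size, self.beta1, self.beta2, self.adam_eps) <= 0:
            raise ValueError("all optimizer scalars must be positive")


@dataclass
class TrainLog:
    """Per-epoch records of a training run."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, record: dict) -> None:
        self.epochs.append(record)

    @property
    def train_losses(self) -> list[float]:
        return [e["train_loss"] for e in self.epochs]

    @property
    def val_losses(self) -> list[float]:
        return [e["val_loss"] for e in self.epochs]

    def epochs_to_reach(self, threshold: float) -> int | None:
        """First epoch number (1-based) whose validation loss is below the
        threshold, or None if never reached."""
        for e in self.epochs:
            if e["val_loss"] < threshold:
                return e["epoch"]
        return None

    def write_jsonl(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for e in self.epochs:
                fh.write(json.dumps(e) + "\n")


def _mask_loss_background(t_onehot: np.ndarray, include_background: bool):
    return t_onehot if include_background else t_onehot[1:]


def _epoch_items(originals, config: TrainConfig, epoch: int):
    if config.augment_enabled:
        return epoch_augment(originals, config.augment, config.copies_per_image,
                             epoch_seed=int((config.seed + 1) * 100_000 + epoch))
    order = np.random.default_rng((config.seed + 1) * 100_000 + epoch)
    items = list(originals)
    return [items[j] for j in order.permutation(len(items))]


def _loss_on(model: VParNet, image: IntensityVolume, labels: LabelVolume,
             config: TrainConfig, training: bool):
    p = model.forward_tensor(image.data, training=training)
    t = one_hot(labels.data, model.spec.n_labels)
    if config.loss_includes_background:
        return ag.mean_dice_loss(p, t, config.loss_epsilon)
    # background excluded from the mean (ablation flag)
    pf = ag.Tensor(p.data[1:], (p,), lambda g: (np.concatenate(
        [np.zeros((1, *g.shape[1:]), dtype=np.float32), g]),))
    return ag.mean_dice_loss(pf, t[1:], config.loss_epsilon)


def train(train_set, val_set, config: TrainConfig,
          checkpoint_dir=None, verbose: bool = False):
    """Train the network; returns ``(model, TrainLog)``.

    ``train_set`` and ``val_set`` are disjoint lists of
    ``(IntensityVolume, LabelVolume)`` pairs sharing a common grid shape
    compatible with the network depth.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be nonempty")
    train_ids = {id(img) for img, _ in train_set}
    if any(id(img) in train_ids for img, _ in val_set):
        raise ValueError("train and validation sets must be disjoint")
    model = build_vparnet(replace(config.network, seed=config.seed))
    model.check_input_shape(train_set[0][0].data.shape)
    model.reset_dropout_rng(config.seed)
    opt = ag.Adam(model.parameters(), config.step_size, config.beta1,
                  config.beta2, config.adam_eps)
    log = TrainLog()
    best = (np.inf, None)
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
    for epoch in range(1, config.epochs + 1):
        t0 = time.time()
        items = _epoch_items(train_set, config, epoch)
        losses = []
        pending = 0
        for image, labels in items:
            loss = _loss_on(model, image, labels, config, training=True)
            loss.backward()
            losses.append(float(loss.data))
            pending += 1
            if pending == config.batch_size:
                if config.batch_size > 1:
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad / config.batch_size
                opt.step()
                opt.zero_grad()
                pending = 0
        if pending:
            opt.step()
            opt.zero_grad()
        val = float(np.mean([
            float(_loss_on(model, img, lab, config, training=False).data)
            for img, lab in val_set]))
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val,
            "n_items": len(items),
            "wall_time_s": round(time.time() - t0, 3),
        }
        if ckpt_dir and config.checkpoint_every and epoch % config.checkpoint_every == 0:
            path = ckpt_dir / f"epoch_{epoch:04d}.npz"
            save_checkpoint(model, path, extra={"epoch": epoch})
            record["checkpoint"] = str(path)
        log.append(record)
        if verbose:
            print(f"epoch {epoch:3d}  train {record['train_loss']:.4f}  "
                  f"val {val:.4f}  ({record['wall_time_s']:.1f}s)")
        if val < best[0]:
            best = (val, model.state_arrays() if config.select_best_validation else None)
    if config.select_best_validation and best[1] is not None:
        model.load_state_arrays(best[1])
    if ckpt_dir:
        save_checkpoint(model, ckpt_dir / "final.npz",
                        extra={"epoch": config.epochs})
    return model, log


def predict(image: IntensityVolume, model, mask: BrainMask | None = None,
            target_shape=None, return_probabilities: bool = False):
    """Segment one volume: crop around the brain, run the network in
    inference mode, argmax-decode (ties to the lowest label), place the
    result back into the original frame.

    ``model`` is a :class:`VParNet` or a checkpoint path.  Without a mask,
    the nonzero-intensity support is used; without a ``target_shape``, the
    full grid is used when already compatible with the network depth,
    otherwise the smallest compatible window around the mask.
    """
    if not isinstance(model, VParNet):
        model = load_checkpoint(model)
    if mask is None:
        mask = BrainMask.from_intensity(image)
    div = 2 ** (model.spec.depth - 1)
    shape = image.data.shape
    if target_shape is None:
        if all(n % div == 0 for n in shape):
            target_shape = shape
        else:
            bbox = mask.bounding_box()
            target_shape = []
            for axis, (lo, hi) in enumerate(bbox):
                want = -(-(hi - lo + 1) // div) * div
                if want > shape[axis]:
                    raise ValueError(
                        f"axis {axis}: no window of a multiple of {div} fits the "
                        f"brain within the volume; pad the input to at least {want}")
                target_shape.append(want)
    cropped, offsets = crop_to_brain(image, mask, target_shape)
    proba = model(cropped, training=False)
    labels = proba.argmax_labels()
    out = uncrop(labels, offsets, shape)
    out.affine = image.affine
    if return_probabilities:
        return out, proba
    return out


def evaluate_cohort(pairs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate (prediction, truth) pairs; returns per-subject rows and a
    mean +/- sd summary per structure and metric.

    With a single subject the sd is reported as 0 and flagged degenerate.
    """
    if not pairs:
        raise ValueError("no pairs to evaluate")
    frames = []
    for subject, (pred, true) in enumerate(pairs):
        df = evaluate(pred, true).reset_index()
        df.insert(0, "subject", subject)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    metrics = ["dsc", "hd95_mm", "avd_pct"]
    grouped = table.groupby("structure", sort=False)[metrics]
    summary = grouped.agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    n = len(pairs)
    if n == 1:
        for m in metrics:
            summary[f"{m}_std"] = 0.0
    summary["n_subjects"] = n
    summary["degenerate_sd"] = n == 1
    return table, summary


#: The standard ablation matrix: each variant toggles one design element.
ABLATION_VARIANTS: dict[str, dict] = {
    "CNN-1": {"augment_enabled": False},
    "CNN-2": {"norm_kind": "batch"},
    "CNN-3": {"encoder_kind": "plain"},
    "CNN-4": {"fuse_multilevel": False},
    "VParNet": {},
}


def run_ablation(base_config: TrainConfig, train_set, val_set, test_set,
                 variants: dict[str, dict] | None = None,
                 val_threshold: float = 0.1, verbose: bool = False):
    """Train each ablation variant from the same seed on the same data.

    Returns ``(comparison, logs)``: a table of mean DSC/HD95/AVD per
    structure per variant (plus each variant's epochs to reach the
    validation-loss threshold, operationalizing the convergence-speed
    comparison between the fusion and no-fusion heads), and the TrainLogs.
    """
    variants = ABLATION_VARIANTS if variants is None else variants
    rows = []
    logs: dict[str, TrainLog] = {}
    for name, switches in variants.items():
        net_fields = {f.name for f in dataclasses.fields(NetworkSpec)}
        net_over = {k: v for k, v in switches.items() if k in net_fields}
        cfg_over = {k: v for k, v in switches.items() if k not in net_fields}
        config = replace(base_config,
                         network=replace(base_config.network, **net_over),
                         **cfg_over)
        model, log = train(train_set, val_set, config, verbose=verbose)
        logs[name] = log
        preds = [(predict(img, model), lab) for img, lab in test_set]
        _, summary = evaluate_cohort(preds)
        row = {"variant": name,
               "epochs_to_val_threshold": log.epochs_to_reach(val_threshold)}
        for structure in summary.index:
            for metric in ("dsc", "hd95_mm", "avd_pct"):
                row[f"{structure}_{metric}"] = summary.loc[structure, f"{metric}_mean"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant"), logs


# ---------------------------------------------------------------------------
# Config presets and YAML round-trip
# ---------------------------------------------------------------------------

def desk_config(seed: int = 0) -> TrainConfig:
    """Desk-scale preset: depth-3 network on small phantoms, CPU-friendly."""
    return TrainConfig(
        network=NetworkSpec(depth=3, channels=(8, 16, 32), seed=seed),
        # elastic scales sized for the 4 mm desk phantoms (4 voxel smoothing,
        # at most 1 voxel displacement)
        augment=AugmentSpec(rotation_max_deg=10.0, elastic_sigma=16.0,
                            elastic_alpha=4.0, seed=seed),
        epochs=20, seed=seed)


def paper_scale_config(seed: int = 0) -> TrainConfig:
    """Full-scale preset (192x256x192 inputs, depth-4 network, 150 epochs).

    Provided as configuration only: training at this scale needs
    accelerator-class hardware."""
    return TrainConfig(
        network=NetworkSpec(depth=4, channels=(32, 64, 128, 256), seed=seed),
        augment=AugmentSpec(seed=seed),
        epochs=150, seed=seed)


def config_to_yaml(config: TrainConfig, path=None) -> str:
    d = dataclasses.asdict(config)
    d["network"]["channels"] = list(d["network"]["channels"])
    text = yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_preset(name: str) -> TrainConfig:
    """Load a shipped config preset ("desk" or "paper_scale")."""
    from importlib.resources import files
    text = files("ventparc").joinpath(f"presets/{name}.yaml").read_text()
    return config_from_yaml(text)


def config_from_yaml(source) -> TrainConfig:
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        source = Path(source).read_text()
    d = yaml.safe_load(source)
    network = d.pop("network", {})
    network["channels"] = tuple(network.get("channels", (8, 16, 32)))
    augment = d.pop("augment", {})
    return TrainConfig(network=NetworkSpec(**network),
                       augment=AugmentSpec(**augment), **d)
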
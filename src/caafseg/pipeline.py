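"""Training, evaluation, ablation and prediction orchestration.

The experiment harness mirrors the reference training protocol: AdamW at
an initial learning rate of 1e-4 with a step decay of 0.1 every 30
epochs, a composite Dice + boundary loss selected by configuration, and
per-epoch bookkeeping of the mean training loss, the learning rate and
the validation Dice. The AAC ablation trains matched adaptive and
fixed-weight (0.5, 0.5) variants on identical data with identical seeds
and compares per-case Dice scores with a two-tailed paired t-test.

All randomness (parameter initialisation, shuffling, data splits) derives
from explicit integer seeds, so a (config, seed, data) triple determines
every reported number.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import losses, metrics, nn
from .metrics import PairedTestResult
from .network import CAAFResUNet, NetworkConfig
from .nn import Tensor

__all__ = [
    "TrainConfig",
    "ExperimentRecord",
    "AblationResult",
    "TrainingDivergedError",
    "fixtures_to_arrays",
    "split_fixtures",
    "train",
    "evaluate",
    "ablation_aac",
    "predict",
    "difference_map",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

# difference-map colour semantics (RGB)
COLOR_TP = (0, 255, 0)      # green: true positive
COLOR_TN = (0, 0, 255)      # blue:  true negative
COLOR_FP = (255, 0, 0)      # red:   false positive
COLOR_FN = (255, 255, 0)    # yellow: false negative


class TrainingDivergedError(RuntimeError):
    """Raised when a loss component becomes non-finite during training."""


@dataclass
class TrainConfig:
    """Optimisation settings.

    Defaults follow the reference protocol (AdamW, lr 1e-4, step decay
    0.1 every 30 epochs); batch size and weight decay are exposed knobs
    with conventional defaults.
    """

    epochs: int = 100
    batch_size: int = 8
    lr: float = 1e-4
    weight_decay: float = 1e-2
    scheduler_step: int = 30
    scheduler_gamma: float = 0.1
    loss_variant: str = "hausdorff"
    boundary_weight: float = 1.0
    seed: int = 0
    eval_every: int = 1  # validation-Dice cadence in epochs

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 < self.scheduler_gamma < 1:
            raise ValueError("scheduler_gamma must be in (0, 1)")
        if self.loss_variant not in losses.LOSS_VARIANTS:
            raise ValueError(f"loss_variant must be one of {losses.LOSS_VARIANTS}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentRecord:
    """Per-epoch bookkeeping of one training run plus the final weights."""

    train_config: dict
    network_config: dict
    loss_trajectory: list = field(default_factory=list)
    lr_trajectory: list = field(default_factory=list)
    dice_trajectory: list = field(default_factory=list)
    best_epoch: int = -1
    best_dice: float = float("nan")
    state: dict | None = None       # final parameters (numpy arrays)
    best_state: dict | None = None  # best-validation-Dice parameters

    def to_json_dict(self) -> dict:
        return {
            "train_config": self.train_config,
            "network_config": self.network_config,
            "loss_trajectory": self.loss_trajectory,
            "lr_trajectory": self.lr_trajectory,
            "dice_trajectory": self.dice_trajectory,
            "best_epoch": self.best_epoch,
            "best_dice": self.best_dice,
        }

    def save(self, directory) -> Path:
        """Write record.json plus npz parameter archives; returns the dir."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "record.json").write_text(
            json.dumps(self.to_json_dict(), indent=2))
        if self.state is not None:
            save_checkpoint(self.state, self.network_config, directory / "final.npz")
        if self.best_state is not None:
            save_checkpoint(self.best_state, self.network_config, directory / "best.npz")
        return directory

    @classmethod
    def load(cls, directory) -> "ExperimentRecord":
        directory = Path(directory)
        payload = json.loads((directory / "record.json").read_text())
        rec = cls(**payload)
        if (directory / "final.npz").exists():
            rec.state, _ = load_checkpoint(directory / "final.npz")
        if (directory / "best.npz").exists():
            rec.best_state, _ = load_checkpoint(directory / "best.npz")
        return rec


@dataclass
class AblationResult:
    test: PairedTestResult
    summary_aac: dict
    summary_fixed: dict
    n_test_cases: int


# -----------------------------------------------------------------------------
# data plumbing
# -----------------------------------------------------------------------------

def fixtures_to_arrays(fixtures) -> tuple[np.ndarray, np.ndarray]:
    """Stack fixtures into (B×1×H×W) image and mask arrays."""
    images = np.stack([np.asarray(f.image, dtype=np.float32) for f in fixtures])
    masks = np.stack([np.asarray(f.mask, dtype=np.float32) for f in fixtures])
    return images, masks


def split_fixtures(fixtures, fractions=(0.7, 0.15, 0.15), seed: int = 0):
    """Seeded shuffle split into train/val/test lists."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("split fractions must sum to 1")
    idx = np.arange(len(fixtures))
    np.random.default_rng(seed).shuffle(idx)
    n_train = int(round(fractions[0] * len(fixtures)))
    n_val = int(round(fractions[1] * len(fixtures)))
    train_ix, val_ix = idx[:n_train], idx[n_train:n_train + n_val]
    test_ix = idx[n_train + n_val:]
    pick = lambda ix: [fixtures[i] for i in ix]
    return pick(train_ix), pick(val_ix), pick(test_ix)


def _loss_components(prob: Tensor, target: Tensor, variant: str,
                     boundary_weight: float) -> tuple[Tensor, float, float]:
    dice = losses.dice_loss(prob, target)
    boundary = losses._BOUNDARY_FNS[variant](prob, target)
    total = dice + boundary_weight * boundary
    return total, dice.item(), boundary.item()


# -----------------------------------------------------------------------------
# training / evaluation
# -----------------------------------------------------------------------------

def train(config: TrainConfig, data, net_config: NetworkConfig | None = None,
          val_data=None, model: CAAFResUNet | None = None) -> tuple[ExperimentRecord, CAAFResUNet]:
    """Train a model on fixture data; returns (record, model).

    With ``epochs=0`` the record has an empty trajectory and the initial
    parameters are stored as both final and best state.
    """
    if not data:
        raise ValueError("training data must be nonempty")
    net_config = net_config or NetworkConfig()
    if model is None:
        model = CAAFResUNet(net_config, seed=config.seed)
    images, masks = fixtures_to_arrays(data)
    n = images.shape[0]

    optimizer = nn.AdamW(model.parameters(), lr=config.lr,
                         weight_decay=config.weight_decay)
    scheduler = nn.StepLR(optimizer, step_size=config.scheduler_step,
                          gamma=config.scheduler_gamma)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    record = ExperimentRecord(train_config=config.to_dict(),
                              network_config=net_config.to_dict())
    monitor = val_data if val_data else data
    best_dice, best_epoch, best_state = -1.0, -1, model.state_dict()

    for epoch in range(config.epochs):
        model.train()
        order = shuffle_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            x = Tensor(images[batch])
            y = Tensor(masks[batch])
            out = model(x)
            total, dice_val, boundary_val = _loss_components(
                out.prob_mask, y, config.loss_variant, config.boundary_weight)
            if not np.isfinite(dice_val):
                raise TrainingDivergedError(
                    f"Dice loss diverged (value {dice_val}) at epoch {epoch}")
            if not np.isfinite(boundary_val):
                raise TrainingDivergedError(
                    f"{config.loss_variant} boundary loss diverged "
                    f"(value {boundary_val}) at epoch {epoch}")
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            epoch_losses.append(total.item())
        record.loss_trajectory.append(float(np.mean(epoch_losses)))
        record.lr_trajectory.append(scheduler.get_lr())

        if epoch % config.eval_every == 0 or epoch == config.epochs - 1:
            _, summary = evaluate(model, monitor, batch_size=config.batch_size)
            epoch_dice = summary["dice_mean"]
            record.dice_trajectory.append([epoch, epoch_dice])
            if epoch_dice > best_dice:
                best_dice, best_epoch, best_state = epoch_dice, epoch, model.state_dict()
            logger.info("epoch %d: loss=%.4f dice=%.4f lr=%.2e", epoch,
                        record.loss_trajectory[-1], epoch_dice, record.lr_trajectory[-1])
        scheduler.step()

    record.state = model.state_dict()
    record.best_state = best_state
    record.best_epoch = best_epoch
    record.best_dice = best_dice
    return record, model


def evaluate(model: CAAFResUNet, data, batch_size: int = 8,
             threshold: float = 0.5) -> tuple[pd.DataFrame, dict]:
    """Per-case metrics and fusion weights plus a mean ± SD summary."""
    if not data:
        raise ValueError("evaluation data must be nonempty")
    images, masks = fixtures_to_arrays(data)
    model.eval()
    reports, weights = [], []
    with nn.no_grad():
        for start in range(0, images.shape[0], batch_size):
            x = Tensor(images[start:start + batch_size])
            out = model(x)
            probs = out.prob_mask.data
            w = out.fusion_weights.data
            for i in range(probs.shape[0]):
                c = metrics.confusion(probs[i], masks[start + i], threshold=threshold)
                reports.append(metrics.compute_metrics(c))
                weights.append((float(w[i, 0]), float(w[i, 1])))
    frame = metrics.report_frame(range(len(reports)), reports, weights)
    summary = {}
    for name in ("dice", "iou", "sensitivity", "miss_rate", "specificity"):
        vals = np.array([getattr(r, name) for r in reports])
        summary[f"{name}_mean"] = float(vals.mean())
        summary[f"{name}_std"] = float(vals.std())
    warr = np.asarray(weights)
    summary["w1_mean"] = float(warr[:, 0].mean())
    summary["w2_mean"] = float(warr[:, 1].mean())
    summary["n_cases"] = len(reports)
    return frame, summary


def ablation_aac(config: TrainConfig, data, net_config: NetworkConfig | None = None,
                 fractions=(0.7, 0.15, 0.15)) -> AblationResult:
    """Train matched AAC-on and fixed-weight variants; paired t-test on Dice.

    Both arms share the data split, initial seed and training protocol;
    only the fusion-weight source differs (adaptive controller vs the
    fixed (0.5, 0.5) baseline).
    """
    from dataclasses import replace

    net_config = net_config or NetworkConfig()
    train_set, val_set, test_set = split_fixtures(data, fractions, seed=config.seed)
    if len(test_set) < 2:
        raise ValueError("ablation needs at least 2 test cases")

    cfg_on = replace(net_config, aac_enabled=True)
    cfg_off = replace(net_config, aac_enabled=False, aac_fixed_weights=(0.5, 0.5))
    _, model_on = train(config, train_set, cfg_on, val_data=val_set or None)
    _, model_off = train(config, train_set, cfg_off, val_data=val_set or None)

    frame_on, summary_on = evaluate(model_on, test_set)
    frame_off, summary_off = evaluate(model_off, test_set)
    dice_on = frame_on["dice"].iloc[:-1].to_numpy(dtype=float)
    dice_off = frame_off["dice"].iloc[:-1].to_numpy(dtype=float)
    test = metrics.paired_t_test(dice_on, dice_off)
    return AblationResult(test=test, summary_aac=summary_on,
                          summary_fixed=summary_off, n_test_cases=len(test_set))


# -----------------------------------------------------------------------------
# prediction
# -----------------------------------------------------------------------------

def difference_map(pred_binary: np.ndarray, target: np.ndarray) -> np.ndarray:
    """RGB error map: green TP, blue TN, red FP, yellow FN."""
    pb = pred_binary > 0
    tb = target > 0
    out = np.zeros(pb.shape + (3,), dtype=np.uint8)
    out[pb & tb] = COLOR_TP
    out[~pb & ~tb] = COLOR_TN
    out[pb & ~tb] = COLOR_FP
    out[~pb & tb] = COLOR_FN
    return out


def predict(model: CAAFResUNet, images: np.ndarray, ground_truth: np.ndarray | None = None,
            out_dir=None, threshold: float = 0.5, batch_size: int = 8):
    """Segment images; returns (binary masks, difference maps or None).

    When ``out_dir`` is given, binary mask PNGs (and, with ground truth,
    4-colour difference maps) are written there.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4:
        raise ValueError(f"expected B×1×H×W images, got shape {images.shape}")
    model.eval()
    masks = []
    with nn.no_grad():
        for start in range(0, images.shape[0], batch_size):
            out = model(Tensor(images[start:start + batch_size]))
            masks.append(out.prob_mask.data >= threshold)
    pred = np.concatenate(masks, axis=0)[:, 0]  # B×H×W bool

    diff_maps = None
    if ground_truth is not None:
        gt = np.asarray(ground_truth)
        if gt.ndim == 4:
            gt = gt[:, 0]
        if gt.shape != pred.shape:
            raise ValueError(f"ground truth shape {gt.shape} does not match predictions {pred.shape}")
        diff_maps = np.stack([difference_map(p, g) for p, g in zip(pred, gt)])

    if out_dir is not None:
        import imageio.v3 as iio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, p in enumerate(pred):
            iio.imwrite(out_dir / f"mask_{i:04d}.png", (p * 255).astype(np.uint8))
        if diff_maps is not None:
            for i, dm in enumerate(diff_maps):
                iio.imwrite(out_dir / f"diff_{i:04d}.png", dm)
    return pred, diff_maps


# -----------------------------------------------------------------------------
# checkpoints
# -----------------------------------------------------------------------------

def _config_hash(config_dict: dict) -> str:
    canon = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_checkpoint(state: dict, network_config: dict | NetworkConfig, path) -> Path:
    """Write a parameter archive (npz) plus a YAML config sidecar with hash."""
    path = Path(path)
    if isinstance(network_config, NetworkConfig):
        network_config = network_config.to_dict()
    np.savez(path, **state)
    sidecar = {"network_config": _plain(network_config),
               "config_hash": _config_hash(_plain(network_config))}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))
    return path


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_checkpoint(path) -> tuple[dict, dict]:
    """Load (state dict, network config); validates the config hash."""
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    cfg = sidecar["network_config"]
    if _config_hash(cfg) != sidecar["config_hash"]:
        raise ValueError(f"checkpoint config hash mismatch for {path}")
    with np.load(path) as archive:
        state = {k: archive[k].copy() for k in archive.files}
    return state, cfg


def load_model(path) -> CAAFResUNet:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    state, cfg = load_checkpoint(path)
    cfg = dict(cfg)
    for key in ("stage_channels", "aspp_dilations", "aac_fixed_weights"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    model = CAAFResUNet(NetworkConfig(**cfg))
    model.load_state_dict(state)
    return model
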
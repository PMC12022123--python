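"""Patch-based training: fold splitting, patch sampling, the SGD loop with
MixUp and deep supervision, checkpointing and model selection.

The optimization recipe follows the patch-based 3D segmentation setup the
networks were designed for: SGD with Nesterov momentum 0.99, initial
learning rate 0.01 decayed polynomially (exponent 0.9), weight decay 3e-5,
a raw batch of 2 patches oversampled toward foreground, and — when MixUp is
enabled — 2 additional mixed patches per step so the effective batch is 4.
Raw patches are supervised with the deep-supervision CE+Dice loss; mixed
patches with cross-entropy only at the finest resolution.

Model selection: after each validation pass the checkpoint with the highest
mean aggregated DSC over the two lesion classes on the held-out fold is
kept as "best"; the last epoch is kept as "final".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augmentation import AugmentParams, augment_patch, mixup, sample_lambda, \
    random_bezier, bezier_intensity_transform
from .evaluation import aggregated_dsc, dsc_per_case
from .inference import InferenceConfig, probabilities_to_labels, \
    sliding_window_predict
from .losses import deep_supervision_loss, downsample_labels, mixup_loss, one_hot
from .networks import BasicSegNet, DFUNet, FusionSpec, NetworkSpec
from .preprocessing import preprocess_case
from .volume import read_volume

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainingCase",
    "TrainResult",
    "make_folds",
    "sample_patch",
    "poly_lr",
    "train_fold",
    "build_network",
    "save_checkpoint",
    "load_checkpoint",
    "load_pretrained",
    "cases_from_cohort",
]

TASK_MODES = ("task1_single", "task2_three_channel", "task2_dfunet")


@dataclass
class TrainConfig:
    epochs: int = 1000
    iterations_per_epoch: int = 250
    batch_size_raw: int = 2
    use_mixup: bool = False
    mixup_alpha: float = 0.2
    patch_size: tuple[int, int, int] = (56, 224, 160)
    momentum: float = 0.99
    initial_lr: float = 0.01
    weight_decay: float = 3e-5
    lr_exponent: float = 0.9
    fg_oversample_fraction: float = 1.0 / 3.0
    seed: int = 0
    task_mode: str = "task1_single"
    val_every: int = 10
    augment: AugmentParams = field(default_factory=AugmentParams)
    bezier_prob: float = 0.0   # pre-training-style intensity augmentation
    pretrained_weights: str | None = None

    def __post_init__(self):
        if self.batch_size_raw < 1:
            raise ValueError("batch size must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.task_mode not in TASK_MODES:
            raise ValueError(f"task_mode must be one of {TASK_MODES}")

    @property
    def effective_batch_size(self) -> int:
        return self.batch_size_raw * (2 if self.use_mixup else 1)


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: list[str]
    val_ids: list[str]


@dataclass
class TrainingCase:
    """A preprocessed case ready for patch sampling: channel-stacked image
    and an integer label map on the same grid."""

    case_id: str
    image: np.ndarray       # (C, D, H, W) float32
    labels: np.ndarray      # (D, H, W) int

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.image.shape[1:] != self.labels.shape:
            raise ValueError("image and labels grids differ")


@dataclass
class TrainResult:
    fold_index: int
    best_val_dsc: float
    best_epoch: int
    final_train_loss: float
    best_checkpoint: Path
    final_checkpoint: Path
    log: pd.DataFrame


def make_folds(case_ids, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Deterministic shuffle, then k near-equal validation folds that
    partition the cohort."""
    ids = list(case_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} cases")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    chunks = np.array_split(np.arange(len(order)), k)
    folds = []
    for i, chunk in enumerate(chunks):
        val = [order[j] for j in chunk]
        train = [c for c in order if c not in val]
        folds.append(FoldSplit(i, train, val))
    return folds


def sample_patch(image: np.ndarray, labels: np.ndarray, patch_size,
                 fg_oversample_fraction: float, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Sample one (image, label) patch.

    With probability ``fg_oversample_fraction`` (and when any foreground
    exists) the patch is centered on a random foreground voxel, clamped to
    the bounds; otherwise it is uniformly positioned.  Volumes smaller than
    the patch are symmetrically zero-padded first.
    """
    image = np.asarray(image, dtype=np.float32)
    labels = np.asarray(labels)
    pads = [(0, 0)]
    lab_pads = []
    for ax in range(3):
        short = max(0, patch_size[ax] - image.shape[ax + 1])
        pads.append((short // 2, short - short // 2))
        lab_pads.append(pads[-1])
    if any(p != (0, 0) for p in pads):
        image = np.pad(image, pads)
        labels = np.pad(labels, lab_pads)
    shape = image.shape[1:]
    fg = np.argwhere(labels > 0)
    starts = []
    if fg.size and rng.uniform() < fg_oversample_fraction:
        center = fg[rng.integers(len(fg))]
        for ax in range(3):
            lo = int(center[ax]) - patch_size[ax] // 2
            lo = min(max(lo, 0), shape[ax] - patch_size[ax])
            starts.append(lo)
    else:
        for ax in range(3):
            starts.append(int(rng.integers(0, shape[ax] - patch_size[ax] + 1)))
    sl = tuple(slice(s, s + p) for s, p in zip(starts, patch_size))
    return image[(slice(None),) + sl].copy(), labels[sl].copy()


def poly_lr(epoch: int, total_epochs: int, initial_lr: float,
            exponent: float = 0.9) -> float:
    """Polynomial decay: lr = lr0 * (1 - epoch/total)**exponent."""
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    return initial_lr * (1.0 - epoch / total_epochs) ** exponent


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def build_network(kind: str, spec: NetworkSpec,
                  fusion: FusionSpec | None = None, seed: int = 0,
                  in_channels: int | None = None):
    if kind == "basic":
        return BasicSegNet(spec, seed=seed, in_channels=in_channels)
    if kind == "dfunet":
        return DFUNet(spec, fusion, seed=seed)
    raise ValueError(f"unknown network kind '{kind}'")


def save_checkpoint(network, path: str | Path, extra: dict | None = None
                    ) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    kind = "dfunet" if isinstance(network, DFUNet) else "basic"
    meta = {
        "kind": kind,
        "spec": network.spec.to_dict(),
        "in_channels": network.in_channels,
        "extra": extra or {},
    }
    if kind == "dfunet":
        meta["fusion"] = network.fusion_spec.to_dict()
    arrays = {f"param:{k}": v for k, v in network.state_dict().items()}
    np.savez_compressed(path, _meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path, seed: int = 0):
    """Rebuild the network stored in a checkpoint. Returns (network, meta)."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        state = {k[len("param:"):]: z[k] for k in z.files
                 if k.startswith("param:")}
    spec = NetworkSpec.from_dict(meta["spec"])
    fusion = FusionSpec.from_dict(meta["fusion"]) if "fusion" in meta else None
    net = build_network(meta["kind"], spec, fusion, seed=seed,
                        in_channels=meta["in_channels"])
    net.load_state_dict(state, strict=True)
    return net, meta


def load_pretrained(network, checkpoint: str | Path | dict,
                    strict: bool = False, reinit_heads: bool = False,
                    seed: int = 0) -> dict:
    """Copy matching-shape weights from a checkpoint into ``network``.

    With ``reinit_heads`` the deep-supervision heads are freshly
    re-initialized after loading (class-count changes across datasets).
    Returns a transfer report of loaded/skipped tensor names.
    """
    if isinstance(checkpoint, (str, Path)):
        with np.load(Path(checkpoint)) as z:
            state = {k[len("param:"):]: z[k] for k in z.files
                     if k.startswith("param:")}
    else:
        state = dict(checkpoint)
    if reinit_heads:
        state = {k: v for k, v in state.items()
                 if ".heads." not in k}
    report = network.load_state_dict(state, strict=strict)
    if reinit_heads:
        rng = np.random.default_rng(seed)
        for head in network.decoder.heads:
            fan_in = head.weight.data.shape[1]
            head.weight.data = nn.he_init(rng, head.weight.data.shape, fan_in)
            if head.bias is not None:
                head.bias.data = np.zeros_like(head.bias.data)
    return report


# ---------------------------------------------------------------------------
# cohort loading
# ---------------------------------------------------------------------------

def cases_from_cohort(cohort_dir: str | Path, task_mode: str,
                      case_ids=None, body_threshold: float = 60.0,
                      target_spacing=(1.2, 0.5, 0.5),
                      match_reference=None) -> dict[str, dict]:
    """Preprocess a phantom-style cohort directory into training cases.

    Returns {case_id: {"case": TrainingCase, "pre": PreprocessedCase}}.
    Channel layout per task mode:
    ``task1_single`` — [pre image], labels = pre mask;
    ``task2_three_channel`` / ``task2_dfunet`` — [mid image, registered pre
    image, pre mask rescaled to {0, 0.5, 1}], labels = mid mask.
    """
    if task_mode not in TASK_MODES:
        raise ValueError(f"unknown task mode '{task_mode}'")
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "cohort.csv")
    if case_ids is not None:
        manifest = manifest[manifest["case_id"].isin(set(case_ids))]
    out = {}
    for _, row in manifest.iterrows():
        cid = row["case_id"]
        if task_mode == "task1_single":
            img = read_volume(row["pre_image"])
            lab = read_volume(row["pre_mask"], as_labels=True)
            pp = preprocess_case(img, lab, body_threshold=body_threshold,
                                 target_spacing=target_spacing,
                                 match_reference=match_reference)
            chans = [pp.image.data]
        else:
            img = read_volume(row["mid_image"])
            lab = read_volume(row["mid_mask"], as_labels=True)
            prior_img = read_volume(row["pre_image"])
            prior_lab = read_volume(row["pre_mask"], as_labels=True)
            pp = preprocess_case(img, lab, extra_images=(prior_img,),
                                 extra_labels=(prior_lab,),
                                 body_threshold=body_threshold,
                                 target_spacing=target_spacing,
                                 match_reference=match_reference)
            prior_mask = pp.extra_images[1].data.astype(np.float32) / 2.0
            chans = [pp.image.data, pp.extra_images[0].data, prior_mask]
        case = TrainingCase(cid, np.stack(chans), pp.labels.data)
        out[cid] = {"case": case, "pre": pp}
    return out


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def _forward(network, batch: np.ndarray):
    if isinstance(network, DFUNet):
        return network(batch[:, :1], batch[:, 1:])
    return network(batch)


def _validate(network, cases: dict[str, TrainingCase], patch_size
              ) -> float:
    """Mean aggregated DSC over the lesion classes on the validation set."""
    cfg = InferenceConfig(patch_size=patch_size, window_step_fraction=0.5,
                          gaussian_weighting=True, tta_flip_axes=())
    rows = {1: [], 2: []}
    for case in cases.values():
        probs = sliding_window_predict(network, case.image, cfg)
        pred = probabilities_to_labels(probs)
        for c in (1, 2):
            inter, np_, nr, _ = dsc_per_case(pred, case.labels, c)
            rows[c].append((inter, np_, nr))
    return float(np.mean([aggregated_dsc(rows[c]) for c in (1, 2)]))


def train_fold(config: TrainConfig, fold: FoldSplit,
               cases: dict[str, TrainingCase], out_dir: str | Path,
               network_kind: str = "basic", spec: NetworkSpec | None = None,
               fusion: FusionSpec | None = None) -> TrainResult:
    """Train one fold end-to-end and return the result summary.

    ``cases`` maps case ids (covering train and validation ids) to
    preprocessed TrainingCase objects.  Fully seeded: data order, patch
    positions, augmentation draws and weight init all derive from
    ``config.seed`` and the fold index, so a repeat run reproduces the
    final loss bitwise.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = [c for c in fold.train_ids + fold.val_ids if c not in cases]
    if missing:
        raise KeyError(f"cases absent from cohort: {missing}")
    train_cases = [cases[c] for c in fold.train_ids]
    val_cases = {c: cases[c] for c in fold.val_ids}
    assert not set(fold.train_ids) & set(fold.val_ids)

    spec = spec or NetworkSpec()
    net_seed = int((config.seed * 1000003 + fold.fold_index) % (2**31 - 1))
    if network_kind == "basic":
        in_ch = train_cases[0].image.shape[0]
        network = build_network("basic", spec, seed=net_seed, in_channels=in_ch)
    else:
        network = build_network("dfunet", spec, fusion, seed=net_seed)
    if config.pretrained_weights:
        load_pretrained(network, config.pretrained_weights)

    opt = nn.SGD(network.parameters(), lr=config.initial_lr,
                 momentum=config.momentum, weight_decay=config.weight_decay)
    rng = np.random.default_rng([config.seed, fold.fold_index, 17])
    head_strides = spec.head_strides()
    n_classes = spec.n_classes

    best_dsc, best_epoch = -1.0, -1
    best_path = out_dir / f"fold{fold.fold_index}_best.npz"
    final_path = out_dir / f"fold{fold.fold_index}_final.npz"
    log_rows = []
    final_loss = float("nan")

    for epoch in range(config.epochs):
        opt.lr = poly_lr(epoch, config.epochs, config.initial_lr,
                         config.lr_exponent)
        epoch_losses = []
        for _ in range(config.iterations_per_epoch):
            idx = rng.integers(0, len(train_cases), size=config.batch_size_raw)
            patches, labels = [], []
            for i in idx:
                c = train_cases[i]
                p, l = sample_patch(c.image, c.labels, config.patch_size,
                                    config.fg_oversample_fraction, rng)
                p, l = augment_patch(p, l, rng, config.augment)
                if config.bezier_prob and rng.uniform() < config.bezier_prob:
                    p = bezier_intensity_transform(p, random_bezier(rng))
                patches.append(p)
                labels.append(l)
            x_raw = np.stack(patches)
            y_raw = np.stack(labels)

            logits = _forward(network, x_raw)
            targets = downsample_labels(y_raw, head_strides)
            breakdown = deep_supervision_loss(logits, targets, n_classes)
            loss = breakdown.total

            if config.use_mixup and config.batch_size_raw >= 2:
                y_onehot = one_hot(y_raw, n_classes)
                mixed_x, mixed_y = [], []
                for i in range(config.batch_size_raw):
                    j = int(rng.integers(0, config.batch_size_raw - 1))
                    j = j if j < i else j + 1
                    lam = sample_lambda(config.mixup_alpha, rng)
                    m = mixup(x_raw[i], y_onehot[i], x_raw[j], y_onehot[j], lam)
                    mixed_x.append(m.x_mix)
                    mixed_y.append(m.y_mix)
                mix_logits = _forward(network, np.stack(mixed_x))
                loss = loss + mixup_loss(mix_logits[0], np.stack(mixed_y))

            loss_val = loss.item()
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss_val}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss_val)

        final_loss = float(np.mean(epoch_losses))
        row = {"epoch": epoch, "lr": opt.lr, "train_loss": final_loss,
               "effective_batch_size": config.effective_batch_size,
               "val_mean_agg_dsc": np.nan}
        if (epoch + 1) % config.val_every == 0 or epoch == config.epochs - 1:
            val_dsc = _validate(network, val_cases, config.patch_size)
            row["val_mean_agg_dsc"] = val_dsc
            if val_dsc > best_dsc:
                best_dsc, best_epoch = val_dsc, epoch
                save_checkpoint(network, best_path,
                                extra={"epoch": epoch, "val_dsc": val_dsc})
        log_rows.append(row)

    save_checkpoint(network, final_path,
                    extra={"epoch": config.epochs - 1,
                           "train_loss": final_loss})
    log = pd.DataFrame(log_rows)
    log.to_csv(out_dir / f"fold{fold.fold_index}_log.csv", index=False)
    return TrainResult(fold.fold_index, best_dsc, best_epoch, final_loss,
                       best_path, final_path, log)
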
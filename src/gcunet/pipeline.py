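"""Data loading, augmentation, the training loop, and batch prediction.

Augmentation applies one sampled geometric transform to image and mask
alike (bilinear for the image, nearest for the mask) and scales 8-bit
intensities to [0,1]. Training is an Adam loop over shuffled mini-batches
of the combined BCE + dice loss; every random draw in epoch ``e`` comes
from a generator seeded with ``(seed, e)`` so a run resumed from a
checkpoint reproduces the remaining epoch records exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .metrics import extract_instances, dice as dice_score
from .network import (GCUNet, load_checkpoint, save_checkpoint,
                      segmentation_loss)

log = logging.getLogger("gcunet")

IMAGE_EXTS = {".png", ".tif", ".tiff"}


@dataclass
class AugmentConfig:
    rotate: bool = True
    angles: tuple[float, ...] = (0.0, 90.0, 180.0, 270.0)
    jitter_deg: float = 15.0
    translate: bool = True
    max_shift: float = 0.1
    normalize: bool = True
    variants_per_image: int = 10  # on-the-fly dataset enlargement factor


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 200
    image_size: int = 512
    optimizer: str = "adam"
    bce_weight: float = 1.0
    dice_weight: float = 1.0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    checkpoint_every: int = 50
    device: str = "cpu"

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.device not in ("cpu", "gpu"):
            raise ValueError("device must be 'cpu' or 'gpu'")
        if self.device == "gpu":
            raise ValueError("this build is CPU-only; set device='cpu'")
        if self.image_size % 32:
            raise ValueError("image_size must be a multiple of 32")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_dice: float
    lr: float
    wall_notes: str = ""


# -- data loading ----------------------------------------------------------


def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return arr


def _mask_candidates(stem: str) -> list[str]:
    out = [stem]
    if stem.startswith("image_"):
        out.append("inst_" + stem[len("image_"):])
        out.append("mask_" + stem[len("image_"):])
    out += ["inst_" + stem, "mask_" + stem, stem + "_mask"]
    return out


class PairDataset:
    """Lazily yields (image float32 (3,H,W) in [0,1], instance map (H,W))."""

    def __init__(self, images_dir, masks_dir):
        self.images_dir = Path(images_dir)
        self.masks_dir = Path(masks_dir)
        self.pairs: list[tuple[Path, Path]] = []
        image_files = sorted(
            p for p in self.images_dir.iterdir()
            if p.suffix.lower() in IMAGE_EXTS
            and not p.name.startswith(("inst_", "mask_", "prob_")))
        if not image_files:
            raise FileNotFoundError(f"no images found in {self.images_dir}")
        mask_stems = {p.stem: p for p in self.masks_dir.iterdir()
                      if p.suffix.lower() in IMAGE_EXTS}
        for img in image_files:
            mask = next((mask_stems[c] for c in _mask_candidates(img.stem)
                         if c in mask_stems and mask_stems[c] != img), None)
            if mask is None:
                raise FileNotFoundError(
                    f"no mask found in {self.masks_dir} for image stem "
                    f"{img.stem!r}")
            self.pairs.append((img, mask))

    def __len__(self):
        return len(self.pairs)

    def __getitem__(self, i: int):
        img_path, mask_path = self.pairs[i]
        img = _read_image(img_path)
        mask = _read_image(mask_path)
        if mask.ndim == 3:
            mask = mask[..., 0]
        if img.shape[:2] != mask.shape:
            raise ValueError(
                f"image {img_path.name} is {img.shape[:2]} but mask "
                f"{mask_path.name} is {mask.shape}")
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[..., :3].astype(np.float32)
        if img.max() > 1.0:
            img = img / 255.0
        return img.transpose(2, 0, 1), mask.astype(np.int64)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def load_pairs(images_dir, masks_dir) -> PairDataset:
    return PairDataset(images_dir, masks_dir)


# -- augmentation ----------------------------------------------------------


def _resize_pair(image: np.ndarray, mask: np.ndarray, size: int):
    from skimage.transform import resize

    if image.shape[1:] == (size, size):
        return image, mask
    img = resize(image, (image.shape[0], size, size), order=1,
                 preserve_range=True, anti_aliasing=image.shape[1] > size)
    msk = resize(mask, (size, size), order=0, preserve_range=True,
                 anti_aliasing=False)
    return img.astype(np.float32), msk.astype(mask.dtype)


def augment_pair(image: np.ndarray, mask: np.ndarray, cfg: AugmentConfig,
                 rng: np.random.Generator, out_size: int | None = None):
    """Shared geometric transform on an image/mask pair.

    The image is warped with bilinear interpolation and filled with its
    per-channel median outside the original support; the mask uses nearest
    neighbour with zero fill, so pixelwise correspondence is preserved.
    """
    from skimage.transform import AffineTransform, warp

    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape[1:] != mask.shape:
        raise ValueError(f"image {image.shape[1:]} vs mask {mask.shape}")
    if cfg.normalize and image.max() > 1.0:
        image = image / 255.0

    angle = 0.0
    if cfg.rotate:
        angle = float(rng.choice(cfg.angles))
        angle += float(rng.uniform(-cfg.jitter_deg, cfg.jitter_deg))
    ty = tx = 0.0
    if cfg.translate:
        ty = float(rng.uniform(-cfg.max_shift, cfg.max_shift)) * image.shape[1]
        tx = float(rng.uniform(-cfg.max_shift, cfg.max_shift)) * image.shape[2]

    if angle != 0.0 or ty != 0.0 or tx != 0.0:
        h, w = mask.shape
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
        tf = (AffineTransform(translation=-center)
              + AffineTransform(rotation=np.deg2rad(angle))
              + AffineTransform(translation=center)
              + AffineTransform(translation=(tx, ty)))
        warped = np.empty_like(image)
        for c in range(image.shape[0]):
            warped[c] = warp(image[c], tf.inverse, order=1, mode="constant",
                             cval=float(np.median(image[c])), preserve_range=True)
        image = warped
        mask = warp(mask.astype(np.float64), tf.inverse, order=0,
                    mode="constant", cval=0, preserve_range=True).astype(mask.dtype)

    if out_size is not None:
        image, mask = _resize_pair(image, mask, out_size)
    return np.clip(image, 0.0, 1.0), mask


# -- training --------------------------------------------------------------


def _epoch_samples(pairs, cfg: TrainConfig, epoch: int):
    """Augmented (image, binary target) list for one epoch, seeded by epoch."""
    rng = np.random.default_rng([cfg.seed, epoch])
    out = []
    for img, inst in pairs:
        for _ in range(max(1, cfg.augment.variants_per_image)):
            aug_img, aug_mask = augment_pair(img, inst, cfg.augment, rng,
                                             out_size=cfg.image_size)
            out.append((aug_img, (aug_mask > 0).astype(np.float32)))
    order = rng.permutation(len(out))
    return [out[i] for i in order]


def train(model: GCUNet, dataset, cfg: TrainConfig, out_dir=None,
          resume_from=None):
    """Train in place; returns (model, [EpochRecord...])."""
    pairs = list(dataset)
    if not pairs:
        raise ValueError("training dataset is empty")
    optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    start_epoch = 0
    if resume_from is not None:
        model, start_epoch, optim_state = load_checkpoint(resume_from)
        optimizer = nn.Adam(model.parameters(), lr=cfg.learning_rate)
        if optim_state:
            optimizer.load_state_dict(optim_state)
        log.info("resumed from %s at epoch %d", resume_from, start_epoch)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    records: list[EpochRecord] = []
    model.train()
    for epoch in range(start_epoch + 1, cfg.epochs + 1):
        samples = _epoch_samples(pairs, cfg, epoch)
        losses, dices = [], []
        for b0 in range(0, len(samples), cfg.batch_size):
            batch = samples[b0 : b0 + cfg.batch_size]
            x = np.stack([s[0] for s in batch])
            t = np.stack([s[1] for s in batch])[:, None]
            pred = model(x)
            loss = segmentation_loss(pred, t, cfg.bce_weight, cfg.dice_weight)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {b0 // cfg.batch_size}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
            dices.append(dice_score(t > 0.5, pred.data > 0.5))
        record = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)),
                             train_dice=float(np.mean(dices)), lr=cfg.learning_rate)
        records.append(record)
        log.info("epoch %d loss=%.4f dice=%.4f", epoch, record.train_loss,
                 record.train_dice)
        if out_dir is not None and (
                epoch % max(1, cfg.checkpoint_every) == 0 or epoch == cfg.epochs):
            save_checkpoint(out_dir / f"checkpoint_{epoch:04d}.npz", model,
                            optimizer, epoch)
            (out_dir / "history.json").write_text(
                json.dumps([asdict(r) for r in records], indent=2))
    return model, records


# -- prediction ------------------------------------------------------------


def _pad_to_multiple(img: np.ndarray, multiple: int = 32):
    _, h, w = img.shape
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph == 0 and pw == 0:
        return img, (0, 0)
    padded = np.pad(img, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return padded, (ph, pw)


def predict(model: GCUNet, images_dir, out_dir, threshold: float = 0.5,
            min_size: int = 10) -> dict:
    """Run the model over a directory; writes a probability map (32-bit
    TIFF), binary mask (PNG) and instance map (16-bit PNG) per image."""
    import imageio.v3 as iio
    import tifffile

    images_dir, out_dir = Path(images_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    image_files = sorted(
        p for p in images_dir.iterdir()
        if p.suffix.lower() in IMAGE_EXTS
        and not p.name.startswith(("inst_", "mask_", "prob_")))
    if not image_files:
        raise FileNotFoundError(f"no images found in {images_dir}")
    model.eval()
    entries = []
    for path in image_files:
        img = _read_image(path).astype(np.float32)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        img = img[..., :3]
        if img.max() > 1.0:
            img = img / 255.0
        chw = img.transpose(2, 0, 1)
        padded, (ph, pw) = _pad_to_multiple(chw)
        with nn.no_grad():
            prob = model(padded[None]).data[0, 0]
        h, w = chw.shape[1:]
        prob = prob[:h, :w]
        inst = extract_instances(prob, threshold=threshold, min_size=min_size)
        stem = path.stem
        if stem.startswith("image_"):  # keep synth-style numbering aligned
            stem = stem[len("image_"):]
        prob_name = f"prob_{stem}.tif"
        mask_name = f"mask_{stem}.png"
        inst_name = f"inst_{stem}.png"
        tifffile.imwrite(out_dir / prob_name, prob.astype(np.float32))
        iio.imwrite(out_dir / mask_name,
                    ((prob >= threshold) * 255).astype(np.uint8))
        iio.imwrite(out_dir / inst_name, inst.astype(np.uint16))
        entries.append({"image": path.name, "prob": prob_name, "mask": mask_name,
                        "instances": inst_name, "n_instances": int(inst.max())})
    manifest = {"threshold": threshold, "min_size": min_size, "outputs": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
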
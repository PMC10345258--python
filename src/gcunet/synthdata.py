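"""Seeded generator of smear-like microscopy scenes with exact ground truth.

Scenes contain rotated elliptical nuclei (dark purple on a pale pink field
by default), a controllable fraction of deliberately overlapping placements,
radial shading, faint background clutter, Gaussian texture noise, and a
Gaussian blur that softens nucleus boundaries. The instance map stays an
exact partition: on contested pixels the later id wins, while the rendered
image keeps the visual overlap.

All randomness derives from the spec-level seed through a counter-based
(Philox) stream keyed by ``(seed, scene_index)``, so any scene can be
regenerated independently and in parallel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage


@dataclass
class SceneSpec:
    height: int = 64
    width: int = 64
    n_nuclei: tuple[int, int] = (4, 8)
    radius_px: tuple[float, float] = (6.0, 11.0)
    eccentricity: tuple[float, float] = (0.0, 0.6)
    overlap_fraction: float = 0.25
    texture_noise_sd: float = 0.03
    blur_sigma_px: float = 0.8
    nucleus_rgb: tuple[float, float, float] = (0.36, 0.22, 0.47)  # dark purple
    background_rgb: tuple[float, float, float] = (0.93, 0.82, 0.86)  # pale pink
    clutter: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.n_nuclei
        if lo > hi or lo < 0:
            raise ValueError(f"invalid nucleus count range {self.n_nuclei}")
        rlo, rhi = self.radius_px
        if rlo > rhi or rlo <= 0:
            raise ValueError(f"invalid radius range {self.radius_px}")
        if 2 * rhi > min(self.height, self.width):
            raise ValueError(
                f"radius range {self.radius_px} does not fit a "
                f"{self.height}x{self.width} canvas")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0,1]")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self).items()}


@dataclass
class SyntheticSample:
    image: np.ndarray       # float32 (3,H,W) in [0,1]
    instances: np.ndarray   # int32 (H,W)
    binary: np.ndarray      # bool (H,W), == instances > 0
    clean_image: np.ndarray  # pre-noise render, used by consistency checks


def _scene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([seed, index])))


def _ellipse_mask(h, w, cy, cx, a, b, theta):
    """Boolean mask of a filled rotated ellipse, plus its bounding box."""
    r = max(a, b)
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    d2 = (u / a) ** 2 + (v / b) ** 2
    return d2 <= 1.0, d2, (y0, y1, x0, x1)


def generate_scene(spec: SceneSpec, index: int = 0) -> SyntheticSample:
    """Render one scene. ``index`` selects an independent stream from the
    same spec seed (scene i of a dataset)."""
    rng = _scene_rng(spec.seed, index)
    h, w = spec.height, spec.width
    n = int(rng.integers(spec.n_nuclei[0], spec.n_nuclei[1] + 1))
    instances = np.zeros((h, w), dtype=np.int32)
    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = spec.background_rgb

    placed = []  # (cy, cx, max_radius)
    for k in range(1, n + 1):
        a = rng.uniform(*spec.radius_px)
        ecc = rng.uniform(*spec.eccentricity)
        b = a * np.sqrt(1.0 - ecc ** 2)
        theta = rng.uniform(0.0, np.pi)
        overlap = bool(placed) and rng.random() < spec.overlap_fraction
        if overlap:
            oy, ox, orad = placed[int(rng.integers(len(placed)))]
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.3, 1.0) * 2 * orad  # within one diameter
            cy = float(np.clip(oy + dist * np.sin(ang), a, h - 1 - a))
            cx = float(np.clip(ox + dist * np.cos(ang), a, w - 1 - a))
        else:
            cy = cx = None
            for _ in range(60):
                ty = rng.uniform(a, h - 1 - a)
                tx = rng.uniform(a, w - 1 - a)
                if all((ty - py) ** 2 + (tx - px) ** 2 > (a + pr + 2) ** 2
                       for py, px, pr in placed):
                    cy, cx = ty, tx
                    break
            if cy is None:  # crowded canvas: accept the last try
                cy, cx = ty, tx
        placed.append((cy, cx, a))
        mask, d2, (y0, y1, x0, x1) = _ellipse_mask(h, w, cy, cx, a, b, theta)
        instances[y0:y1, x0:x1][mask] = k  # later id wins on contested pixels
        base = np.clip(np.asarray(spec.nucleus_rgb)
                       + rng.normal(0.0, 0.02, size=3), 0.0, 1.0)
        shade = (0.85 + 0.35 * d2[mask])[:, None]  # lighter toward the rim
        image[y0:y1, x0:x1][mask] = np.clip(base[None, :] * shade, 0.0, 1.0)

    clean = image.copy()

    if spec.clutter:  # faint debris blobs; background, never labelled
        for _ in range(int(rng.integers(0, 4))):
            ca = rng.uniform(1.5, 4.0)
            cyc = rng.uniform(ca, h - 1 - ca)
            cxc = rng.uniform(ca, w - 1 - ca)
            mask, _, (y0, y1, x0, x1) = _ellipse_mask(
                h, w, cyc, cxc, ca, ca * rng.uniform(0.5, 1.0),
                rng.uniform(0, np.pi))
            region = image[y0:y1, x0:x1]
            region[mask] = np.clip(region[mask] - rng.uniform(0.03, 0.10), 0, 1)

    if spec.texture_noise_sd > 0:
        image = image + rng.normal(0.0, spec.texture_noise_sd, size=image.shape)
    if spec.blur_sigma_px > 0:
        image = ndimage.gaussian_filter(
            image, sigma=(spec.blur_sigma_px, spec.blur_sigma_px, 0.0))
    image = np.clip(image, 0.0, 1.0)

    # keep only ids that survived occlusion, renumbered contiguously
    from .metrics import relabel_sequential
    instances = relabel_sequential(instances)

    return SyntheticSample(
        image=np.ascontiguousarray(image.transpose(2, 0, 1).astype(np.float32)),
        instances=instances,
        binary=instances > 0,
        clean_image=np.ascontiguousarray(clean.transpose(2, 0, 1).astype(np.float32)),
    )


def generate_dataset(spec: SceneSpec, n_images: int, out_dir) -> dict:
    """Write ``image_XXXX.png`` (8-bit RGB), ``inst_XXXX.png`` (16-bit) pairs
    and a ``manifest.json``; returns the manifest."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_images):
        sample = generate_scene(spec, index=i)
        img8 = np.round(sample.image.transpose(1, 2, 0) * 255).astype(np.uint8)
        n_inst = int(sample.instances.max())
        if n_inst > np.iinfo(np.uint16).max:
            raise ValueError(f"scene {i} has too many instances for 16-bit storage")
        img_name, inst_name = f"image_{i:04d}.png", f"inst_{i:04d}.png"
        try:
            iio.imwrite(out_dir / img_name, img8)
            iio.imwrite(out_dir / inst_name, sample.instances.astype(np.uint16))
        except OSError as exc:
            raise OSError(f"failed writing scene {i} under {out_dir}: {exc}") from exc
        entries.append({"index": i, "image": img_name, "instances": inst_name,
                        "n_nuclei": n_inst})
    manifest = {"spec": spec.to_dict(), "n_images": n_images, "images": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
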
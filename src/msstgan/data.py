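"""Synthetic slit-lamp-like data, preprocessing, augmentation and folds.

The generator emulates fluorescein-stained cornea photographs well enough
to exercise segmentation training end-to-end without any download: a dark
background, a centered cornea disk with a bluish-green base and smooth
shading, and bright-green lesions in three phenotypes —

* ``point_like``   — scattered tiny dots (unlabeled by default: in the
  real archive these lesions are too small to annotate),
* ``point_flaky``  — dots mixed with small patches,
* ``flaky``        — one or two large irregular blobs.

The mask is the exact lesion support before noise is added, so noiseless
renders are pixel-perfect. Lesion radii are specified at a 128-pixel
reference size and scale linearly with the requested size. No claim of
clinical realism is made; the lesion color model (green-channel dominance
inside the cornea) exists so the networks have signal to learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import transform as sktf

__all__ = [
    "PHENOTYPES", "SyntheticSample", "DatasetManifest",
    "generate_sample", "generate_dataset", "resize_bilinear", "resize_mask",
    "augment", "make_folds", "read_pair", "write_pair", "load_manifest",
]

PHENOTYPES = ("point_like", "point_flaky", "flaky")
_REFERENCE_SIZE = 128  # lesion radii below are stated at this image size


@dataclass
class SyntheticSample:
    image: np.ndarray                  # (H, W, 3) uint8
    mask: np.ndarray | None            # (H, W) uint8 {0,1}; present iff labeled
    phenotype: str
    seed: int

    @property
    def labeled(self) -> bool:
        return self.mask is not None


def _disk(shape, center, radius) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _check_size(size: int) -> None:
    if size < 64 or size % 32:
        raise ValueError(f"size must be >= 64 and divisible by 32, got {size}")


def generate_sample(phenotype: str, size: int = 128, seed: int = 0,
                    labeled: bool | None = None, noise: bool = True) -> SyntheticSample:
    """Render one synthetic image (and, if labeled, its exact mask).

    ``labeled`` defaults to the phenotype convention: ``point_like``
    samples are unlabeled, the other two phenotypes labeled. The mask is
    computed from the noiseless render, so it equals the lesion support
    pixel-perfectly.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}; expected one of {PHENOTYPES}")
    _check_size(size)
    if labeled is None:
        labeled = phenotype != "point_like"
    rng = np.random.default_rng(seed)
    s = size / _REFERENCE_SIZE

    # background: dark with mild smooth variation
    img = np.empty((size, size, 3), dtype=float)
    base = rng.uniform(8, 20)
    for ch in range(3):
        img[:, :, ch] = base + rng.uniform(0, 6)

    # cornea disk, bluish-green base with radial shading
    r_cornea = rng.uniform(0.35, 0.45) * size
    center = (size / 2 + rng.uniform(-0.02, 0.02) * size,
              size / 2 + rng.uniform(-0.02, 0.02) * size)
    cornea = _disk((size, size), center, r_cornea)
    yy, xx = np.mgrid[:size, :size]
    dist = np.sqrt((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / r_cornea
    shading = np.clip(1.15 - 0.35 * dist**2, 0.0, 1.2)
    cornea_rgb = np.array([rng.uniform(30, 55), rng.uniform(80, 110), rng.uniform(70, 100)])
    for ch in range(3):
        img[:, :, ch] = np.where(cornea, cornea_rgb[ch] * shading, img[:, :, ch])

    # lesions: union of disks, clipped to the cornea
    lesion = np.zeros((size, size), dtype=bool)

    def _centers(n, spread):
        ang = rng.uniform(0, 2 * np.pi, n)
        rad = rng.uniform(0, spread, n) * r_cornea
        return np.stack([center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang)], axis=1)

    if phenotype == "point_like":
        for cy, cx in _centers(rng.integers(3, 16), 0.8):
            lesion |= _disk((size, size), (cy, cx), max(1.0, rng.uniform(1, 2) * s))
    elif phenotype == "point_flaky":
        for cy, cx in _centers(rng.integers(3, 11), 0.8):
            lesion |= _disk((size, size), (cy, cx), max(1.0, rng.uniform(1, 2) * s))
        for cy, cx in _centers(rng.integers(1, 4), 0.5):
            lesion |= _disk((size, size), (cy, cx), rng.uniform(4, 10) * s)
    else:  # flaky: 1-2 irregular blobs, each a union of overlapping disks
        for _ in range(rng.integers(1, 3)):
            by, bx = _centers(1, 0.35)[0]
            cy, cx = by, bx
            blob = np.zeros_like(lesion)
            for _ in range(rng.integers(5, 16)):
                r = rng.uniform(8, 25) * s * 0.55
                blob |= _disk((size, size), (cy, cx), r)
                cy += rng.uniform(-6, 6) * s
                cx += rng.uniform(-6, 6) * s
            # light smoothing rounds the disk-union silhouette
            blob = ndi.gaussian_filter(blob.astype(float), sigma=1.0 * s) > 0.5
            lesion |= blob
    lesion &= _disk((size, size), center, r_cornea * 0.95)

    # fluorescent green lesion coloring with mild internal variation
    glow = rng.uniform(0.85, 1.0, (size, size))
    lesion_rgb = (rng.uniform(70, 110), rng.uniform(200, 240), rng.uniform(50, 90))
    for ch, val in enumerate(lesion_rgb):
        img[:, :, ch] = np.where(lesion, val * glow, img[:, :, ch])

    mask = lesion.astype(np.uint8)

    if noise:
        img *= rng.uniform(0.9, 1.1)                       # brightness jitter
        img += rng.normal(0.0, 5.0, img.shape)             # sensor noise
    img = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSample(image=img, mask=mask if labeled else None,
                           phenotype=phenotype, seed=seed)


# ---------------------------------------------------------------------------
# preprocessing


def resize_bilinear(image: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize of an (H, W, 3) or (H, W) image to target x target."""
    if target_size % 32:
        raise ValueError(f"target size must be divisible by 32, got {target_size}")
    pil = Image.fromarray(image)
    out = pil.resize((target_size, target_size), Image.BILINEAR)
    return np.asarray(out)


def resize_mask(mask: np.ndarray, target_size: int) -> np.ndarray:
    """Nearest-neighbor mask resize, re-binarized so values stay in {0,1}."""
    if target_size % 32:
        raise ValueError(f"target size must be divisible by 32, got {target_size}")
    pil = Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255)
    out = np.asarray(pil.resize((target_size, target_size), Image.NEAREST))
    return (out > 127).astype(np.uint8)


# ---------------------------------------------------------------------------
# augmentation


def augment(sample: SyntheticSample, seed: int = 0) -> SyntheticSample:
    """Online augmentation: each transform applied with probability 0.5.

    Rotation uniform in [-10, 10] degrees, horizontal flip, vertical flip,
    additive Gaussian noise, and a small affine (scale 0.9-1.1, translation
    up to 5%). The identical geometric transform is applied to image and
    mask; the mask stays binary (nearest-neighbor interpolation).
    """
    rng = np.random.default_rng(seed)
    img = sample.image.astype(float)
    mask = None if sample.mask is None else sample.mask.astype(float)

    def _warp_pair(tform_or_angle, rotate=False):
        nonlocal img, mask
        if rotate:
            img = sktf.rotate(img, tform_or_angle, order=1, preserve_range=True)
            if mask is not None:
                mask = sktf.rotate(mask, tform_or_angle, order=0, preserve_range=True)
        else:
            img = sktf.warp(img, tform_or_angle.inverse, order=1, preserve_range=True)
            if mask is not None:
                mask = sktf.warp(mask, tform_or_angle.inverse, order=0, preserve_range=True)

    if rng.random() < 0.5:
        _warp_pair(rng.uniform(-10, 10), rotate=True)
    if rng.random() < 0.5:
        img = img[:, ::-1].copy()
        if mask is not None:
            mask = mask[:, ::-1].copy()
    if rng.random() < 0.5:
        img = img[::-1].copy()
        if mask is not None:
            mask = mask[::-1].copy()
    if rng.random() < 0.5:
        img = img + rng.normal(0, 5, img.shape)
    if rng.random() < 0.5:
        h, w = img.shape[:2]
        scale = rng.uniform(0.9, 1.1)
        trans = (rng.uniform(-0.05, 0.05) * w, rng.uniform(-0.05, 0.05) * h)
        center_shift = np.array([w, h]) / 2.0
        tform = (sktf.SimilarityTransform(translation=-center_shift)
                 + sktf.SimilarityTransform(scale=scale)
                 + sktf.SimilarityTransform(translation=center_shift + trans))
        _warp_pair(tform)

    out_img = np.clip(img, 0, 255).astype(np.uint8)
    out_mask = None if mask is None else (mask > 0.5).astype(np.uint8)
    return SyntheticSample(image=out_img, mask=out_mask,
                           phenotype=sample.phenotype, seed=sample.seed)


# ---------------------------------------------------------------------------
# fold bookkeeping


def make_folds(ids, k: int = 4, sizes=None, seed: int = 0) -> dict:
    """Seeded partition of ids into k folds.

    With 354 ids and k=4 and no explicit sizes, the historical split sizes
    90/90/90/84 are applied; otherwise a near-equal split. Returns a
    mapping id -> fold index in [0, k).
    """
    ids = list(ids)
    n = len(ids)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if sizes is None:
        if n == 354 and k == 4:
            sizes = [90, 90, 90, 84]
        else:
            base, extra = divmod(n, k)
            sizes = [base + (1 if i < extra else 0) for i in range(k)]
    if len(sizes) != k or sum(sizes) != n:
        raise ValueError(f"fold sizes {sizes} do not partition {n} ids into {k} folds")
    order = list(np.random.default_rng(seed).permutation(n))
    assignment: dict = {}
    pos = 0
    for fold, sz in enumerate(sizes):
        for idx in order[pos : pos + sz]:
            assignment[ids[idx]] = fold
        pos += sz
    return assignment


# ---------------------------------------------------------------------------
# PNG I/O and the dataset manifest


def write_pair(sample: SyntheticSample, image_path, mask_path=None) -> None:
    """Write image (8-bit RGB PNG) and, if labeled, mask ({0,255} PNG)."""
    Image.fromarray(sample.image).save(image_path)
    if sample.mask is not None:
        if mask_path is None:
            raise ValueError("labeled sample needs a mask path")
        Image.fromarray((sample.mask * 255).astype(np.uint8)).save(mask_path)


def read_pair(image_path, mask_path=None, phenotype: str = "flaky",
              seed: int = -1) -> SyntheticSample:
    """Lossless PNG round-trip loader; masks must be strictly {0, 255}."""
    image_path = Path(image_path)
    if not image_path.exists():
        raise FileNotFoundError(f"image file not found: {image_path}")
    image = np.asarray(Image.open(image_path).convert("RGB"))
    mask = None
    if mask_path is not None:
        mask_path = Path(mask_path)
        if not mask_path.exists():
            raise FileNotFoundError(f"mask file not found: {mask_path}")
        raw = np.asarray(Image.open(mask_path).convert("L"))
        bad = ~np.isin(raw, (0, 255))
        if bad.any():
            raise ValueError(
                f"mask {mask_path} is not binary: contains values "
                f"{sorted(np.unique(raw[bad]))[:5]}")
        mask = (raw == 255).astype(np.uint8)
    return SyntheticSample(image=image, mask=mask, phenotype=phenotype, seed=seed)


@dataclass
class DatasetManifest:
    """Bookkeeping for a generated dataset (paths, folds, seeds)."""

    root: str
    size: int
    master_seed: int
    labeled: list = field(default_factory=list)     # dicts: id, image, mask, phenotype, seed, fold
    unlabeled: list = field(default_factory=list)   # dicts: id, image, phenotype, seed

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))

    def fold_ids(self, fold: int) -> list:
        return [e["id"] for e in self.labeled if e["fold"] == fold]

    def load_labeled(self, ids=None) -> list[SyntheticSample]:
        entries = self.labeled if ids is None else [e for e in self.labeled if e["id"] in set(ids)]
        root = Path(self.root)
        return [read_pair(root / e["image"], root / e["mask"],
                          phenotype=e["phenotype"], seed=e["seed"]) for e in entries]

    def load_unlabeled(self) -> list[SyntheticSample]:
        root = Path(self.root)
        return [read_pair(root / e["image"], None, phenotype=e["phenotype"],
                          seed=e["seed"]) for e in self.unlabeled]


def load_manifest(path) -> DatasetManifest:
    payload = json.loads(Path(path).read_text())
    return DatasetManifest(**payload)


def _child_seeds(master_seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def generate_dataset(n_labeled: int, n_unlabeled: int, size: int,
                     master_seed: int, outdir) -> DatasetManifest:
    """Generate and write a labeled + unlabeled synthetic dataset.

    Labeled samples are drawn from the ``point_flaky`` and ``flaky``
    phenotypes; the unlabeled subset is all ``point_like``. Regenerating
    with the same master seed reproduces byte-identical files.
    """
    if n_labeled < 4:
        raise ValueError("need at least 4 labeled images (one per fold)")
    _check_size(size)
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)

    seeds = _child_seeds(master_seed, n_labeled + n_unlabeled + 1)
    pheno_rng = np.random.default_rng(seeds[-1])
    manifest = DatasetManifest(root=str(outdir), size=size, master_seed=master_seed)

    folds = make_folds(list(range(n_labeled)), k=4, seed=master_seed)
    for i in range(n_labeled):
        phenotype = str(pheno_rng.choice(["point_flaky", "flaky"]))
        sample = generate_sample(phenotype, size=size, seed=seeds[i])
        img_rel, mask_rel = f"images/labeled_{i:04d}.png", f"masks/labeled_{i:04d}.png"
        write_pair(sample, outdir / img_rel, outdir / mask_rel)
        manifest.labeled.append({"id": i, "image": img_rel, "mask": mask_rel,
                                 "phenotype": phenotype, "seed": seeds[i],
                                 "fold": folds[i]})
    for j in range(n_unlabeled):
        sample = generate_sample("point_like", size=size, seed=seeds[n_labeled + j])
        img_rel = f"images/unlabeled_{j:04d}.png"
        write_pair(sample, outdir / img_rel)
        manifest.unlabeled.append({"id": n_labeled + j, "image": img_rel,
                                   "phenotype": "point_like",
                                   "seed": seeds[n_labeled + j]})
    manifest.save(outdir / "manifest.json")
    return manifest
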
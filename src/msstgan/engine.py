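"""Training and evaluation engine for the two-branch adversarial protocol.

Each semi-supervised iteration draws one labeled and one unlabeled batch
and applies, in strict alternation:

* a supervised step — segmentor update minimizing BCE + Dice + adversarial
  (discriminator frozen), then a discriminator update on (image, detached
  prediction) fake pairs and (image, ground truth) real pairs;
* an unsupervised step — segmentor update minimizing the adversarial term
  only, then a fake-only discriminator update (no ground truth exists for
  these images).

Generator and discriminator hold disjoint parameter sets with one Adam
optimizer each; update order is G then D, one step each. Everything is
seeded, so identical (config, seed, data) reproduce identical loss curves.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import objectives
from .data import DatasetManifest, augment, read_pair
from .metrics import MetricReport, binarize, evaluate_set
from .networks import (DiscriminatorSpec, EncoderSpec, PatchDiscriminator,
                       Segmentor, build_discriminator, build_segmentor,
                       discriminate, segment)
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig", "RunRecord", "supervised_step", "unsupervised_step",
    "train", "train_on_samples", "cross_validate", "evaluate",
    "images_to_batch", "masks_to_batch", "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    """Hyperparameters; defaults are the full-scale training setting."""

    learning_rate: float = 0.0005
    d_learning_rate: float | None = None   # discriminator lr; defaults to learning_rate
    weight_decay: float = 0.0001
    batch_size: int = 4
    epochs: int = 100
    steps_per_epoch: int | None = None     # None: one sweep over the labeled set
    mode: str = "semi"                 # "supervised" | "semi"
    seed: int = 0
    image_size: int = 512
    encoder_scale: str = "full"        # "full" | "tiny"
    bce_weight: float = 1.0
    dice_weight: float = 1.0
    adv_weight: float = 1.0
    threshold: float = 0.5
    augment: bool = True
    transposed_decoder: bool = False
    resample_real_for_unlabeled: bool = False
    warmup_epochs: int = 0             # epochs before unlabeled steps begin
    select: str = "best"               # "best" (val Dice) | "last"
    val_fraction: float = 0.25

    def __post_init__(self):
        if self.mode not in ("supervised", "semi"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.encoder_scale not in ("full", "tiny"):
            raise ValueError(f"unknown encoder scale {self.encoder_scale!r}")
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """CPU-scale smoke profile: 64 px, small channel plan, 10 epochs of
        16 iterations each (on few-image sets an epoch is a fixed iteration
        count, not one sweep), a from-scratch learning rate, a slower
        discriminator so it does not overpower the segmentor in so few
        steps, and augmentation off for determinism of the short runs."""
        base = dict(learning_rate=0.02, d_learning_rate=1e-4, epochs=10,
                    steps_per_epoch=16, image_size=64, encoder_scale="tiny",
                    augment=False)
        base.update(overrides)
        return cls(**base)

    @property
    def loss_weights(self) -> objectives.LossWeights:
        return objectives.LossWeights(bce=self.bce_weight, dice=self.dice_weight,
                                      adv=self.adv_weight)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "TrainConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


@dataclass
class RunRecord:
    """Per-epoch loss history plus the final validation metric report."""

    config: dict
    epoch_losses: list = field(default_factory=list)
    val_dice: list = field(default_factory=list)
    best_epoch: int = -1
    report: dict | None = None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


# ---------------------------------------------------------------------------
# batching helpers


def images_to_batch(images) -> Tensor:
    """(N, H, W, 3) uint8 images -> (N, 3, H, W) float tensor in [0, 1]."""
    arr = np.asarray(images, dtype=np.float64) / 255.0
    return Tensor(arr.transpose(0, 3, 1, 2))


def masks_to_batch(masks) -> Tensor:
    """(N, H, W) binary masks -> (N, 1, H, W) float tensor."""
    arr = np.asarray(masks, dtype=np.float64)[:, None]
    return Tensor(arr)


# ---------------------------------------------------------------------------
# the two step types (Fig. 2's two branches)


def supervised_step(g: Segmentor, d: PatchDiscriminator, batch, cfg: TrainConfig,
                    opt_g: Adam, opt_d: Adam) -> dict:
    """One labeled iteration: G minimizes the joint loss with D frozen,
    then D is updated on fake (detached prediction) and real pairs."""
    images, masks = batch
    if masks is None:
        raise ValueError("supervised step requires masks")
    # -- generator update (D frozen: its gradients are discarded)
    pred = g(images)
    fake_scores = discriminate(d, images, pred)
    bce = objectives.bce_loss(pred, masks)
    dice = objectives.dice_loss(pred, masks)
    adv = objectives.adversarial_loss(fake_scores)
    w = cfg.loss_weights
    l_joint = w.bce * bce + w.dice * dice + w.adv * adv
    opt_g.zero_grad()
    opt_d.zero_grad()
    l_joint.backward()
    opt_g.step()
    # -- discriminator update (G frozen via detached prediction)
    fake_scores_d = discriminate(d, images, pred.detach())
    real_scores = discriminate(d, images, masks)
    l_d = objectives.discriminator_loss(fake_scores_d, real_scores)
    opt_d.zero_grad()
    opt_g.zero_grad()
    l_d.backward()
    opt_d.step()
    return {"bce": bce.item(), "dice": dice.item(), "adv": adv.item(),
            "joint": l_joint.item(), "d": l_d.item()}


def unsupervised_step(g: Segmentor, d: PatchDiscriminator, batch, cfg: TrainConfig,
                      opt_g: Adam, opt_d: Adam, real_batch=None) -> dict:
    """One unlabeled iteration: G minimizes the adversarial term only; D is
    updated on the fake pairs (optionally balanced with labeled real pairs
    when ``cfg.resample_real_for_unlabeled`` is set)."""
    images, masks = batch if isinstance(batch, tuple) else (batch, None)
    if masks is not None:
        warnings.warn("unsupervised step received masks; they are ignored",
                      stacklevel=2)
    pred = g(images)
    fake_scores = discriminate(d, images, pred)
    l_adv = objectives.adversarial_loss(fake_scores)
    opt_g.zero_grad()
    opt_d.zero_grad()
    l_adv.backward()
    opt_g.step()

    fake_scores_d = discriminate(d, images, pred.detach())
    real_scores = None
    if cfg.resample_real_for_unlabeled and real_batch is not None:
        real_images, real_masks = real_batch
        real_scores = discriminate(d, real_images, real_masks)
    l_d = objectives.discriminator_loss(fake_scores_d, real_scores)
    opt_d.zero_grad()
    opt_g.zero_grad()
    l_d.backward()
    opt_d.step()
    return {"adv_unlabeled": l_adv.item(), "d_unlabeled": l_d.item()}


# ---------------------------------------------------------------------------
# training


def _build_models(cfg: TrainConfig):
    if cfg.encoder_scale == "tiny":
        enc, dsc_spec = EncoderSpec.tiny(), DiscriminatorSpec.tiny()
    else:
        enc, dsc_spec = EncoderSpec(), DiscriminatorSpec()
    g = build_segmentor(enc, seed=cfg.seed, transposed_decoder=cfg.transposed_decoder)
    d = build_discriminator(dsc_spec, seed=cfg.seed + 1)
    g_params, d_params = list(g.parameters()), list(d.parameters())
    assert not set(map(id, g_params)) & set(map(id, d_params))
    d_lr = cfg.d_learning_rate if cfg.d_learning_rate is not None else cfg.learning_rate
    opt_g = Adam(g_params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    opt_d = Adam(d_params, lr=d_lr, weight_decay=cfg.weight_decay)
    return g, d, opt_g, opt_d


def _mean_dice(g: Segmentor, samples, threshold: float) -> float:
    probs = segment(g, images_to_batch([s.image for s in samples]))
    report = evaluate_set([p[0] for p in probs], [s.mask for s in samples],
                          threshold=threshold)
    return report.mean("dsc")


def _batches(samples, batch_size, rng, augment_flag, steps=None):
    if steps is None:
        order = list(rng.permutation(len(samples)))
        starts = range(0, len(samples), batch_size)
        chunks = [[samples[i] for i in order[s : s + batch_size]] for s in starts]
    else:  # fixed iteration count: sample batches with replacement
        chunks = [[samples[i] for i in rng.integers(0, len(samples), batch_size)]
                  for _ in range(steps)]
    for chunk in chunks:
        if augment_flag:
            chunk = [augment(s, seed=int(rng.integers(2**31))) for s in chunk]
        yield chunk


def train_on_samples(labeled, unlabeled, cfg: TrainConfig, val=None):
    """Core loop over in-memory samples.

    Returns ``(segmentor, discriminator, RunRecord)``; the returned
    segmentor carries the selected (best-validation-Dice or last) weights.
    """
    if not labeled:
        raise ValueError("training requires labeled samples")
    if cfg.mode == "semi" and not unlabeled:
        raise ValueError("semi mode requires unlabeled samples; use mode='supervised'")
    if any(s.mask is None for s in labeled):
        raise ValueError("labeled samples must all carry masks")
    rng = np.random.default_rng(cfg.seed)
    if val is None:
        n_val = max(1, int(round(cfg.val_fraction * len(labeled))))
        order = rng.permutation(len(labeled))
        val = [labeled[i] for i in order[:n_val]]
        labeled = [labeled[i] for i in order[n_val:]]
    g, d, opt_g, opt_d = _build_models(cfg)
    record = RunRecord(config=cfg.to_dict())
    best_dice, best_state = -1.0, None
    unlabeled_pool = list(unlabeled or [])
    u_idx = 0
    for epoch in range(cfg.epochs):
        g.train(), d.train()
        epoch_log: dict[str, list[float]] = {}
        for chunk in _batches(labeled, cfg.batch_size, rng, cfg.augment,
                              steps=cfg.steps_per_epoch):
            batch = (images_to_batch([s.image for s in chunk]),
                     masks_to_batch([s.mask for s in chunk]))
            losses = supervised_step(g, d, batch, cfg, opt_g, opt_d)
            if cfg.mode == "semi" and epoch >= cfg.warmup_epochs:
                u_chunk = []
                for _ in range(min(cfg.batch_size, len(unlabeled_pool))):
                    u_chunk.append(unlabeled_pool[u_idx % len(unlabeled_pool)])
                    u_idx += 1
                if cfg.augment:
                    u_chunk = [augment(s, seed=int(rng.integers(2**31))) for s in u_chunk]
                u_batch = (images_to_batch([s.image for s in u_chunk]), None)
                real = batch if cfg.resample_real_for_unlabeled else None
                losses.update(unsupervised_step(g, d, u_batch, cfg, opt_g, opt_d,
                                                real_batch=real))
            for k, v in losses.items():
                epoch_log.setdefault(k, []).append(v)
        means = {k: float(np.mean(v)) for k, v in epoch_log.items()}
        if not all(np.isfinite(list(means.values()))):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}: {means}")
        record.epoch_losses.append(means)
        vd = _mean_dice(g, val, cfg.threshold)
        record.val_dice.append(vd)
        if vd > best_dice:
            best_dice, best_state = vd, g.state_dict()
            record.best_epoch = epoch
    if cfg.select == "best" and best_state is not None:
        g.load_state_dict(best_state)
    probs = segment(g, images_to_batch([s.image for s in val]))
    final = evaluate_set([p[0] for p in probs], [s.mask for s in val],
                         threshold=cfg.threshold)
    record.report = {m: {"mean": final.mean(m), "std": final.std(m)}
                     for m in final.METRICS}
    return g, d, record


def train(manifest: DatasetManifest, cfg: TrainConfig, train_ids=None,
          val_ids=None, run_dir=None):
    """Train from a dataset manifest; optionally persist record + weights."""
    labeled_ids = [e["id"] for e in manifest.labeled]
    if train_ids is None:
        train_ids = labeled_ids
    labeled = manifest.load_labeled(train_ids)
    val = manifest.load_labeled(val_ids) if val_ids is not None else None
    unlabeled = manifest.load_unlabeled() if cfg.mode == "semi" else []
    g, d, record = train_on_samples(labeled, unlabeled, cfg, val=val)
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        record.to_json(run_dir / "record.json")
        save_checkpoint(g, run_dir / "segmentor.npz")
        save_checkpoint(d, run_dir / "discriminator.npz")
        _losses_csv(record, run_dir / "losses.csv")
    return g, d, record


def _losses_csv(record: RunRecord, path) -> None:
    import csv

    keys = sorted({k for row in record.epoch_losses for k in row})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", *keys, "val_dice"])
        for i, row in enumerate(record.epoch_losses):
            writer.writerow([i, *(f"{row.get(k, float('nan')):.6f}" for k in keys),
                             f"{record.val_dice[i]:.6f}"])


def cross_validate(manifest: DatasetManifest, cfg: TrainConfig, k: int = 4):
    """k-fold cross-validation over the manifest's fold assignment.

    Each model trains on k-1 folds and is validated/evaluated on its
    held-out fold; returns per-fold run records plus the pooled report.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    records, pooled_preds, pooled_gts = [], [], []
    unlabeled = manifest.load_unlabeled() if cfg.mode == "semi" else []
    for fold in range(k):
        held = manifest.fold_ids(fold)
        rest = [e["id"] for e in manifest.labeled if e["fold"] != fold]
        if not held or not rest:
            raise ValueError(f"fold {fold} is empty or exhausts the data")
        train_samples = manifest.load_labeled(rest)
        val_samples = manifest.load_labeled(held)
        g, _, record = train_on_samples(train_samples, unlabeled,
                                        replace(cfg, seed=cfg.seed + fold),
                                        val=val_samples)
        records.append(record)
        probs = segment(g, images_to_batch([s.image for s in val_samples]))
        pooled_preds.extend(p[0] for p in probs)
        pooled_gts.extend(s.mask for s in val_samples)
    pooled = evaluate_set(pooled_preds, pooled_gts, threshold=cfg.threshold)
    return records, pooled


# ---------------------------------------------------------------------------
# checkpoints and directory evaluation


def save_checkpoint(model, path) -> None:
    np.savez(path, **model.state_dict())


def load_checkpoint(model, path):
    with np.load(path) as payload:
        model.load_state_dict({k: payload[k] for k in payload.files})
    return model


def _overlay(image: np.ndarray, pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """Error overlay: yellow = correct lesion, red = false positive,
    blue = false negative."""
    out = image.copy()
    p, g = pred.astype(bool), gt.astype(bool)
    out[p & g] = (255, 255, 0)
    out[p & ~g] = (255, 0, 0)
    out[~p & g] = (0, 0, 255)
    return out


def evaluate(model: Segmentor, image_dir, mask_dir, threshold: float = 0.5,
             report_path=None, overlay_dir=None) -> MetricReport:
    """Segment every image in ``image_dir`` and score against ``mask_dir``.

    Files are paired by identical filename; unpaired files on either side
    are an error listing the orphans.
    """
    from PIL import Image

    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    images = {p.name: p for p in sorted(image_dir.glob("*.png"))}
    masks = {p.name: p for p in sorted(mask_dir.glob("*.png"))}
    orphans = sorted(set(images) ^ set(masks))
    if orphans:
        raise ValueError(f"unpaired files between {image_dir} and {mask_dir}: {orphans}")
    if not images:
        raise ValueError(f"no PNG files found in {image_dir}")
    preds, gts, names = [], [], []
    for name in sorted(images):
        sample = read_pair(images[name], masks[name])
        prob = segment(model, images_to_batch([sample.image]))[0, 0]
        preds.append(prob)
        gts.append(sample.mask)
        names.append(name)
        if overlay_dir is not None:
            overlay_dir = Path(overlay_dir)
            overlay_dir.mkdir(parents=True, exist_ok=True)
            ov = _overlay(sample.image, binarize(prob, threshold), sample.mask)
            Image.fromarray(ov).save(overlay_dir / name)
    report = evaluate_set(preds, gts, threshold=threshold)
    if report_path is not None:
        report_path = Path(report_path)
        report.to_json(report_path.with_suffix(".json"))
        report.to_csv(report_path.with_suffix(".csv"))
    return report
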
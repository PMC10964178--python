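"""Alternating minmax training of the two generators and two discriminators.

Each optimisation step draws an unpaired OCT batch and H&E batch, updates
the generators (including their SCPA heads) on the generator-side total
loss, then updates the discriminators on the least-squares discriminator
loss with detached fakes.  The learning rate starts at ``lr0`` and decays
linearly to zero in blocks of ``decay_every`` epochs.  All randomness
(batch order, flips) flows from a single seeded generator, so a fixed seed
reproduces a run bit-for-bit in single-threaded execution.

One epoch is one pass over the union of manifest rows:
``ceil(n_rows / batch_size)`` steps, each domain cycling through its own
shuffled queue (reshuffled on exhaustion) so the pairing of OCT and H&E
images is random and independent.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .ctgen import Generator, GeneratorConfig
from .losses import (Discriminator, LossBreakdown, LossWeights,
                     adversarial_loss_from_scores, pa_loss, sc_loss,
                     total_loss, LOSS_CSV_COLUMNS)
from .nn import Adam, Tensor
from .phantom import PhantomSample, load_manifest, load_sample_arrays

__all__ = [
    "TrainConfig", "Batch", "ModelBundle", "lr_at", "train_step", "fit",
    "save_checkpoint", "load_checkpoint",
    "pathology_accuracy", "segmentation_accuracy", "palette_layer_matches",
]

CHECKPOINT_FORMAT_VERSION = 1
BACKGROUND_CLASS = 3


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule and loss weights."""

    batch_size: int = 9
    lr0: float = 1e-4
    decay_every: int = 2
    epochs: int = 10_000
    weights: LossWeights = field(default_factory=LossWeights)
    flip_augment: bool = True
    seed: int = 0
    checkpoint_every: int = 0          # steps; 0 = final checkpoint only
    image_size: int = 64
    use_fake_pool: bool = False        # optional CycleGAN-style history pool
    fake_pool_size: int = 50

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.decay_every < 1 or self.epochs < 1:
            raise ValueError("decay_every and epochs must be at least 1")

    def to_text(self) -> str:
        d = asdict(self)
        w = d.pop("weights")
        d.update(w)
        return "".join(f"{k}: {v}\n" for k, v in d.items())

    @classmethod
    def from_text(cls, text: str) -> "TrainConfig":
        import yaml
        raw = yaml.safe_load(text) or {}
        wkeys = {k: float(raw.pop(k)) for k in ("alpha", "beta", "gamma", "iota")
                 if k in raw}
        return cls(weights=LossWeights(**wkeys), **raw)


def lr_at(epoch: int, config: TrainConfig) -> float:
    """Piecewise-constant linear ramp from lr0 to 0 over the horizon."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    n_blocks = math.ceil(config.epochs / config.decay_every)
    block = epoch // config.decay_every
    return config.lr0 * max(0.0, 1.0 - block / n_blocks)


@dataclass
class Batch:
    """One domain's mini-batch: images plus optional supervision.

    ``masks`` uses layer codes {0, 1, 2, 3}; samples without a pixel mask
    carry -1 everywhere.  ``labels`` are image-level pathology labels.
    """

    images: np.ndarray                    # (B, C, H, W) float32 in [0, 1]
    masks: np.ndarray | None = None       # (B, H, W) int, -1 = unlabeled
    labels: np.ndarray | None = None      # (B,) in {0, 1}


@dataclass
class ModelBundle:
    """Both generators (with SCPA heads), both discriminators, optimizers."""

    g_oh: Generator
    g_ho: Generator
    d_h: Discriminator
    d_o: Discriminator
    opt_g: Adam
    opt_d: Adam

    @classmethod
    def create(cls, config_oh: GeneratorConfig, seed: int,
               lr: float = 1e-4, d_width: int = 8) -> "ModelBundle":
        """Deterministic initialisation; the H&E->OCT generator mirrors the
        OCT->H&E config with channels swapped."""
        config_ho = replace(config_oh, in_channels=config_oh.out_channels,
                            out_channels=config_oh.in_channels)
        rngs = [np.random.default_rng([seed, i]) for i in range(4)]
        g_oh = Generator(config_oh, rngs[0])
        g_ho = Generator(config_ho, rngs[1])
        d_h = Discriminator(config_oh.out_channels, rngs[2], base_width=d_width)
        d_o = Discriminator(config_oh.in_channels, rngs[3], base_width=d_width)
        opt_g = Adam(g_oh.parameters() + g_ho.parameters(), lr=lr)
        opt_d = Adam(d_h.parameters() + d_o.parameters(), lr=lr)
        return cls(g_oh, g_ho, d_h, d_o, opt_g, opt_d)

    def set_lr(self, lr: float) -> None:
        self.opt_g.lr = lr
        self.opt_d.lr = lr

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.data).sum() for p in
                         self.opt_g.params + self.opt_d.params))


def _masked_sc(scpa_out, masks: np.ndarray | None) -> Tensor:
    if scpa_out is None or masks is None:
        return Tensor(0.0)
    valid = (masks >= 0) & (masks != BACKGROUND_CLASS)
    if not valid.any():
        return Tensor(0.0)
    labels = np.where(valid, masks, 0)
    return sc_loss(scpa_out.segmentation, labels, valid)


def train_step(batch_o: Batch, batch_h: Batch, models: ModelBundle,
               config: TrainConfig) -> LossBreakdown:
    """One alternating minmax step; returns the generator-side breakdown."""
    w = config.weights
    xo = Tensor(batch_o.images)
    xh = Tensor(batch_h.images)

    # ---- generator-side pass ----
    out_oh = models.g_oh(xo)                    # OCT -> fake H&E
    out_ho = models.g_ho(xh)                    # H&E -> fake OCT
    fake_h, fake_o = out_oh.translated, out_ho.translated
    cyc_o = models.g_ho(fake_h).translated      # OCT -> H&E -> OCT
    cyc_h = models.g_oh(fake_o).translated      # H&E -> OCT -> H&E

    g_adv_h, _ = adversarial_loss_from_scores(Tensor(0.0), models.d_h(fake_h))
    g_adv_o, _ = adversarial_loss_from_scores(Tensor(0.0), models.d_o(fake_o))
    cycle = (cyc_o - xo).abs().mean() + (cyc_h - xh).abs().mean()
    embedding = ((out_oh.bottleneck - models.g_oh.embed(cyc_o)).abs().mean()
                 + (out_ho.bottleneck - models.g_ho.embed(cyc_h)).abs().mean())
    sc = _masked_sc(out_oh.scpa, batch_o.masks) + _masked_sc(out_ho.scpa, batch_h.masks)
    pa = Tensor(0.0)
    if batch_o.labels is not None:
        pa = pa + pa_loss(out_oh.scpa.pathology_score, batch_o.labels)
    if batch_h.labels is not None:
        pa = pa + pa_loss(out_ho.scpa.pathology_score, batch_h.labels)

    g_total = (g_adv_h + g_adv_o + w.alpha * cycle + w.beta * embedding
               + w.gamma * sc + w.iota * pa)
    if not np.isfinite(g_total.data):
        for name, term in (("adv_H", g_adv_h), ("adv_O", g_adv_o),
                           ("cycle", cycle), ("embedding", embedding),
                           ("sc", sc), ("pa", pa)):
            if not np.isfinite(term.data):
                raise FloatingPointError(f"loss term '{name}' is not finite")
    models.opt_g.zero_grad()
    models.opt_d.zero_grad()
    g_total.backward()
    models.opt_g.step()

    # ---- discriminator-side pass (detached fakes) ----
    _, d_h_loss = adversarial_loss_from_scores(models.d_h(xh),
                                               models.d_h(fake_h.detach()))
    _, d_o_loss = adversarial_loss_from_scores(models.d_o(xo),
                                               models.d_o(fake_o.detach()))
    models.opt_d.zero_grad()
    (d_h_loss + d_o_loss).backward()
    models.opt_d.step()

    breakdown = total_loss(g_adv_h.item(), g_adv_o.item(), cycle.item(),
                           embedding.item(), sc.item(), pa.item(), w)
    assert breakdown.verify(w, tol=1e-6 * max(1.0, abs(breakdown.total)))
    return breakdown


# -- data plumbing ----------------------------------------------------------

class _DomainQueue:
    """Shuffled without-replacement cycling over one domain's sample indices."""

    def __init__(self, n: int, rng: np.random.Generator):
        if n == 0:
            raise ValueError("domain has zero images")
        self.n = n
        self.rng = rng
        self.order = rng.permutation(n)
        self.pos = 0

    def take(self, k: int) -> np.ndarray:
        out = []
        while k > 0:
            avail = self.n - self.pos
            grab = min(k, avail)
            out.append(self.order[self.pos:self.pos + grab])
            self.pos += grab
            k -= grab
            if self.pos == self.n:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
        return np.concatenate(out)


def _load_domain(manifest_path, rows, channels: int):
    images, masks, labels = [], [], []
    for row in rows:
        img, mask = load_sample_arrays(manifest_path, row)
        if img.ndim == 2:
            img = img[..., None]
        if img.shape[2] != channels:
            raise ValueError(f"{row['path']}: expected {channels} channels")
        images.append(img.transpose(2, 0, 1))
        masks.append(mask if mask is not None
                     else np.full(img.shape[:2], -1, dtype=np.int16))
        labels.append(row["pathology_label"])
    return (np.stack(images).astype(np.float32),
            np.stack(masks).astype(np.int16),
            np.array(labels, dtype=np.float32))


def _make_batch(images, masks, labels, idx, flip: np.ndarray) -> Batch:
    imgs = images[idx].copy()
    msks = masks[idx].copy()
    for j, f in enumerate(flip):
        if f:
            imgs[j] = imgs[j, :, :, ::-1]
            msks[j] = msks[j, :, ::-1]
    return Batch(images=imgs, masks=msks, labels=labels[idx])


def fit(manifest_path, config: TrainConfig, out_dir,
        models: ModelBundle | None = None,
        generator_config: GeneratorConfig | None = None,
        max_steps: int | None = None,
        resume_from: str | Path | None = None):
    """Train on a manifest dataset; write checkpoints and a loss CSV.

    Returns ``(models, rows)`` where ``rows`` are the per-step loss CSV
    records.  ``resume_from`` restores parameters, optimizer state, RNG
    state and step counter, making an interrupted run bit-identical to an
    uninterrupted one.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(manifest_path)
    rows_all = load_manifest(manifest_path)
    rows_o = [r for r in rows_all if r["domain"] == "oct"]
    rows_h = [r for r in rows_all if r["domain"] == "he"]
    if not rows_o or not rows_h:
        raise ValueError("both domains must be non-empty")

    gen_cfg = generator_config or GeneratorConfig.test_preset(
        image_size=config.image_size)
    if models is None:
        models = ModelBundle.create(gen_cfg, seed=config.seed, lr=config.lr0)

    imgs_o, masks_o, labels_o = _load_domain(manifest_path, rows_o,
                                             gen_cfg.in_channels)
    imgs_h, masks_h, labels_h = _load_domain(manifest_path, rows_h,
                                             gen_cfg.out_channels)

    # the data/flip stream always restarts from the seed and is replayed to
    # the resume point, so an interrupted run is bit-identical to a straight one
    rng = np.random.default_rng([config.seed, 0xDA7A])
    start_step = 0
    if resume_from is not None:
        start_step, _ = load_checkpoint(resume_from, models)

    queue_o = _DomainQueue(len(rows_o), rng)
    queue_h = _DomainQueue(len(rows_h), rng)
    steps_per_epoch = math.ceil(len(rows_all) / config.batch_size)
    total_steps = config.epochs * steps_per_epoch
    if max_steps is not None:
        total_steps = min(total_steps, max_steps)

    # replay data order deterministically up to the resume point
    for _ in range(start_step):
        queue_o.take(config.batch_size)
        queue_h.take(config.batch_size)
        if config.flip_augment:
            rng.random(2 * config.batch_size)

    csv_path = out_dir / "loss.csv"
    mode = "a" if (resume_from is not None and csv_path.exists()) else "w"
    records: list[dict] = []
    with open(csv_path, mode, newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(LOSS_CSV_COLUMNS))
        if mode == "w":
            writer.writeheader()
        for step in range(start_step, total_steps):
            epoch = step // steps_per_epoch
            models.set_lr(lr_at(epoch, config))
            io = queue_o.take(config.batch_size)
            ih = queue_h.take(config.batch_size)
            if config.flip_augment:
                flips = rng.random(2 * config.batch_size) < 0.5
            else:
                flips = np.zeros(2 * config.batch_size, dtype=bool)
            bo = _make_batch(imgs_o, masks_o, labels_o, io,
                             flips[:config.batch_size])
            bh = _make_batch(imgs_h, masks_h, labels_h, ih,
                             flips[config.batch_size:])
            breakdown = train_step(bo, bh, models, config)
            rec = {"step": step, **{k: getattr(breakdown, k)
                                    for k in LOSS_CSV_COLUMNS[1:]}}
            writer.writerow(rec)
            records.append(rec)
            if config.checkpoint_every and (step + 1) % config.checkpoint_every == 0:
                save_checkpoint(out_dir / f"ckpt_step{step + 1}.bin",
                                models, gen_cfg, step + 1, rng)
    save_checkpoint(out_dir / f"ckpt_step{total_steps}.bin",
                    models, gen_cfg, total_steps, rng)
    return models, records


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(path, models: ModelBundle, gen_cfg: GeneratorConfig,
                    step: int, rng: np.random.Generator | None = None) -> None:
    """Single-file archive: all parameters keyed by hierarchical names plus
    embedded config metadata and a versioned header."""
    arrays: dict[str, np.ndarray] = {}
    for prefix, module in (("g_oh", models.g_oh), ("g_ho", models.g_ho),
                           ("d_h", models.d_h), ("d_o", models.d_o)):
        for name, p in module.named_parameters():
            arrays[f"{prefix}.{name}"] = p.data
    arrays.update(models.opt_g.state_arrays("opt_g"))
    arrays.update(models.opt_d.state_arrays("opt_d"))
    header = {"format_version": CHECKPOINT_FORMAT_VERSION,
              "generator_config": asdict(gen_cfg),
              "step": int(step),
              "rng_state": rng.bit_generator.state if rng is not None else None}
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def read_checkpoint_header(path) -> dict:
    with np.load(path) as data:
        return json.loads(bytes(data["__header__"]).decode("utf-8"))


def load_checkpoint(path, models: ModelBundle):
    """Restore parameters and optimizer/RNG state; returns (step, rng)."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode("utf-8"))
        if header["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint version "
                             f"{header['format_version']}")
        arrays = {k: data[k] for k in data.files if k != "__header__"}
    for prefix, module in (("g_oh", models.g_oh), ("g_ho", models.g_ho),
                           ("d_h", models.d_h), ("d_o", models.d_o)):
        state = {name: arrays[f"{prefix}.{name}"]
                 for name, _ in module.named_parameters()}
        module.load_state_dict(state)
    models.opt_g.load_state_arrays(arrays, "opt_g")
    models.opt_d.load_state_arrays(arrays, "opt_d")
    rng = np.random.default_rng(0)
    if header["rng_state"] is not None:
        rng.bit_generator.state = header["rng_state"]
    return header["step"], rng


def load_generator(path, which: str = "g_oh") -> Generator:
    """Rebuild one generator (for inference) from a checkpoint file."""
    header = read_checkpoint_header(path)
    cfg_dict = dict(header["generator_config"])
    cfg = GeneratorConfig(**cfg_dict)
    if which == "g_ho":
        cfg = replace(cfg, in_channels=cfg.out_channels,
                      out_channels=cfg.in_channels)
    gen = Generator(cfg, np.random.default_rng(0))
    with np.load(path) as data:
        state = {name: data[f"{which}.{name}"]
                 for name, _ in gen.named_parameters()}
    gen.load_state_dict(state)
    return gen


def split_folds(rows: list[dict], k: int, seed: int) -> list[list[dict]]:
    """Deterministic k-fold split of manifest rows by sample id.

    Phantoms have no patient grouping, so folds are per-sample; with real
    data, group rows by patient before calling this.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    ids = sorted({r["id"] for r in rows})
    order = np.random.default_rng([seed, 0xF01D]).permutation(len(ids))
    fold_of = {ids[j]: int(i % k) for i, j in enumerate(order)}
    folds: list[list[dict]] = [[] for _ in range(k)]
    for r in rows:
        folds[fold_of[r["id"]]].append(r)
    return folds


# -- evaluation helpers -----------------------------------------------------

def _forward_oct(g_oh: Generator, samples: list[PhantomSample]):
    x = np.stack([s.oct_image[None] for s in samples]).astype(np.float32)
    return g_oh(Tensor(x))


def pathology_accuracy(g_oh: Generator, samples: list[PhantomSample]) -> float:
    """SCPA normal/pathological accuracy on held-out OCT phantoms."""
    out = _forward_oct(g_oh, samples)
    pred = (out.scpa.pathology_score.data >= 0.5).astype(int)
    truth = np.array([s.pathology_label for s in samples])
    return float((pred == truth).mean())


def segmentation_accuracy(g_oh: Generator, samples: list[PhantomSample]) -> float:
    """Pixel accuracy of the SCPA layer segmentation over tissue pixels."""
    out = _forward_oct(g_oh, samples)
    pred = out.scpa.segmentation.data.argmax(axis=-1)
    correct = total = 0
    for i, s in enumerate(samples):
        if s.layer_mask is None:
            continue
        valid = s.layer_mask != BACKGROUND_CLASS
        correct += int((pred[i][valid] == s.layer_mask[valid]).sum())
        total += int(valid.sum())
    if total == 0:
        raise ValueError("no labeled tissue pixels in the evaluation set")
    return correct / total


def palette_layer_matches(g_oh: Generator, samples: list[PhantomSample],
                          palette_means: np.ndarray) -> int:
    """How many of the 3 layers map to their own H&E palette colour.

    Translates held-out OCT phantoms, averages output RGB over each true
    layer, and counts layers whose mean colour is closer (L2) to their own
    palette entry than to either other layer's entry.
    """
    out = _forward_oct(g_oh, samples)
    rgb = out.translated.data.transpose(0, 2, 3, 1)        # (B, H, W, 3)
    matches = 0
    for layer in range(3):
        num = np.zeros(3)
        cnt = 0
        for i, s in enumerate(samples):
            if s.layer_mask is None:
                continue
            m = s.layer_mask == layer
            num += rgb[i][m].sum(axis=0)
            cnt += int(m.sum())
        if cnt == 0:
            continue
        mean_rgb = num / cnt
        dists = np.linalg.norm(palette_means[:3] - mean_rgb[None], axis=1)
        if dists.argmin() == layer:
            matches += 1
    return matches
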
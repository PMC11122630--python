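"""Training orchestration for deep consistent collaborative learning.

One training run couples four ingredients around a U-Net backbone:

* supervised CE+Dice on the scarce labeled batch (U-Net and, when the
  co-training branch is on, the transformer too);
* feature-perturbation consistency — the unlabeled batch is encoded
  once, three perturbed copies of the bottleneck are decoded by three
  independent auxiliary decoders, and their probability maps are pulled
  towards the main decoder's (MSE);
* input-perturbation consistency — an EMA teacher sees a noised copy of
  the unlabeled batch and the student is pulled towards its detached
  prediction (MSE);
* cross pseudo-label co-training between the U-Net and the Swin-style
  transformer on the unlabeled batch (symmetric Dice on detached argmax
  maps).

Labeled data only ever reach the two backbones; unlabeled data reach
every branch.  Each component can be toggled independently, which
reproduces the ablation lattice (baseline, +Aux, +Tea, +ViT, the pairs,
and the full model).  The optimizer covers every trainable branch except
the teacher, whose parameters are updated only by EMA after each step.
"""

from __future__ import annotations

import csv
import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import dynamics, losses, metrics, nn, perturbations
from .backbones import FeaturePyramid, SwinSeg, UNetDecoder, UNetEncoder, UNet
from .dynamics import RampSchedule, TeacherState
from .losses import LossBreakdown
from .perturbations import PerturbationConfig
from .phantom import SplitDataset

logger = logging.getLogger(__name__)

# fixed sub-stream codes so toggling one component never shifts another's RNG
_STREAMS = {"data_labeled": 0, "data_unlabeled": 1, "perturbation": 2,
            "dropout": 3, "augment": 4, "init_encoder": 10, "init_decoder": 11,
            "init_aux0": 12, "init_aux1": 13, "init_aux2": 14, "init_swin": 16}


def seed_streams(master_seed: int) -> dict[str, np.random.Generator]:
    """Named, independent RNG streams derived from one master seed."""
    return {name: np.random.default_rng([master_seed, code])
            for name, code in _STREAMS.items()}


class ConfigError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class Components:
    """Ablation toggles; the U-Net backbone itself is always active."""

    aux: bool = True
    teacher: bool = True
    vit: bool = True

    def tag(self) -> str:
        parts = [n for n in ("aux", "teacher", "vit") if getattr(self, n)]
        return "unet" + ("+" + "+".join(parts) if parts else "")


@dataclass
class RunConfig:
    n_classes: int = 4
    components: Components = field(default_factory=Components)
    batch_labeled: int = 8
    batch_unlabeled: int = 8
    total_iters: int = 30_000
    eval_every: int = 200
    base_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    unet_depth: int = 4
    unet_base_channels: int = 16
    swin_patch: int = 4
    swin_embed: int = 48
    swin_heads: int = 2
    swin_window: int = 4
    swin_blocks: int = 2
    ema_decay: float = 0.99
    ramp_base_weight: float = 0.01
    ramp_u: float = 15.0
    ramp_every: int = 150
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    dropout_p: float = 0.5
    augment: bool = True
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.batch_labeled < 1:
            raise ConfigError("batch_labeled must be >= 1")
        if self.total_iters < 1:
            raise ConfigError("total_iters must be >= 1")
        if self.base_lr <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ConfigError("invalid optimizer settings")

    def schedule(self) -> RampSchedule:
        return RampSchedule(base_weight=self.ramp_base_weight, u=self.ramp_u,
                            ramp_every=self.ramp_every, total_iters=self.total_iters)


@dataclass
class ImageBatch:
    """Half labeled / half unlabeled by default (8 + 8 at full scale)."""

    x_l: np.ndarray                    # (B_l, 1, H, W)
    y_l: np.ndarray                    # (B_l, H, W)
    x_u: np.ndarray                    # (B_u, 1, H, W); may be empty


@dataclass
class Models:
    encoder: UNetEncoder
    decoder: UNetDecoder
    aux_decoders: list[UNetDecoder]
    swin: SwinSeg | None
    teacher: TeacherState | None
    n_classes: int

    def trainable_modules(self) -> list[nn.Module]:
        mods = [self.encoder, self.decoder, *self.aux_decoders]
        if self.swin is not None:
            mods.append(self.swin)
        return mods

    def trainable_parameters(self) -> list[nn.Parameter]:
        return [p for m in self.trainable_modules() for p in m.parameters()]

    def train(self):
        for m in self.trainable_modules():
            m.train()
        if self.teacher is not None:
            self.teacher.model.train()

    def backbone(self) -> UNet:
        net = UNet.__new__(UNet)
        nn.Module.__init__(net)
        net.encoder = self.encoder
        net.decoder = self.decoder
        net.n_classes = self.n_classes
        return net


def build_models(config: RunConfig) -> Models:
    streams = seed_streams(config.seed)
    c = config
    encoder = UNetEncoder(1, c.unet_base_channels, c.unet_depth, streams["init_encoder"])
    decoder = UNetDecoder(c.n_classes, c.unet_base_channels, c.unet_depth,
                          streams["init_decoder"])
    aux = [UNetDecoder(c.n_classes, c.unet_base_channels, c.unet_depth,
                       streams[f"init_aux{i}"]) for i in range(3)] \
        if c.components.aux else []
    swin = SwinSeg(c.n_classes, 1, c.swin_patch, c.swin_embed, c.swin_heads,
                   c.swin_window, c.swin_blocks, streams["init_swin"]) \
        if c.components.vit else None
    teacher = None
    if c.components.teacher:
        def factory():
            rng = np.random.default_rng(0)
            net = UNet.__new__(UNet)
            nn.Module.__init__(net)
            net.encoder = UNetEncoder(1, c.unet_base_channels, c.unet_depth, rng)
            net.decoder = UNetDecoder(c.n_classes, c.unet_base_channels, c.unet_depth, rng)
            net.n_classes = c.n_classes
            return net
        student = UNet.__new__(UNet)
        nn.Module.__init__(student)
        student.encoder = encoder
        student.decoder = decoder
        student.n_classes = c.n_classes
        teacher = dynamics.make_teacher(student, factory, decay=c.ema_decay)
    return Models(encoder=encoder, decoder=decoder, aux_decoders=aux, swin=swin,
                  teacher=teacher, n_classes=c.n_classes)


# ---------------------------------------------------------------------
# data pipeline
# ---------------------------------------------------------------------

def augment_pair(image: np.ndarray, label: np.ndarray | None,
                 rng: np.random.Generator):
    """Axis-aligned rotation (multiples of 90 degrees) and flips, applied
    identically to image and label so label maps stay exact."""
    k = int(rng.integers(0, 4))
    flip_lr = bool(rng.integers(0, 2))
    flip_ud = bool(rng.integers(0, 2))
    img = np.rot90(image, k)
    lab = np.rot90(label, k) if label is not None else None
    if flip_lr:
        img = img[:, ::-1]
        lab = lab[:, ::-1] if lab is not None else None
    if flip_ud:
        img = img[::-1, :]
        lab = lab[::-1, :] if lab is not None else None
    return np.ascontiguousarray(img), (np.ascontiguousarray(lab) if lab is not None else None)


class _Cycler:
    """Independent shuffled epoch cycler over a list of item indices."""

    def __init__(self, n: int, rng: np.random.Generator):
        self.n = n
        self.rng = rng
        self.order = rng.permutation(n) if n else np.empty(0, dtype=int)
        self.pos = 0

    def take(self, k: int) -> list[int]:
        out = []
        while len(out) < k and self.n:
            if self.pos >= self.n:
                self.order = self.rng.permutation(self.n)
                self.pos = 0
            out.append(int(self.order[self.pos]))
            self.pos += 1
        return out

    def get_state(self):
        return {"order": self.order.copy(), "pos": self.pos,
                "rng": self.rng.bit_generator.state}

    def set_state(self, state):
        self.order = np.asarray(state["order"])
        self.pos = state["pos"]
        self.rng.bit_generator.state = state["rng"]


def next_batch(data: SplitDataset, cyc_l: _Cycler, cyc_u: _Cycler,
               config: RunConfig, rng_aug: np.random.Generator) -> ImageBatch:
    xs, ys = [], []
    for i in cyc_l.take(config.batch_labeled):
        img, lab = data.labeled[i]
        if config.augment:
            img, lab = augment_pair(img, lab, rng_aug)
        xs.append(img)
        ys.append(lab)
    xu = []
    for i in cyc_u.take(config.batch_unlabeled if data.unlabeled else 0):
        img = data.unlabeled[i]
        if config.augment:
            img, _ = augment_pair(img, None, rng_aug)
        xu.append(img)
    x_l = np.stack(xs).astype(np.float32)[:, None]
    y_l = np.stack(ys).astype(np.int64)
    x_u = (np.stack(xu).astype(np.float32)[:, None] if xu
           else np.empty((0, 1) + x_l.shape[2:], dtype=np.float32))
    return ImageBatch(x_l=x_l, y_l=y_l, x_u=x_u)


# ---------------------------------------------------------------------
# one optimization step
# ---------------------------------------------------------------------

def train_step(models: Models, batch: ImageBatch, iteration: int,
               config: RunConfig, schedule: RampSchedule, optimizer: nn.SGD,
               rngs: dict[str, np.random.Generator]) -> LossBreakdown:
    """One full forward/backward/update; returns the loss breakdown."""
    comp = config.components
    backbone = models.backbone()

    out_l = backbone(batch.x_l)
    sup_u = losses.supervised_loss(out_l, batch.y_l)
    sup_su = losses.supervised_loss(models.swin(batch.x_l), batch.y_l) \
        if comp.vit else 0.0

    unsup_aux = unsup_teacher = unsup_cotrain = 0.0
    has_unlabeled = batch.x_u.shape[0] > 0
    if has_unlabeled and (comp.aux or comp.teacher or comp.vit):
        pyr_u = models.encoder(batch.x_u)
        out_u = models.decoder(pyr_u)
        if comp.aux:
            prng = rngs["perturbation"]
            h = pyr_u.bottleneck
            perturbed = [
                perturbations.feature_noise(h, prng, config.perturbation),
                perturbations.feature_dropout(h, prng, config.perturbation),
                perturbations.dropout_perturb(h, rngs["dropout"], config.dropout_p),
            ]
            aux_outs = [dec(FeaturePyramid(hp, pyr_u.skips))
                        for dec, hp in zip(models.aux_decoders, perturbed)]
            unsup_aux = losses.aux_consistency_loss(out_u, aux_outs)
        if comp.teacher:
            x_noi = perturbations.input_noise(batch.x_u, rngs["perturbation"],
                                              config.perturbation)
            with ad.no_grad():
                out_t = models.teacher.model(x_noi)
            unsup_teacher = losses.teacher_consistency_loss(out_u, out_t)
        if comp.vit:
            out_u_su = models.swin(batch.x_u)
            unsup_cotrain = losses.cotrain_loss(out_u, out_u_su)

    l1, l2 = schedule.weights_at(iteration)
    total, breakdown = losses.total_loss(
        sup_u, sup_su, unsup_aux, unsup_teacher, unsup_cotrain,
        lambda1=l1, lambda2=l2)
    if not np.isfinite(breakdown.total):
        raise TrainingDivergedError(
            f"non-finite loss at iteration {iteration}: {breakdown.as_row()}")

    optimizer.zero_grad()
    total.backward()
    optimizer.lr = dynamics.poly_lr(iteration, config.total_iters, config.base_lr)
    optimizer.step()
    if comp.teacher:
        dynamics.ema_update(models.teacher, models.backbone())
    return breakdown


# ---------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------

def predict(model: nn.Module, images, batch_size: int = 8) -> np.ndarray:
    """Per-pixel argmax class maps (ties -> lowest class index)."""
    imgs = np.asarray(images, dtype=np.float32)
    if imgs.ndim == 2:
        imgs = imgs[None]
    if imgs.ndim == 3:
        imgs = imgs[:, None]
    model.eval()
    maps = []
    with ad.no_grad():
        for i in range(0, imgs.shape[0], batch_size):
            out = model(imgs[i:i + batch_size])
            maps.append(out.probs.data.argmax(axis=1))
    model.train()
    return np.concatenate(maps, axis=0).astype(np.int16)


def evaluate_pairs(model: nn.Module, pairs, n_classes: int) -> metrics.MetricReport:
    images = [p[0] for p in pairs]
    labels = [p[1] for p in pairs]
    preds = predict(model, np.stack(images))
    return metrics.evaluate(list(preds), labels, n_classes)


# ---------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------

@dataclass
class TrainedRun:
    config: RunConfig
    best_iteration: int
    best_val_dsc: float
    val_history: list[tuple[int, float]]
    log: list[dict]
    test_report: metrics.MetricReport
    best_state: dict[str, np.ndarray]
    out_dir: str | None = None

    def best_backbone(self) -> UNet:
        net = UNet(self.config.n_classes, 1, self.config.unet_base_channels,
                   self.config.unet_depth)
        net.load_state_dict(self.best_state)
        return net


_LOG_FIELDS = ("iteration",) + LossBreakdown.FIELDS + ("lr",)


class Trainer:
    """Mutable training state; supports checkpoint/resume."""

    def __init__(self, config: RunConfig, data: SplitDataset):
        if not data.labeled:
            raise ConfigError("labeled partition is empty")
        needs_unlabeled = (config.components.aux or config.components.teacher
                           or config.components.vit)
        if needs_unlabeled and not data.unlabeled:
            logger.warning("no unlabeled images: consistency terms will be zero")
        self.config = config
        self.data = data
        self.models = build_models(config)
        self.schedule = config.schedule()
        self.optimizer = nn.SGD(self.models.trainable_parameters(), lr=config.base_lr,
                                momentum=config.momentum, weight_decay=config.weight_decay)
        self._assert_teacher_frozen()
        self.rngs = seed_streams(config.seed)
        self.cyc_l = _Cycler(len(data.labeled), self.rngs["data_labeled"])
        self.cyc_u = _Cycler(len(data.unlabeled), self.rngs["data_unlabeled"])
        self.iteration = 0
        self.log: list[dict] = []
        self.val_history: list[tuple[int, float]] = []
        self.best_val_dsc = -1.0
        self.best_iteration = -1
        self.best_state: dict[str, np.ndarray] | None = None

    def _assert_teacher_frozen(self):
        if self.models.teacher is None:
            return
        opt_ids = {id(p) for p in self.optimizer.params}
        t_ids = {id(p) for p in self.models.teacher.model.parameters()}
        if opt_ids & t_ids:
            raise ConfigError("teacher parameters must not be in the optimizer")

    def step(self) -> LossBreakdown:
        batch = next_batch(self.data, self.cyc_l, self.cyc_u, self.config,
                           self.rngs["augment"])
        breakdown = train_step(self.models, batch, self.iteration, self.config,
                               self.schedule, self.optimizer, self.rngs)
        lr = dynamics.poly_lr(self.iteration, self.config.total_iters, self.config.base_lr)
        row = {"iteration": self.iteration, **breakdown.as_row(), "lr": lr}
        self.log.append(row)
        self.iteration += 1
        return breakdown

    def validate(self) -> float:
        report = evaluate_pairs(self.models.backbone(), self.data.val,
                                self.config.n_classes)
        return report.mean["dsc"]

    def run(self, progress: bool = False) -> TrainedRun:
        cfg = self.config
        while self.iteration < cfg.total_iters:
            self.step()
            if self.iteration % cfg.eval_every == 0 or self.iteration == cfg.total_iters:
                val_dsc = self.validate()
                self.val_history.append((self.iteration, val_dsc))
                if val_dsc > self.best_val_dsc:
                    self.best_val_dsc = val_dsc
                    self.best_iteration = self.iteration
                    self.best_state = self.models.backbone().state_dict()
                if progress:
                    logger.info("iter %d  val DSC %.4f (best %.4f @ %d)",
                                self.iteration, val_dsc, self.best_val_dsc,
                                self.best_iteration)
        if self.best_state is None:  # no eval happened (tiny runs)
            self.best_val_dsc = self.validate()
            self.best_iteration = self.iteration
            self.best_state = self.models.backbone().state_dict()
        best_net = UNet(cfg.n_classes, 1, cfg.unet_base_channels, cfg.unet_depth)
        best_net.load_state_dict(self.best_state)
        test_report = evaluate_pairs(best_net, self.data.test, cfg.n_classes)
        run = TrainedRun(config=cfg, best_iteration=self.best_iteration,
                         best_val_dsc=self.best_val_dsc, val_history=self.val_history,
                         log=self.log, test_report=test_report,
                         best_state=self.best_state, out_dir=cfg.out_dir)
        if cfg.out_dir:
            self._write_artifacts(run)
        return run

    # -- persistence ---------------------------------------------------
    def _write_artifacts(self, run: TrainedRun):
        from .interface import config_to_yaml  # local import to avoid a cycle

        out = Path(self.config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(config_to_yaml(self.config))
        with open(out / "training_log.csv", "w", newline="") as f:
            writer = csv.DictWriter(f, fieldnames=_LOG_FIELDS)
            writer.writeheader()
            writer.writerows(run.log)
        with open(out / "metrics.json", "w") as f:
            json.dump({"best_iteration": run.best_iteration,
                       "best_val_dsc": run.best_val_dsc,
                       "val_history": run.val_history,
                       "test": run.test_report.to_dict()}, f, indent=2)
        self.save_checkpoint(out / "best.ckpt", best_only=True)

    def save_checkpoint(self, path, best_only: bool = False):
        payload = {"iteration": self.iteration, "config": self.config,
                   "best_val_dsc": self.best_val_dsc,
                   "best_iteration": self.best_iteration,
                   "best_state": self.best_state,
                   "val_history": self.val_history}
        if not best_only:
            payload.update({
                "encoder": self.models.encoder.state_dict(),
                "decoder": self.models.decoder.state_dict(),
                "aux": [d.state_dict() for d in self.models.aux_decoders],
                "swin": self.models.swin.state_dict() if self.models.swin else None,
                "teacher": (self.models.teacher.model.state_dict()
                            if self.models.teacher else None),
                "teacher_count": (self.models.teacher.update_count
                                  if self.models.teacher else 0),
                "optimizer": self.optimizer.state_dict(),
                "rngs": {k: g.bit_generator.state for k, g in self.rngs.items()},
                "cyc_l": self.cyc_l.get_state(), "cyc_u": self.cyc_u.get_state(),
                "log": self.log})
        with open(path, "wb") as f:
            pickle.dump(payload, f)

    def load_checkpoint(self, path):
        with open(path, "rb") as f:
            payload = pickle.load(f)
        if "encoder" not in payload:
            raise ValueError("checkpoint holds only the best weights; cannot resume")
        self.iteration = payload["iteration"]
        self.best_val_dsc = payload["best_val_dsc"]
        self.best_iteration = payload["best_iteration"]
        self.best_state = payload["best_state"]
        self.val_history = list(payload["val_history"])
        self.log = list(payload["log"])
        self.models.encoder.load_state_dict(payload["encoder"])
        self.models.decoder.load_state_dict(payload["decoder"])
        for dec, st in zip(self.models.aux_decoders, payload["aux"]):
            dec.load_state_dict(st)
        if self.models.swin is not None and payload["swin"] is not None:
            self.models.swin.load_state_dict(payload["swin"])
        if self.models.teacher is not None and payload["teacher"] is not None:
            self.models.teacher.model.load_state_dict(payload["teacher"])
            self.models.teacher.update_count = payload["teacher_count"]
        self.optimizer.load_state_dict(payload["optimizer"])
        for k, g in self.rngs.items():
            g.bit_generator.state = payload["rngs"][k]
        self.cyc_l.set_state(payload["cyc_l"])
        self.cyc_u.set_state(payload["cyc_u"])


def fit(config: RunConfig, data: SplitDataset, progress: bool = False,
        resume_from=None) -> TrainedRun:
    """Run a full training; returns the record with the best checkpoint."""
    trainer = Trainer(config, data)
    if resume_from is not None:
        trainer.load_checkpoint(resume_from)
    return trainer.run(progress=progress)
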
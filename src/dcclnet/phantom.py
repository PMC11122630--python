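"""Synthetic 2D multi-class phantoms for semi-supervised segmentation.

Each phantom mimics a short-axis cardiac slice: a bright elliptical
cavity (highest class label) inside a darker muscular annulus, with an
adjacent crescent-shaped chamber — three foreground structures over
background, with per-class intensity contrast, a smooth multiplicative
bias field and additive Gaussian noise.  Pose, size and orientation vary
per image; labels are rasterised exactly (a pixel belongs to the
innermost shape covering its centre, no anti-aliasing).

Datasets are split 70/10/20 % into train/val/test pools; within the
train pool only a small ``labeled_fraction`` keeps its label maps,
emulating the scarce-annotation regime.  Fixtures round-trip through a
single HDF5 container; identical :class:`PhantomSpec` values yield
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

# geometry and noise use separate derived streams so that a noise-free
# regeneration of an image reuses the exact same geometry
_GEOM_STREAM = 0
_NOISE_STREAM = 1
_SPLIT_STREAM = 2


class InvalidSpecError(ValueError):
    pass


class FixtureFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one synthetic dataset."""

    image_size: int = 64
    n_classes: int = 4
    n_images: int = 100
    labeled_fraction: float = 0.1
    noise_sigma: float = 0.05
    bias_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16:
            raise InvalidSpecError(f"image_size must be >= 16, got {self.image_size}")
        if self.n_classes < 2:
            raise InvalidSpecError(f"n_classes must be >= 2, got {self.n_classes}")
        if not (0.0 < self.labeled_fraction <= 1.0):
            raise InvalidSpecError(
                f"labeled_fraction must be in (0, 1], got {self.labeled_fraction}")
        if self.n_images < 1:
            raise InvalidSpecError(f"n_images must be >= 1, got {self.n_images}")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise InvalidSpecError("noise_sigma and bias_amplitude must be >= 0")
        gap = self.intensity_gap()
        if gap < 2.0 * self.noise_sigma:
            raise InvalidSpecError(
                f"class-mean gap {gap:.3f} < 2*noise_sigma; lower noise_sigma "
                f"or n_classes")

    def intensity_gap(self) -> float:
        """Spacing between adjacent class mean intensities, before jitter."""
        return 0.75 / (self.n_classes - 1)

    def class_means(self) -> np.ndarray:
        return 0.15 + self.intensity_gap() * np.arange(self.n_classes)


def _rng(spec: PhantomSpec, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index, stream])


def _ellipse_mask(yy, xx, cy, cx, a, b, angle) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    u = (yy - cy) * ca + (xx - cx) * sa
    v = -(yy - cy) * sa + (xx - cx) * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _label_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float) + 0.5
    cy = s / 2 + rng.uniform(-s / 10, s / 10)
    cx = s / 2 + rng.uniform(-s / 10, s / 10)
    angle = rng.uniform(0, np.pi)
    a_core = rng.uniform(s / 8, s / 5.5)
    b_core = a_core * rng.uniform(0.75, 1.0)
    label = np.zeros((s, s), dtype=np.int16)
    n_fg = spec.n_classes - 1

    # innermost structure: the bright cavity (highest class index)
    core = _ellipse_mask(yy, xx, cy, cx, a_core, b_core, angle)
    shapes = [core]
    # annular shells around the core, one per remaining inner class
    scale = 1.45
    outer_prev = core
    outer_a, outer_b = a_core, b_core
    for _ in range(max(0, n_fg - 2)):
        outer_a, outer_b = outer_a * scale, outer_b * scale
        shell_outer = _ellipse_mask(yy, xx, cy, cx, outer_a, outer_b, angle)
        shapes.append(shell_outer & ~outer_prev)
        outer_prev = shell_outer
    # outermost structure: a crescent-shaped chamber hugging the shells
    if n_fg >= 2:
        direction = rng.uniform(0, 2 * np.pi)
        dist = (outer_a + outer_b) / 2 * 1.05
        ccy = cy + dist * np.sin(direction)
        ccx = cx + dist * np.cos(direction)
        r = (outer_a + outer_b) / 2 * rng.uniform(0.75, 0.95)
        crescent = _ellipse_mask(yy, xx, ccy, ccx, r, r, 0.0) & ~outer_prev
        shapes.append(crescent)

    # innermost shape wins; paint outermost (lowest class) first
    for cls, mask in zip(range(1, len(shapes) + 1), reversed(shapes)):
        label[mask] = cls
    return label


def generate_phantom(spec: PhantomSpec, index: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one (image, label_map) pair; deterministic in (spec, index)."""
    if index >= spec.n_images:
        raise InvalidSpecError(f"index {index} >= n_images {spec.n_images}")
    geom = _rng(spec, index, _GEOM_STREAM)
    label = _label_map(spec, geom)
    means = spec.class_means()
    jitter_amp = min(0.02, spec.intensity_gap() / 4)
    jitter = geom.uniform(-jitter_amp, jitter_amp, size=spec.n_classes)
    image = (means + jitter)[label].astype(np.float64)

    s = spec.image_size
    if spec.bias_amplitude > 0:
        yy, xx = np.mgrid[0:s, 0:s].astype(float)
        fy, fx = geom.uniform(0.5, 1.5, size=2) * np.pi / s
        phase = geom.uniform(0, 2 * np.pi)
        bias = 1.0 + spec.bias_amplitude * np.sin(fy * yy + fx * xx + phase)
        image = image * bias
    noise_rng = _rng(spec, index, _NOISE_STREAM)
    if spec.noise_sigma > 0:
        image = image + noise_rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0).astype(np.float32), label


@dataclass
class SplitDataset:
    """Index-disjoint partitions of one generated dataset."""

    labeled: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    unlabeled: list[np.ndarray] = field(default_factory=list)
    val: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    test: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    n_classes: int = 4
    indices: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def image_size(self) -> int:
        if self.labeled:
            return self.labeled[0][0].shape[-1]
        return self.val[0][0].shape[-1]


def split_sizes(n_images: int, labeled_fraction: float) -> tuple[int, int, int, int]:
    """(n_labeled, n_unlabeled, n_val, n_test) under the 70/10/20 split."""
    n_val = round(0.1 * n_images)
    n_test = round(0.2 * n_images)
    n_train = n_images - n_val - n_test
    n_labeled = int(np.floor(labeled_fraction * n_train))
    return n_labeled, n_train - n_labeled, n_val, n_test


def make_split(spec: PhantomSpec) -> SplitDataset:
    """Generate all images and partition them train(labeled/unlabeled)/val/test."""
    if spec.n_images < 10:
        raise InvalidSpecError(f"n_images must be >= 10 to split, got {spec.n_images}")
    n_labeled, n_unlabeled, n_val, n_test = split_sizes(spec.n_images, spec.labeled_fraction)
    if n_labeled == 0:
        raise InvalidSpecError(
            f"labeled_fraction {spec.labeled_fraction} yields zero labeled images")
    order = np.random.default_rng([spec.seed, 0, _SPLIT_STREAM]).permutation(spec.n_images)
    idx = {
        "labeled": order[:n_labeled],
        "unlabeled": order[n_labeled:n_labeled + n_unlabeled],
        "val": order[n_labeled + n_unlabeled:n_labeled + n_unlabeled + n_val],
        "test": order[n_labeled + n_unlabeled + n_val:],
    }
    pairs = {i: generate_phantom(spec, int(i)) for i in order}
    return SplitDataset(
        labeled=[pairs[i] for i in idx["labeled"]],
        unlabeled=[pairs[i][0] for i in idx["unlabeled"]],
        val=[pairs[i] for i in idx["val"]],
        test=[pairs[i] for i in idx["test"]],
        n_classes=spec.n_classes,
        indices=idx,
    )


_GROUPS = ("labeled", "unlabeled", "val", "test")


def write_fixture(ds: SplitDataset, path) -> None:
    """Persist a split dataset to one HDF5 container (deterministic bytes)."""
    path = Path(path)
    with h5py.File(path, "w", track_order=False) as f:
        f.attrs["n_classes"] = ds.n_classes
        for name in _GROUPS:
            grp = f.create_group(name)
            if name == "unlabeled":
                images = np.stack(ds.unlabeled) if ds.unlabeled else \
                    np.empty((0, ds.image_size, ds.image_size), dtype=np.float32)
                grp.create_dataset("images", data=images, track_times=False)
            else:
                part = getattr(ds, name)
                size = ds.image_size
                images = np.stack([p[0] for p in part]) if part else \
                    np.empty((0, size, size), dtype=np.float32)
                labels = np.stack([p[1] for p in part]) if part else \
                    np.empty((0, size, size), dtype=np.int16)
                grp.create_dataset("images", data=images, track_times=False)
                grp.create_dataset("labels", data=labels, track_times=False)


def read_fixture(path) -> SplitDataset:
    """Load a fixture container written by :func:`write_fixture`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in _GROUPS:
            if name not in f:
                raise FixtureFormatError(f"fixture missing group {name!r}")
        n_classes = int(f.attrs.get("n_classes", 4))
        unl = [img for img in f["unlabeled"]["images"][...]]

        def pairs(name):
            grp = f[name]
            if "images" not in grp or "labels" not in grp:
                raise FixtureFormatError(f"group {name!r} missing images/labels")
            return list(zip(grp["images"][...], grp["labels"][...]))

        return SplitDataset(labeled=pairs("labeled"), unlabeled=unl,
                            val=pairs("val"), test=pairs("test"),
                            n_classes=n_classes)


def label_png_scale(n_classes: int) -> int:
    return 255 // (n_classes - 1)


def export_png(image: np.ndarray, label: np.ndarray, n_classes: int,
               image_path, label_path) -> None:
    """8-bit grayscale PNG export; label gray levels are ``k * floor(255/(C-1))``."""
    from PIL import Image

    Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8)).save(image_path)
    Image.fromarray((label.astype(np.int32) * label_png_scale(n_classes))
                    .astype(np.uint8)).save(label_path)


def read_label_png(path, n_classes: int) -> np.ndarray:
    """Inverse lookup of :func:`export_png` label encoding."""
    from PIL import Image

    arr = np.asarray(Image.open(path))
    return (arr // label_png_scale(n_classes)).astype(np.int16)
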
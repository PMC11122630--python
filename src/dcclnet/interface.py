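"""Configuration files, real-data readers and overlay export.

YAML round-trips for :class:`~dcclnet.trainer.RunConfig` and
:class:`~dcclnet.phantom.PhantomSpec`; readers for real 2D datasets
(NIfTI volumes sliced along the last axis, or paired PNG files) with
min-max normalisation and resizing (bilinear for images, nearest for
labels, preserving label integrality); and colour overlay export using
the conventional palette (class 1 red, class 2 blue, class 3 green).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .perturbations import PerturbationConfig
from .phantom import PhantomSpec, SplitDataset
from .trainer import Components, RunConfig

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# YAML configuration round-trips
# ---------------------------------------------------------------------

def config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(asdict(config), sort_keys=True)


def config_from_yaml(text: str) -> RunConfig:
    raw = yaml.safe_load(text) or {}
    if "components" in raw and isinstance(raw["components"], dict):
        raw["components"] = Components(**raw["components"])
    if "perturbation" in raw and isinstance(raw["perturbation"], dict):
        raw["perturbation"] = PerturbationConfig(**raw["perturbation"])
    return RunConfig(**raw)


def phantom_spec_to_yaml(spec: PhantomSpec) -> str:
    return yaml.safe_dump(asdict(spec), sort_keys=True)


def phantom_spec_from_yaml(text: str) -> PhantomSpec:
    return PhantomSpec(**(yaml.safe_load(text) or {}))


def setup_logging(level=logging.INFO, log_file=None):
    handlers = [logging.StreamHandler()]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(level=level, handlers=handlers,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


# ---------------------------------------------------------------------
# real-data readers
# ---------------------------------------------------------------------

class ManifestError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RealDataSpec:
    """Description of an on-disk 2D dataset.

    ``nifti_dir`` expects ``<root>/images/*.nii[.gz]`` with matching
    basenames under ``<root>/labels`` for labeled cases; volumes are
    sliced along the last axis.  ``png_pairs`` expects
    ``<root>/images/*.png`` and ``<root>/labels/*.png``.
    Images without a label file form the unlabeled pool.
    """

    root: str
    format: str = "nifti_dir"          # or "png_pairs"
    resize_to: int = 224
    val_fraction: float = 0.1
    test_fraction: float = 0.2
    n_classes: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.format not in ("nifti_dir", "png_pairs"):
            raise ManifestError(f"unknown format {self.format!r}")


def minmax_normalize(image: np.ndarray) -> np.ndarray:
    image = image.astype(np.float64)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    return resize(image, (size, size), order=1, preserve_range=True,
                  anti_aliasing=False).astype(np.float32)


def resize_label(label: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize: never introduces new class values."""
    from skimage.transform import resize

    out = resize(label, (size, size), order=0, preserve_range=True,
                 anti_aliasing=False)
    return np.rint(out).astype(np.int16)


def _read_slices_nifti(path) -> list[np.ndarray]:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if vol.ndim == 2:
        return [vol]
    return [vol[..., k] for k in range(vol.shape[-1])]


def _read_png(path) -> np.ndarray:
    from PIL import Image

    return np.asarray(Image.open(path))


def load_real_dataset(spec: RealDataSpec) -> SplitDataset:
    """Read, normalise and resize a real 2D dataset into the split layout.

    Labeled slices are split val/test/train by the configured fractions;
    images lacking a label map form the unlabeled train pool.
    """
    root = Path(spec.root)
    img_dir, lab_dir = root / "images", root / "labels"
    if not img_dir.is_dir():
        raise ManifestError(f"missing images directory {img_dir}")
    suffixes = (".nii", ".nii.gz") if spec.format == "nifti_dir" else (".png",)
    reader = _read_slices_nifti if spec.format == "nifti_dir" else \
        (lambda p: [_read_png(p)])

    labeled_pairs, unlabeled_imgs = [], []
    files = sorted(p for p in img_dir.iterdir()
                   if any(p.name.endswith(s) for s in suffixes))
    if not files:
        raise ManifestError(f"no {spec.format} images under {img_dir}")
    for img_path in files:
        lab_path = lab_dir / img_path.name
        img_slices = reader(img_path)
        if lab_path.exists():
            lab_slices = reader(lab_path)
            if len(lab_slices) != len(img_slices):
                raise DataError(f"{img_path.name}: image/label slice count differs")
            for img, lab in zip(img_slices, lab_slices):
                if not np.allclose(lab, np.rint(lab)):
                    raise DataError(f"{lab_path.name}: non-integer label values")
                labeled_pairs.append((
                    resize_image(minmax_normalize(img), spec.resize_to),
                    resize_label(np.rint(lab).astype(np.int16), spec.resize_to)))
        else:
            for img in img_slices:
                unlabeled_imgs.append(
                    resize_image(minmax_normalize(img), spec.resize_to))

    if not labeled_pairs:
        raise ManifestError("no labeled images found")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(labeled_pairs))
    n_val = max(1, round(spec.val_fraction * len(labeled_pairs)))
    n_test = max(1, round(spec.test_fraction * len(labeled_pairs)))
    val_idx = order[:n_val]
    test_idx = order[n_val:n_val + n_test]
    train_idx = order[n_val + n_test:]
    return SplitDataset(
        labeled=[labeled_pairs[i] for i in train_idx],
        unlabeled=unlabeled_imgs,
        val=[labeled_pairs[i] for i in val_idx],
        test=[labeled_pairs[i] for i in test_idx],
        n_classes=spec.n_classes)


# ---------------------------------------------------------------------
# overlay export
# ---------------------------------------------------------------------

# conventional display palette: RV-analog red, myocardium-analog blue,
# cavity-analog green
_PALETTE = {1: (255, 0, 0), 2: (0, 0, 255), 3: (0, 255, 0)}


# documented fallback cycle for additional classes
_EXTRA = [(255, 255, 0), (255, 0, 255), (0, 255, 255), (255, 128, 0),
          (128, 0, 255), (0, 128, 128)]


def class_color(c: int) -> tuple[int, int, int]:
    if c in _PALETTE:
        return _PALETTE[c]
    return _EXTRA[(c - 4) % len(_EXTRA)]


def export_overlay(image: np.ndarray, label_map: np.ndarray, path,
                   alpha: float = 0.5) -> None:
    """RGB PNG of the grayscale image with class colours alpha-blended."""
    from PIL import Image

    image = np.asarray(image, dtype=np.float64)
    label_map = np.asarray(label_map)
    if image.shape != label_map.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {label_map.shape}")
    gray = np.clip(image, 0, 1) * 255
    rgb = np.repeat(gray[..., None], 3, axis=-1)
    for c in np.unique(label_map):
        if c == 0:
            continue
        color = np.array(class_color(int(c)), dtype=np.float64)
        mask = label_map == c
        rgb[mask] = (1 - alpha) * rgb[mask] + alpha * color
    Image.fromarray(np.clip(np.rint(rgb), 0, 255).astype(np.uint8)).save(path)
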
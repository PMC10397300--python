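"""Synthetic burn-image generation, augmentation and manifest I/O.

The generator emulates the color semantics clinicians use to grade burn
depth: superficial lesions are red / pale pink, deep dermal lesions are
blotchy red-and-white, and full-thickness lesions show a white/brown rim
with a deep-red center.  Each image is an elliptical lesion painted over a
skin-tone background with Gaussian pixel noise; the whole dataset is a pure
function of its :class:`~burnganext.config.SynthConfig`.

Real datasets are read through a CSV manifest (``id,path,label,split``) of
PNG/JPEG files, resized to the configured input size.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import rotate as _sk_rotate

from .config import SynthConfig
from .errors import ConfigurationError, InputError, UsageError

__all__ = [
    "LABELS",
    "BINARY_LABELS",
    "ImageRecord",
    "ClassPalette",
    "DEFAULT_PALETTES",
    "AugmentationSet",
    "generate_burn_image",
    "generate_dataset",
    "augment",
    "oversample",
    "to_binary_labels",
    "label_codes",
    "records_to_arrays",
    "save_dataset",
    "load_dataset",
]

LABELS: Tuple[str, ...] = ("superficial", "deep_dermal", "full_thickness")
BINARY_LABELS: Tuple[str, ...] = ("non_graft", "graft")

#: graft = skin replacement needed (deep dermal or full thickness)
_GRAFT_MAP: Dict[str, str] = {
    "superficial": "non_graft",
    "deep_dermal": "graft",
    "full_thickness": "graft",
}


@dataclasses.dataclass
class ImageRecord:
    pixels: np.ndarray  # (H, W, 3) uint8
    label: str
    source: str = "synthetic"  # or "file"
    id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError(f"image must be H x W x 3, got shape {self.pixels.shape}")
        if self.label not in LABELS and self.label not in BINARY_LABELS:
            raise InputError(f"unknown label {self.label!r}")


@dataclasses.dataclass(frozen=True)
class ClassPalette:
    """Color anchors and texture for one burn-depth class.

    For the ``charred_center`` texture the anchors are ordered rim -> center
    (white rim, brown band, deep-red core); mixing weights give the area
    fraction of each anchor and sum to one.
    """

    label: str
    anchors: Tuple[Tuple[int, int, int], ...]
    weights: Tuple[float, ...]
    texture: str  # uniform | blotchy | charred_center

    def validate(self) -> None:
        for a in self.anchors:
            if not all(0 <= v <= 255 for v in a):
                raise ConfigurationError(f"palette anchor {a} outside [0, 255]")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("palette weights must sum to 1")
        if self.texture not in ("uniform", "blotchy", "charred_center"):
            raise ConfigurationError(f"unknown texture {self.texture!r}")

    @property
    def mean_color(self) -> np.ndarray:
        return np.einsum("i,ij->j", np.array(self.weights), np.array(self.anchors, float))


DEFAULT_PALETTES: Dict[str, ClassPalette] = {
    "superficial": ClassPalette(
        "superficial", ((205, 72, 65), (236, 176, 170)), (0.55, 0.45), "uniform"
    ),
    "deep_dermal": ClassPalette(
        "deep_dermal", ((186, 48, 48), (238, 228, 222)), (0.4, 0.6), "blotchy"
    ),
    "full_thickness": ClassPalette(
        "full_thickness",
        ((238, 232, 220), (124, 78, 48), (132, 22, 30)),
        (0.35, 0.30, 0.35),
        "charred_center",
    ),
}

_BACKGROUND = np.array([224.0, 172.0, 140.0])  # beige skin-tone anchor


def _lesion_color_field(
    palette: ClassPalette, rfield: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-pixel lesion color (H, W, 3 float) before noise."""
    h, w = rfield.shape
    anchors = np.array(palette.anchors, dtype=float)
    if palette.texture == "uniform":
        base = palette.mean_color
        noise = gaussian_filter(rng.standard_normal((h, w)), 6.0)
        span = noise.std() or 1.0
        mod = np.clip(noise / (3 * span), -1, 1)
        direction = (anchors[0] - anchors[-1]) / 2.0
        return base[None, None, :] + mod[..., None] * direction[None, None, :] * 0.8
    if palette.texture == "blotchy":
        noise = gaussian_filter(rng.standard_normal((h, w)), 4.0)
        thr = np.quantile(noise, palette.weights[0])
        idx = (noise > thr).astype(int)  # 0 -> red patches, 1 -> white patches
        field = anchors[idx]
        return gaussian_filter(field, (1.0, 1.0, 0.0))
    # charred_center: radial bands, innermost anchor at the lesion core
    rev_w = np.cumsum(palette.weights[::-1])  # center outwards
    r_core = np.sqrt(rev_w[0])
    r_mid = np.sqrt(rev_w[1]) if len(rev_w) > 2 else r_core
    wobble = gaussian_filter(rng.standard_normal((h, w)), 5.0) * 0.08
    r = rfield + wobble
    idx = np.full((h, w), 0)  # rim anchor (first)
    if len(anchors) > 2:
        idx[r <= r_mid] = 1
    idx[r <= r_core] = len(anchors) - 1
    field = anchors[idx]
    return gaussian_filter(field, (1.0, 1.0, 0.0))


def generate_burn_image(
    label: str,
    config: Optional[SynthConfig] = None,
    rng: Optional[np.random.Generator] = None,
    palette: Optional[ClassPalette] = None,
    image_id: str = "",
    geometry: Optional[Tuple[float, float, float, float, float]] = None,
) -> ImageRecord:
    """One labeled synthetic burn image.

    ``geometry`` fixes (center_y, center_x, axis_a, axis_b, angle) for
    reproducible layouts; otherwise geometry is drawn from the config
    ranges.  Deterministic given the generator state.
    """
    if label not in LABELS:
        raise InputError(f"unknown burn-depth label {label!r}")
    config = config or SynthConfig()
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    palette = palette or DEFAULT_PALETTES[label]
    palette.validate()
    h, w = config.height, config.width

    if geometry is None:
        cy = h / 2 + rng.uniform(-config.center_jitter, config.center_jitter)
        cx = w / 2 + rng.uniform(-config.center_jitter, config.center_jitter)
        a = rng.uniform(*config.axis_range)
        b = rng.uniform(*config.axis_range)
        theta = rng.uniform(0, np.pi)
    else:
        cy, cx, a, b, theta = geometry
    if a <= 0 or b <= 0:
        raise ConfigurationError(f"degenerate lesion ellipse axes ({a}, {b})")

    yy, xx = np.mgrid[0:h, 0:w]
    u = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    v = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    rfield = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    mask = rfield <= 1.0

    bg = _BACKGROUND + rng.normal(0, 6.0, size=3)
    img = np.broadcast_to(bg, (h, w, 3)).copy()
    img[mask] = _lesion_color_field(palette, rfield, rng)[mask]
    if config.noise_sd > 0:
        img = img + rng.normal(0, config.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageRecord(pixels=pixels, label=label, source="synthetic", id=image_id)


def generate_dataset(
    config: Optional[SynthConfig] = None,
    palettes: Optional[Dict[str, ClassPalette]] = None,
) -> Tuple[List[ImageRecord], pd.DataFrame]:
    """``n_per_class`` images per label, deterministically shuffled; returns
    the records and a manifest row per image."""
    config = config or SynthConfig()
    config.validate()
    palettes = palettes or DEFAULT_PALETTES
    rng = np.random.default_rng(config.seed)
    records: List[ImageRecord] = []
    for label in LABELS:
        for i in range(config.n_per_class):
            rid = f"{label}-{i:05d}"
            records.append(
                generate_burn_image(label, config, rng, palettes[label], image_id=rid)
            )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    manifest = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "path": [f"images/{r.id}.png" for r in records],
            "label": [r.label for r in records],
            "split": ["" for _ in records],
        }
    )
    return records, manifest


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _rotate_free(pixels: np.ndarray, angle: float) -> np.ndarray:
    out = _sk_rotate(
        pixels.astype(float), angle, resize=False, order=1, mode="reflect",
        preserve_range=True,
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


_TRANSFORMS = {
    "hflip": lambda p: np.flip(p, axis=1).copy(),
    "vflip": lambda p: np.flip(p, axis=0).copy(),
    "rot+30": lambda p: _rotate_free(p, 30.0),
    "rot-30": lambda p: _rotate_free(p, -30.0),
    "rot90": lambda p: np.rot90(p, 1, axes=(0, 1)).copy(),
    "rot270": lambda p: np.rot90(p, 3, axes=(0, 1)).copy(),
}


@dataclasses.dataclass(frozen=True)
class AugmentationSet:
    """Ordered image transforms; the default four-transform set is
    horizontal/vertical flips plus the two 30-degree rotations."""

    transforms: Tuple[str, ...] = ("hflip", "vflip", "rot+30", "rot-30")
    include_original: bool = True

    def validate(self) -> None:
        if len(set(self.transforms)) != len(self.transforms):
            raise ConfigurationError("augmentation transforms must be distinct")
        for t in self.transforms:
            if t not in _TRANSFORMS:
                raise UsageError(
                    f"unknown transform {t!r}; known: {sorted(_TRANSFORMS)}"
                )


FULL_AUGMENTATIONS = AugmentationSet(
    ("hflip", "vflip", "rot+30", "rot-30", "rot90", "rot270")
)


def augment(record: ImageRecord, aug: Optional[AugmentationSet] = None) -> List[ImageRecord]:
    """The original (if flagged) followed by one image per transform."""
    aug = aug or AugmentationSet()
    aug.validate()
    out: List[ImageRecord] = []
    if aug.include_original:
        out.append(record)
    for name in aug.transforms:
        out.append(
            ImageRecord(
                pixels=_TRANSFORMS[name](record.pixels),
                label=record.label,
                source=record.source,
                id=f"{record.id}:{name}" if record.id else name,
            )
        )
    return out


def oversample(
    records: Sequence[ImageRecord],
    target_count: int,
    seed: int = 0,
    angle_range: Tuple[float, float] = (-30.0, 30.0),
) -> List[ImageRecord]:
    """Expand a dataset to ``target_count`` images with randomized
    augmentation parameters (random flips plus a free rotation drawn from
    ``angle_range``), since a fixed transform set can only multiply the
    dataset by its own size.  Deterministic under ``seed``."""
    if target_count < len(records):
        raise InputError(
            f"target_count {target_count} is below the dataset size {len(records)}"
        )
    out = list(records)
    rng = np.random.default_rng(seed)
    i = 0
    while len(out) < target_count:
        rec = records[int(rng.integers(len(records)))]
        px = rec.pixels
        if rng.random() < 0.5:
            px = np.flip(px, axis=1)
        if rng.random() < 0.5:
            px = np.flip(px, axis=0)
        px = _rotate_free(px, float(rng.uniform(*angle_range)))
        out.append(ImageRecord(px, rec.label, rec.source, f"{rec.id}:aug{i:05d}"))
        i += 1
    return out


# ---------------------------------------------------------------------------
# labels and arrays
# ---------------------------------------------------------------------------

def to_binary_labels(label: str) -> str:
    """Depth class -> graft decision: superficial heals without grafting."""
    try:
        return _GRAFT_MAP[label]
    except KeyError:
        raise InputError(f"unknown burn-depth label {label!r}") from None


def label_codes(labels: Sequence[str], task: str = "degree") -> np.ndarray:
    """Integer class codes for a task ('degree': 3-way, 'graft': binary)."""
    if task == "degree":
        return np.array([LABELS.index(l) for l in labels])
    if task == "graft":
        return np.array([BINARY_LABELS.index(to_binary_labels(l)) for l in labels])
    raise UsageError(f"unknown task {task!r}; choose 'degree' or 'graft'")


def records_to_arrays(
    records: Sequence[ImageRecord], task: str = "degree"
) -> Tuple[np.ndarray, np.ndarray]:
    """Stack records into (n, 3, H, W) float32 in [0, 1] plus int codes."""
    x = np.stack([r.pixels for r in records]).astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)
    y = label_codes([r.label for r in records], task)
    return x, y


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def save_dataset(records: Sequence[ImageRecord], out_dir) -> Path:
    """Write PNGs plus ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        rel = f"images/{r.id}.png"
        Image.fromarray(r.pixels, mode="RGB").save(out_dir / rel)
        rows.append({"id": r.id, "path": rel, "label": r.label, "split": ""})
    manifest = pd.DataFrame(rows)
    path = out_dir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def load_dataset(
    manifest_path, size: Tuple[int, int] = (100, 100)
) -> Tuple[List[ImageRecord], List[dict]]:
    """Decode, resize and validate the images listed in a manifest.

    Returns ``(records, errors)``: rows that fail (missing file, unknown
    label, non-RGB image) produce an entry in ``errors`` naming the row and
    do not abort the remaining rows.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    records: List[ImageRecord] = []
    errors: List[dict] = []
    for i, row in df.iterrows():
        try:
            label = str(row["label"])
            if label not in LABELS:
                raise InputError(f"unknown label {label!r}")
            path = base / str(row["path"])
            if not path.exists():
                raise InputError(f"missing file {path}")
            with Image.open(path) as im:
                if im.mode != "RGB":
                    raise InputError(f"non-RGB image (mode {im.mode})")
                im = im.resize((size[1], size[0]), Image.BILINEAR)
                pixels = np.asarray(im, dtype=np.uint8)
            records.append(
                ImageRecord(pixels=pixels, label=label, source="file", id=str(row["id"]))
            )
        except Exception as exc:  # per-row error report
            errors.append({"row": int(i), "id": str(row.get("id", "")), "error": str(exc)})
    return records, errors
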
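"""Synthetic brain-MRI-like detection scenes with YOLO-format annotations.

Each scene is a grayscale axial-slice caricature: a dark background, a bright
skull ring, a speckled brain interior, and (for the three tumor classes) one
elliptical lesion blob with class-specific size, position and intensity
priors:

* ``glioma`` (0)     — mid-bright, lobular outline, anywhere in the brain;
* ``meningioma`` (1) — darker, round, displaced toward the cortex;
* ``no tumor`` (2)   — no lesion; the annotation covers the brain region
  itself (the labeling convention of the emulated public dataset, where the
  detector reports "no tumor" as a detectable class);
* ``pituitary`` (3)  — small, very bright, near the brain center.

The class-conditional intensity ranges are disjoint by construction, so a
trivial mean-intensity threshold classifies the annotated region; this keeps
the detection task learnable at miniature dataset sizes.

The bounding box of a lesion is recomputed from the rendered blob mask
(min/max of foreground pixels), so the emitted record is tight by
construction.  All randomness flows from explicit seeds; per-image seeds are
derived from the master seed with a splitmix64 mix so generation order and
parallelism cannot change the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from .exceptions import InvalidSpecError

__all__ = [
    "CLASS_NAMES",
    "PAPER_TRAIN_COUNTS",
    "PAPER_VAL_COUNTS",
    "SceneSpec",
    "AnnotationRecord",
    "DatasetManifest",
    "derive_seed",
    "random_scene",
    "generate_image",
    "generate_dataset",
    "read_yolo_labels",
    "write_yolo_labels",
    "load_split",
]

CLASS_NAMES = ("glioma", "meningioma", "no tumor", "pituitary")

# per-class image counts of the emulated public dataset's two splits
PAPER_TRAIN_COUNTS = (1153, 1449, 711, 1424)
PAPER_VAL_COUNTS = (136, 140, 100, 136)

# class-conditional lesion priors: (intensity lo, hi), (axis fraction lo, hi)
_INTENSITY = {0: (195.0, 210.0), 1: (145.0, 160.0), 3: (232.0, 248.0)}
_AXIS_FRAC = {0: (0.09, 0.16), 1: (0.08, 0.14), 3: (0.045, 0.085)}
_BRAIN_MEAN = 90.0


def derive_seed(master: int, index: int) -> int:
    """Splitmix64-style mix of (master, index) to an independent stream seed."""
    mask = (1 << 64) - 1
    z = (master * 0x9E3779B97F4A7C15 + index) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    return (z ^ (z >> 31)) & mask


@dataclass(frozen=True)
class AnnotationRecord:
    """One YOLO-format annotation: class id and a normalized center box."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidSpecError(f"annotation extents must be positive: {self}")
        if not (0 < self.cx <= 1 and 0 < self.cy <= 1 and self.w <= 1 and self.h <= 1):
            raise InvalidSpecError(f"annotation outside the unit square: {self}")

    def to_pixels(self, image_size: int) -> tuple[float, float, float, float]:
        """Corner-format pixel box (x1, y1, x2, y2)."""
        s = image_size
        return (
            (self.cx - self.w / 2) * s,
            (self.cy - self.h / 2) * s,
            (self.cx + self.w / 2) * s,
            (self.cy + self.h / 2) * s,
        )


@dataclass(frozen=True)
class SceneSpec:
    """Full deterministic description of one rendered scene."""

    class_id: int
    image_size: int = 640
    seed: int = 0
    # lesion geometry, as fractions of image size
    blob_center: tuple[float, float] = (0.5, 0.5)
    blob_axes: tuple[float, float] = (0.12, 0.10)
    blob_rotation: float = 0.0
    blob_intensity: float = 200.0
    blob_lobularity: float = 0.0  # radial modulation amplitude (gliomas)
    texture_noise: float = 4.0
    # background
    brain_axes: tuple[float, float] = (0.40, 0.44)
    skull_thickness: float = 0.035
    speckle_noise: float = 8.0

    def __post_init__(self):
        if self.class_id not in range(4):
            raise InvalidSpecError(f"class_id must be 0..3, got {self.class_id}")
        if min(self.blob_axes) <= 0 or min(self.brain_axes) <= 0:
            raise InvalidSpecError("ellipse axes must be positive")
        if self.class_id != 2:
            # lesion (with lobular margin) must stay inside the brain ellipse
            margin = 1.0 + self.blob_lobularity
            dx = (self.blob_center[0] - 0.5) / self.brain_axes[0]
            dy = (self.blob_center[1] - 0.5) / self.brain_axes[1]
            reach = math.hypot(dx, dy) + margin * max(self.blob_axes) / min(self.brain_axes)
            if reach > 1.0:
                raise InvalidSpecError("lesion blob would exceed the brain region")


def random_scene(class_id: int, image_size: int, rng: np.random.Generator,
                 seed: int | None = None) -> SceneSpec:
    """Draw a scene from the class-conditional priors."""
    if seed is None:
        seed = int(rng.integers(0, 2**31 - 1))
    brain_axes = (float(rng.uniform(0.36, 0.42)), float(rng.uniform(0.40, 0.46)))
    if class_id == 2:
        return SceneSpec(class_id=2, image_size=image_size, seed=seed,
                         brain_axes=brain_axes)
    lo, hi = _AXIS_FRAC[class_id]
    axes = (float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi)))
    lob = float(rng.uniform(0.15, 0.3)) if class_id == 0 else 0.0
    # admissible center: inside the brain with room for the blob
    reach = (1.0 + lob) * max(axes) / min(brain_axes)
    room = max(0.05, 1.0 - reach - 0.05)
    if class_id == 1:  # meningiomas sit toward the cortex
        r = rng.uniform(0.6 * room, room)
    elif class_id == 3:  # pituitary lesions sit centrally
        r = rng.uniform(0.0, 0.25 * room)
    else:
        r = rng.uniform(0.0, room)
    theta = rng.uniform(0, 2 * math.pi)
    center = (
        0.5 + float(r * math.cos(theta)) * brain_axes[0],
        0.5 + float(r * math.sin(theta)) * brain_axes[1],
    )
    ilo, ihi = _INTENSITY[class_id]
    return SceneSpec(
        class_id=class_id,
        image_size=image_size,
        seed=seed,
        blob_center=center,
        blob_axes=axes,
        blob_rotation=float(rng.uniform(0, math.pi)),
        blob_intensity=float(rng.uniform(ilo, ihi)),
        blob_lobularity=lob,
        brain_axes=brain_axes,
    )


def generate_image(spec: SceneSpec) -> tuple[np.ndarray, list[AnnotationRecord]]:
    """Render a scene to an 8-bit RGB image plus its annotations."""
    s = spec.image_size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:s, 0:s]
    u = (xx + 0.5) / s - 0.5
    v = (yy + 0.5) / s - 0.5

    img = np.full((s, s), 8.0) + rng.normal(0, 2.0, (s, s))
    ax, ay = spec.brain_axes
    r_brain = np.sqrt((u / ax) ** 2 + (v / ay) ** 2)
    brain = r_brain <= 1.0
    skull = (r_brain > 1.0) & (r_brain <= 1.0 + spec.skull_thickness / min(ax, ay))
    img[brain] = _BRAIN_MEAN + rng.normal(0, spec.speckle_noise, int(brain.sum()))
    img[skull] = 225.0 + rng.normal(0, 5.0, int(skull.sum()))

    if spec.class_id == 2:
        ys, xs = np.nonzero(brain)
        record = _mask_to_record(xs, ys, s, 2)
        return _finalize(img), [record]

    cxp = (spec.blob_center[0] - 0.5)
    cyp = (spec.blob_center[1] - 0.5)
    du, dv = u - cxp, v - cyp
    rot = spec.blob_rotation
    ru = du * math.cos(rot) + dv * math.sin(rot)
    rv = -du * math.sin(rot) + dv * math.cos(rot)
    bx, by = spec.blob_axes
    radius = np.sqrt((ru / bx) ** 2 + (rv / by) ** 2)
    if spec.blob_lobularity:
        phase = rng.uniform(0, 2 * math.pi)
        theta = np.arctan2(rv, ru)
        radius = radius / (1.0 + spec.blob_lobularity * np.sin(5 * theta + phase))
    blob = (radius <= 1.0) & brain
    if not blob.any():
        raise InvalidSpecError("lesion blob rendered empty; axes too small for image size")
    img[blob] = spec.blob_intensity + rng.normal(0, spec.texture_noise, int(blob.sum()))
    ys, xs = np.nonzero(blob)
    record = _mask_to_record(xs, ys, s, spec.class_id)
    return _finalize(img), [record]


def _mask_to_record(xs: np.ndarray, ys: np.ndarray, s: int, class_id: int) -> AnnotationRecord:
    x1, x2 = int(xs.min()), int(xs.max()) + 1
    y1, y2 = int(ys.min()), int(ys.max()) + 1
    return AnnotationRecord(
        class_id,
        round((x1 + x2) / 2 / s, 6),
        round((y1 + y2) / 2 / s, 6),
        round((x2 - x1) / s, 6),
        round((y2 - y1) / s, 6),
    )


def _finalize(img: np.ndarray) -> np.ndarray:
    g = np.clip(img, 0, 255).astype(np.uint8)
    return np.repeat(g[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# YOLO label files
# ---------------------------------------------------------------------------


def write_yolo_labels(records: list[AnnotationRecord], path: str | Path) -> None:
    lines = [
        f"{r.class_id} {r.cx:.6f} {r.cy:.6f} {r.w:.6f} {r.h:.6f}" for r in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path: str | Path) -> list[AnnotationRecord]:
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise InvalidSpecError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
        try:
            cid = int(parts[0])
            vals = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise InvalidSpecError(f"{path}:{lineno}: {exc}") from exc
        records.append(AnnotationRecord(cid, *vals))
    return records


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


@dataclass
class DatasetManifest:
    root: Path
    names: tuple[str, ...]
    splits: dict[str, dict[str, Path]]  # split -> {images, labels}
    counts: dict[str, tuple[int, ...]]  # split -> per-class image counts
    image_size: int = 640
    yaml_path: Path | None = None

    def images(self, split: str) -> list[Path]:
        return sorted(self.splits[split]["images"].glob("*.png"))

    def label_for(self, image_path: Path, split: str) -> Path:
        return self.splits[split]["labels"] / (image_path.stem + ".txt")

    @classmethod
    def load(cls, yaml_path: str | Path) -> "DatasetManifest":
        yaml_path = Path(yaml_path)
        doc = yaml.safe_load(yaml_path.read_text())
        root = yaml_path.parent / doc["path"]
        splits = {}
        for split in ("train", "val"):
            if split in doc:
                img_dir = root / doc[split]
                splits[split] = {
                    "images": img_dir,
                    "labels": root / "labels" / split,
                }
        names = tuple(doc["names"][i] for i in sorted(doc["names"]))
        counts = {k: tuple(v) for k, v in doc.get("counts", {}).items()}
        return cls(root, names, splits, counts, doc.get("image_size", 640), yaml_path)


def _scaled_counts(counts: tuple[int, ...], scale: float) -> tuple[int, ...]:
    return tuple(int(round(c * scale)) for c in counts)


def generate_dataset(
    out_dir: str | Path,
    seed: int = 0,
    scale: float = 0.1,
    image_size: int = 640,
    counts: dict[str, tuple[int, int, int, int]] | None = None,
) -> DatasetManifest:
    """Write a miniature dataset emulating the public schema.

    ``counts`` gives per-class image totals for each split; by default the
    emulated dataset's per-class counts are scaled by ``scale``.
    """
    out = Path(out_dir)
    if counts is None:
        counts = {
            "train": _scaled_counts(PAPER_TRAIN_COUNTS, scale),
            "val": _scaled_counts(PAPER_VAL_COUNTS, scale),
        }
    if any(c < 0 for split in counts.values() for c in split):
        raise InvalidSpecError("per-class counts must be >= 0")
    splits: dict[str, dict[str, Path]] = {}
    index = 0
    for split, per_class in counts.items():
        img_dir = out / "images" / split
        lbl_dir = out / "labels" / split
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        splits[split] = {"images": img_dir, "labels": lbl_dir}
        for class_id, n in enumerate(per_class):
            for k in range(n):
                img_seed = derive_seed(seed, index)
                rng = np.random.default_rng(img_seed)
                spec = random_scene(class_id, image_size, rng, seed=img_seed)
                img, records = generate_image(spec)
                stem = f"{split}_{CLASS_NAMES[class_id].replace(' ', '')}_{k:04d}"
                Image.fromarray(img).save(img_dir / f"{stem}.png")
                write_yolo_labels(records, lbl_dir / f"{stem}.txt")
                index += 1
    manifest = DatasetManifest(
        out, CLASS_NAMES, splits,
        {k: tuple(v) for k, v in counts.items()}, image_size,
    )
    doc = {
        "path": ".",
        "train": "images/train",
        "val": "images/val",
        "names": {i: n for i, n in enumerate(CLASS_NAMES)},
        "counts": {k: list(v) for k, v in counts.items()},
        "image_size": image_size,
    }
    yaml_path = out / "dataset.yaml"
    yaml_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    manifest.yaml_path = yaml_path
    return manifest


def load_split(manifest: DatasetManifest, split: str) -> list[dict]:
    """Load a split into memory: float images in [0,1] plus pixel boxes."""
    samples = []
    for img_path in manifest.images(split):
        img = np.asarray(Image.open(img_path), dtype=np.float32) / 255.0
        records = read_yolo_labels(manifest.label_for(img_path, split))
        size = img.shape[0]
        boxes = np.array(
            [r.to_pixels(size) for r in records], dtype=np.float32
        ).reshape(-1, 4)
        classes = np.array([r.class_id for r in records], dtype=np.int64)
        samples.append(
            {"path": img_path, "image": img.transpose(2, 0, 1),
             "boxes": boxes, "classes": classes}
        )
    return samples
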
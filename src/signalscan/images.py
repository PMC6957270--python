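"""Labeled face-image records: loading, validation, standardization, persistence.

Images are stored as H x W x 3 arrays of float64 in [0, 1]. Coordinates are
0-based (row, column) with row 0 at the top. Integer raster values are mapped
to [0, 1] by dividing by the format's maximum value (255 for 8-bit, 65535 for
16-bit), so a saturated 8-bit pixel becomes exactly 1.0.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("image_id", "file", "individual_id", "species_id")

#: Standard face dimensions: width must be even so the face can be split at
#: the vertical midline into two equal hemi-faces.
STANDARD_WIDTH = 392
STANDARD_HEIGHT = 297

SIDES = ("whole", "left", "right")


class ManifestSchemaError(ValueError):
    """Manifest table is missing required columns."""


class ManifestValidationError(ValueError):
    """Manifest contents violate an invariant (duplicates, shapes, labels)."""


def _check_pixels(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"pixels must be H x W x 3, got shape {pixels.shape}")
    if not np.all(np.isfinite(pixels)):
        raise ValueError("pixel values must be finite")
    if pixels.min() < 0.0 or pixels.max() > 1.0:
        raise ValueError("pixel values must lie in [0, 1]")
    return pixels


@dataclass(frozen=True)
class ImageRecord:
    """A single labeled face image.

    ``side`` records whether the pixels cover the whole face or one
    hemi-face (``left``/``right`` half by image column, no mirroring).
    """

    image_id: str
    individual_id: str
    species_id: str
    pixels: np.ndarray
    side: str = "whole"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", _check_pixels(self.pixels))
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ColorTransform:
    """A 3x3 linear map applied to each pixel's channel vector."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError(f"color transform matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("color transform matrix entries must be finite")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "ColorTransform":
        return cls(np.eye(3))


@dataclass(frozen=True)
class Manifest:
    """An ordered collection of ImageRecords grouped by individual and species.

    Invariants (checked on construction): image ids unique, all images share
    one shape and side, every individual belongs to exactly one species.
    ``species_index`` preserves first-appearance order and is the tie-break
    order used by the classifier.
    """

    records: tuple[ImageRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ManifestValidationError(f"duplicate image_id(s): {dupes}")
        shapes = {r.pixels.shape for r in self.records}
        if len(shapes) > 1:
            raise ManifestValidationError(
                f"all images in a manifest must share dimensions; found {sorted(shapes)}"
            )
        sides = {r.side for r in self.records}
        if len(sides) > 1:
            raise ManifestValidationError(
                f"all images in a manifest must share a side; found {sorted(sides)}"
            )
        ind2sp: dict[str, str] = {}
        for r in self.records:
            sp = ind2sp.setdefault(r.individual_id, r.species_id)
            if sp != r.species_id:
                raise ManifestValidationError(
                    f"individual {r.individual_id!r} assigned to multiple species"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species_index(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species_id, None)
        return list(seen)

    @property
    def individual_index(self) -> dict[str, str]:
        return {r.individual_id: r.species_id for r in self.records}

    @property
    def side(self) -> str:
        return self.records[0].side if self.records else "whole"

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.records[0].pixels.shape[:2] if self.records else None

    def individuals_of(self, species_id: str) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            if r.species_id == species_id:
                seen.setdefault(r.individual_id, None)
        return list(seen)

    def images_of_individual(self, individual_id: str) -> list[ImageRecord]:
        return [r for r in self.records if r.individual_id == individual_id]

    def without_individual(self, individual_id: str) -> "Manifest":
        return Manifest(tuple(r for r in self.records if r.individual_id != individual_id))

    def subset_species(self, species_ids) -> "Manifest":
        keep = set(species_ids)
        unknown = keep - set(self.species_index)
        if unknown:
            raise ManifestValidationError(f"unknown species: {sorted(unknown)}")
        return Manifest(tuple(r for r in self.records if r.species_id in keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "individual_id": [r.individual_id for r in self.records],
                "species_id": [r.species_id for r in self.records],
                "side": [r.side for r in self.records],
            }
        )


def decode_image(path: str) -> np.ndarray:
    """Read a raster file to float64 H x W x 3 in [0, 1].

    Grayscale images are broadcast to three channels; an alpha channel, if
    present, is dropped. Integer data are scaled by the dtype's max value.
    """
    arr = iio.imread(path)
    if np.issubdtype(arr.dtype, np.integer):
        maxval = float(np.iinfo(arr.dtype).max)
        arr = arr.astype(np.float64) / maxval
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    return np.clip(arr, 0.0, 1.0)


def _png_info(meta: dict | None):
    if not meta:
        return None
    from PIL.PngImagePlugin import PngInfo

    info = PngInfo()
    for k, v in meta.items():
        info.add_text(str(k), str(v))
    return info


def write_image16(path: str, pixels: np.ndarray, meta: dict | None = None) -> None:
    """Write a [0,1] float image at 16-bit depth.

    Single-channel images (H x W, or H x W x 3 with identical channels) go
    to 16-bit grayscale PNG; color images go to 16-bit RGB TIFF (PNG
    encoders available here do not support 16-bit color). Quantization
    error is at most 0.5/65535 per channel.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    grayscale = arr.ndim == 2
    if not grayscale:
        arr = _check_pixels(arr)
        grayscale = bool(
            np.array_equal(arr[:, :, 0], arr[:, :, 1])
            and np.array_equal(arr[:, :, 0], arr[:, :, 2])
        )
        if grayscale:
            arr = arr[:, :, 0]
    if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 1:
        raise ValueError("pixel values must be finite and in [0, 1]")
    quant = np.round(arr * 65535.0).astype(np.uint16)
    if grayscale:
        if not path.endswith(".png"):
            raise ValueError("grayscale 16-bit output must be a .png path")
        Image.fromarray(quant).save(path, pnginfo=_png_info(meta))
    else:
        if not (path.endswith(".tif") or path.endswith(".tiff")):
            raise ValueError("16-bit color output must be a .tif path")
        import tifffile

        tifffile.imwrite(path, quant, photometric="rgb",
                         description=str(meta) if meta else None)


def write_png8(path: str, pixels: np.ndarray, meta: dict | None = None) -> None:
    """Write a [0,1] float color image as 8-bit RGB PNG."""
    pixels = _check_pixels(pixels)
    arr = np.round(pixels * 255.0).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path, pnginfo=_png_info(meta))


def load_manifest(manifest_path: str, image_root: str | None = None) -> Manifest:
    """Load a manifest CSV (columns image_id,file,individual_id,species_id).

    ``file`` paths are resolved relative to ``image_root`` (default: the
    manifest's directory). Rows whose files cannot be read are reported and
    raise after the full pass so all problems surface at once.
    """
    df = pd.read_csv(manifest_path, dtype=str, comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(
            f"manifest {manifest_path} missing column(s) {missing}; "
            f"expected {list(MANIFEST_COLUMNS)}"
        )
    if image_root is None:
        image_root = os.path.dirname(os.path.abspath(manifest_path))
    if df.empty:
        logger.warning("manifest %s is empty", manifest_path)
        return Manifest(())
    records = []
    bad: list[str] = []
    for row in df.itertuples(index=False):
        path = os.path.join(image_root, row.file)
        try:
            pixels = decode_image(path)
        except Exception as exc:  # decoder backends raise heterogeneous types
            logger.error("unreadable image %s (%s): %s", path, row.image_id, exc)
            bad.append(row.image_id)
            continue
        records.append(
            ImageRecord(
                image_id=row.image_id,
                individual_id=row.individual_id,
                species_id=row.species_id,
                pixels=pixels,
            )
        )
    if bad:
        raise ManifestValidationError(f"unreadable image files for rows: {bad}")
    return Manifest(tuple(records))


def filter_min_individuals(m: Manifest, min_individuals: int) -> Manifest:
    """Keep only species with at least ``min_individuals`` distinct individuals.

    Species order is preserved. Raises if fewer than two species survive
    (nearest-centroid classification is undefined with a single class).
    """
    if min_individuals < 1:
        raise ValueError("min_individuals must be >= 1")
    keep = [
        sp for sp in m.species_index if len(m.individuals_of(sp)) >= min_individuals
    ]
    if len(keep) < 2:
        raise ManifestValidationError(
            f"filtering at min_individuals={min_individuals} leaves "
            f"{len(keep)} species; need at least 2 for classification"
        )
    keepset = set(keep)
    return Manifest(tuple(r for r in m.records if r.species_id in keepset))


def apply_color_transform(
    img: ImageRecord, t: ColorTransform, clip: bool = True
) -> ImageRecord:
    """Left-multiply every pixel's channel vector by the transform matrix.

    Used to move camera RGB into a receiver cone-excitation (LMS) space when
    a calibration matrix is available; the default pipeline matrix is the
    identity. With ``clip`` the result is clamped back to [0, 1].
    """
    out = np.einsum("ij,hwj->hwi", t.matrix, img.pixels)
    if clip:
        out = np.clip(out, 0.0, 1.0)
    elif out.min() < 0.0 or out.max() > 1.0:
        raise ValueError(
            "color transform produced values outside [0, 1]; pass clip=True"
        )
    meta = dict(img.meta)
    meta["color_transform"] = "applied"
    return replace(img, pixels=out, meta=meta)


def resize_standard(img: ImageRecord, width: int, height: int) -> ImageRecord:
    """Resize to exactly (height, width).

    Downscaling uses area (box) interpolation, which preserves mean level;
    upscaling uses bilinear. The method used is recorded in ``meta``.
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"target dimensions must be positive, got {width}x{height}")
    h, w = img.pixels.shape[:2]
    if (h, w) == (height, width):
        meta = dict(img.meta)
        meta["resize"] = "identity"
        return replace(img, meta=meta)
    method = Image.BOX if (width <= w and height <= h) else Image.BILINEAR
    channels = []
    for c in range(3):
        im = Image.fromarray(img.pixels[:, :, c].astype(np.float32), mode="F")
        im = im.resize((width, height), resample=method)
        channels.append(np.asarray(im, dtype=np.float64))
    out = np.clip(np.stack(channels, axis=-1), 0.0, 1.0)
    meta = dict(img.meta)
    meta["resize"] = "box" if method == Image.BOX else "bilinear"
    return replace(img, pixels=out, meta=meta)


def split_hemiface(img: ImageRecord) -> tuple[ImageRecord, ImageRecord]:
    """Split a whole-face image at the vertical midline into (left, right).

    Left = columns [0, W/2), right = [W/2, W); no mirroring. Requires an even
    width (re-standardize to an even width first if necessary).
    """
    h, w = img.pixels.shape[:2]
    if w % 2 != 0:
        raise ValueError(
            f"image width {w} is odd; re-standardize to an even width before "
            "splitting into hemi-faces"
        )
    if img.side != "whole":
        raise ValueError(f"cannot split a {img.side!r} hemi-face")
    half = w // 2
    left = replace(
        img,
        image_id=f"{img.image_id}_L",
        pixels=img.pixels[:, :half, :].copy(),
        side="left",
    )
    right = replace(
        img,
        image_id=f"{img.image_id}_R",
        pixels=img.pixels[:, half:, :].copy(),
        side="right",
    )
    return left, right


def split_manifest_hemifaces(m: Manifest) -> tuple[Manifest, Manifest]:
    """Split every record; returns (left manifest, right manifest)."""
    lefts, rights = [], []
    for r in m.records:
        left, right = split_hemiface(r)
        lefts.append(left)
        rights.append(right)
    return Manifest(tuple(lefts)), Manifest(tuple(rights))
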
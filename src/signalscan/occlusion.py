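"""The occlude-reclassify scan.

For every image the classifier gets right, a disc-shaped occluder filled
with that species' mean face color is slid across the image one pixel at a
time. At each position the occluded image is re-projected into face space
and re-classified; a position whose occlusion breaks classification marks
face information essential to recognizing the species. The scan records a
binary correct/incorrect value at every tested occluder center.

Only centers where the full disc fits inside the image are tested (a margin
of one radius on every border); border cells are marked untested, never
imputed.

Because the occluded image differs from the original only inside the disc,
the change in each eigenface weight is a local correlation of the disc
kernel with eigenface x (fill - image). The accelerated path computes all
centers' weight deltas at once with FFT convolution, one transform per
eigenface; the naive per-center recomputation is retained as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .facespace import AverageFaceSet, FaceSpace, classify, project
from .images import ImageRecord, Manifest

UNTESTED = -1  # sentinel in OcclusionMap.values


@dataclass(frozen=True)
class OccluderSpec:
    """Disc occluder: radius in pixels and fill policy.

    ``species_mean_color`` fills with the per-channel mean of the (training)
    species average face; ``fixed_color`` uses ``fixed_color`` verbatim.
    """

    radius: int = 30
    fill_policy: str = "species_mean_color"
    fixed_color: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("occluder radius must be >= 0")
        if self.fill_policy not in ("species_mean_color", "fixed_color"):
            raise ValueError(f"unknown fill policy {self.fill_policy!r}")
        if self.fill_policy == "fixed_color":
            if self.fixed_color is None:
                raise ValueError("fixed_color fill policy requires a color")
            c = np.asarray(self.fixed_color, dtype=np.float64)
            if c.shape != (3,) or c.min() < 0 or c.max() > 1:
                raise ValueError("fixed_color must be 3 values in [0, 1]")


@dataclass(frozen=True)
class TestedRegion:
    """Boolean grid of valid occluder centers (full disc fits in image)."""

    mask: np.ndarray

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class OcclusionMap:
    """Per-image binary correctness grid over occluder centers.

    values[r, c] is 1 if the image is still classified correctly with the
    occluder centered at (r, c), 0 if not, and UNTESTED (-1) outside the
    tested region.
    """

    image_id: str
    individual_id: str
    species_id: str
    values: np.ndarray  # int8 grid over {0, 1, UNTESTED}
    occluder: OccluderSpec

    @property
    def tested_mask(self) -> np.ndarray:
        return self.values != UNTESTED


def disc_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets (dr, dc) with Euclidean norm <= radius.

    Points at exactly the radius are included ("thirty-pixel radius" is a
    closed disc).
    """
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    inside = dr**2 + dc**2 <= r**2
    return np.stack([dr[inside], dc[inside]], axis=1)


def disc_kernel(radius: int) -> np.ndarray:
    """(2r+1) x (2r+1) float binary disc kernel."""
    r = int(radius)
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    return (dr**2 + dc**2 <= r**2).astype(np.float64)


def species_mean_color(avg: AverageFaceSet, species_id: str) -> np.ndarray:
    """Per-channel mean of the species average face over all its pixels."""
    if species_id not in avg.species_averages:
        raise KeyError(f"unknown species {species_id!r}")
    return avg.species_averages[species_id].mean(axis=(0, 1))


def resolve_fill(
    spec: OccluderSpec, avg: AverageFaceSet, species_id: str
) -> np.ndarray:
    if spec.fill_policy == "fixed_color":
        return np.asarray(spec.fixed_color, dtype=np.float64)
    return species_mean_color(avg, species_id)


def occlude(
    pixels: np.ndarray,
    center: tuple[int, int],
    spec: OccluderSpec,
    fill: np.ndarray,
) -> np.ndarray:
    """Set every pixel within ``spec.radius`` of ``center`` to ``fill``.

    The disc is clipped at image borders; pixels outside it are untouched.
    """
    h, w = pixels.shape[:2]
    r0, c0 = center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError(f"center {center} outside {h}x{w} image")
    out = pixels.copy()
    offs = disc_offsets(spec.radius)
    rr = offs[:, 0] + r0
    cc = offs[:, 1] + c0
    ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    out[rr[ok], cc[ok]] = np.asarray(fill, dtype=np.float64)
    return out


def tested_region(height: int, width: int, spec: OccluderSpec) -> TestedRegion:
    """Centers at least one radius away from every border."""
    r = spec.radius
    if height <= 2 * r or width <= 2 * r:
        raise ValueError(
            f"image {height}x{width} too small for occluder radius {r}; "
            "need both dimensions > 2*radius"
        )
    mask = np.zeros((height, width), dtype=bool)
    mask[r : height - r, r : width - r] = True
    return TestedRegion(mask=mask)


def _weight_deltas(
    pixels: np.ndarray, fill: np.ndarray, fs: FaceSpace, radius: int
) -> np.ndarray:
    """Weight change per occluder center, shape (H, W, k).

    delta_j(center) = sum over disc pixels p of e_j(p) . (fill - pixels(p)),
    a correlation of the (symmetric) disc kernel with the per-pixel inner
    product map, evaluated with FFT convolution.
    """
    h, w, _ = pixels.shape
    diff = fill[None, None, :] - pixels  # H x W x 3
    kernel = disc_kernel(radius)
    deltas = np.empty((h, w, fs.k), dtype=np.float64)
    for j in range(fs.k):
        e = fs.eigenfaces[j].reshape(h, w, 3)
        m = np.einsum("hwc,hwc->hw", e, diff)
        deltas[:, :, j] = fftconvolve(m, kernel, mode="same")
    return deltas


def occlusion_map(
    img: ImageRecord,
    fs: FaceSpace,
    avg: AverageFaceSet,
    spec: OccluderSpec,
    naive: bool = False,
) -> OcclusionMap:
    """Scan one image: binary correctness at every tested occluder center.

    The image must be correctly classified unoccluded (the scan is only
    meaningful, and only defined, for correctly classified images).

    ``naive=True`` recomputes occlude -> project -> classify at every center
    (the oracle path); the default path computes the same weights via
    convolution.
    """
    base = classify(project(img.pixels, fs), fs, true_species=img.species_id)
    if not base.correct:
        raise ValueError(
            f"image {img.image_id!r} is misclassified unoccluded "
            f"(predicted {base.predicted_species!r}); the occlude-reclassify "
            "scan applies only to correctly classified images"
        )
    h, w = img.pixels.shape[:2]
    region = tested_region(h, w, spec)
    fill = resolve_fill(spec, avg, img.species_id)
    values = np.full((h, w), UNTESTED, dtype=np.int8)
    true_idx = fs.species_index.index(img.species_id)
    if naive:
        centers = np.argwhere(region.mask)
        for r0, c0 in centers:
            occ = occlude(img.pixels, (int(r0), int(c0)), spec, fill)
            res = classify(project(occ, fs), fs)
            values[r0, c0] = 1 if res.predicted_species == img.species_id else 0
    else:
        w0 = project(img.pixels, fs)
        deltas = _weight_deltas(img.pixels, fill, fs, spec.radius)
        W = deltas[region.mask] + w0  # N x k occluded weights
        C = fs.centroid_matrix()  # S x k
        d2 = np.sum((W[:, None, :] - C[None, :, :]) ** 2, axis=2)
        pred = np.argmin(d2, axis=1)  # first minimum wins, as in classify()
        values[region.mask] = (pred == true_idx).astype(np.int8)
    return OcclusionMap(
        image_id=img.image_id,
        individual_id=img.individual_id,
        species_id=img.species_id,
        values=values,
        occluder=spec,
    )


def scan_dataset(
    m: Manifest,
    loo_result,
    spec: OccluderSpec,
    naive: bool = False,
) -> list[OcclusionMap]:
    """Occlusion maps for every correctly classified image in a LOO run.

    Each image is scanned under its own leave-one-out fold: the face space
    and fill color come from the training model that excluded that image's
    individual, so the scan sees exactly the model that classified it.
    """
    if loo_result.mode != "distinct_images":
        raise ValueError("scan_dataset requires a distinct_images LOO result")
    by_id = {r.image_id: r for r in m.records}
    maps = []
    for row in loo_result.table.itertuples(index=False):
        if not row.correct:
            continue
        if row.individual_id not in loo_result.folds:
            raise KeyError(f"missing LOO fold for individual {row.individual_id!r}")
        avg, fs = loo_result.folds[row.individual_id]
        maps.append(occlusion_map(by_id[row.image_id], fs, avg, spec, naive=naive))
    return maps
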
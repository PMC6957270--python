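"""Species heatmaps, critical-region metrics, and composite rendering.

Binary occlusion maps are averaged in two stages — within each individual
over its images, then across individuals — giving a per-species heatmap in
[0, 1]: the fraction of correct classifications when each cell is occluded.
Cells below 1 are "critical": occluding them broke classification for at
least one image.

Two summary numbers describe each species' heatmap:

* ``proportion_misclassified`` — critical cells / tested cells. Measures how
  widely the essential face information is spread.
* ``mean_classification_error`` — mean of (1 - value) over critical cells
  (0 if there are none). Measures how essential the flagged regions are:
  higher means occlusion there broke classification for more images. The raw
  mean heatmap value over critical cells is emitted alongside for
  transparency.

A species with a single small diagnostic trait (a nose spot, say) shows a
small proportion with a high mean error; a species recognized by broader
face information shows the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import Manifest
from .occlusion import OccluderSpec, OcclusionMap


@dataclass(frozen=True)
class Heatmap:
    """Per-species fraction-correct grid; NaN outside the tested region."""

    species_id: str
    values: np.ndarray  # float64 H x W, NaN untested
    n_individuals: int
    n_images: int
    occluder: OccluderSpec

    @property
    def tested_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class MetricsRow:
    species_id: str
    n_individuals: int
    n_images: int
    n_tested_cells: int
    n_critical_cells: int
    proportion_misclassified: float
    mean_classification_error: float
    mean_value_critical_raw: float  # raw heatmap mean over critical cells


# Species subsets for range-overlap (sympatric) analyses: every species in
# the source database whose geographic range overlaps the target's by >1%,
# plus the target itself.
SYMPATRIC_PRESETS: dict[str, list[str]] = {
    "C. nictitans": [
        "C. nictitans",
        "A. nigroviridis",
        "C. ascanius",
        "C. diana",
        "C. erythrotis",
        "C. mona",
        "C. neglectus",
        "C. petaurista",
        "C. sclateri",
        "Ch. tantalus",
        "E. patas",
    ],
    "C. mona": [
        "C. mona",
        "C. erythrotis",
        "C. nictitans",
        "C. petaurista",
        "C. sclateri",
        "Ch. tantalus",
        "E. patas",
    ],
}


def aggregate_heatmap(maps: list[OcclusionMap], species_id: str) -> Heatmap:
    """Two-stage mean of binary maps: images -> individual -> species."""
    if not maps:
        raise ValueError("cannot aggregate an empty list of occlusion maps")
    bad_sp = [m.image_id for m in maps if m.species_id != species_id]
    if bad_sp:
        raise ValueError(f"maps from other species passed for {species_id!r}: {bad_sp}")
    shapes = {m.values.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"occlusion maps differ in shape: {sorted(shapes)}")
    specs = {m.occluder for m in maps}
    if len(specs) > 1:
        raise ValueError("occlusion maps were produced with different occluder specs")
    masks = {m.tested_mask.tobytes() for m in maps}
    if len(masks) > 1:
        raise ValueError("occlusion maps differ in tested region")
    tested = maps[0].tested_mask
    by_ind: dict[str, list[np.ndarray]] = {}
    for m in maps:
        by_ind.setdefault(m.individual_id, []).append(m.values.astype(np.float64))
    ind_means = [np.mean(v, axis=0) for v in by_ind.values()]
    values = np.mean(ind_means, axis=0)
    values[~tested] = np.nan
    return Heatmap(
        species_id=species_id,
        values=values,
        n_individuals=len(by_ind),
        n_images=len(maps),
        occluder=maps[0].occluder,
    )


def compute_metrics(h: Heatmap) -> MetricsRow:
    """Spread and importance of critical regions (see module docstring)."""
    tested = h.values[h.tested_mask]
    if tested.size == 0:
        raise ValueError(f"heatmap for {h.species_id!r} has no tested cells")
    critical = tested[tested < 1.0]
    proportion = critical.size / tested.size
    if critical.size:
        mean_error = float(np.mean(1.0 - critical))
        raw = float(np.mean(critical))
    else:
        mean_error = 0.0
        raw = float("nan")
    return MetricsRow(
        species_id=h.species_id,
        n_individuals=h.n_individuals,
        n_images=h.n_images,
        n_tested_cells=int(tested.size),
        n_critical_cells=int(critical.size),
        proportion_misclassified=float(proportion),
        mean_classification_error=mean_error,
        mean_value_critical_raw=raw,
    )


def render_composite(
    h: Heatmap,
    species_average: np.ndarray,
    colormap_name: str = "viridis",
    alpha: float = 0.5,
) -> np.ndarray:
    """Blend a colormapped heatmap over the greyscale species average face.

    Output = alpha * colormap(heatmap) + (1 - alpha) * greyscale(average);
    untested border cells show the greyscale face only. Greyscale uses
    Rec. 709 luminance weights on the displayed color space.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if species_average.shape[:2] != h.values.shape:
        raise ValueError(
            f"species average {species_average.shape[:2]} does not match "
            f"heatmap {h.values.shape}"
        )
    import matplotlib

    try:
        cmap = matplotlib.colormaps[colormap_name]
    except KeyError as exc:
        raise ValueError(f"unknown colormap {colormap_name!r}") from exc
    lum = species_average @ np.array([0.2126, 0.7152, 0.0722])
    grey = np.stack([lum] * 3, axis=-1)
    filled = np.where(np.isnan(h.values), 1.0, h.values)
    colored = np.asarray(cmap(filled), dtype=np.float64)[:, :, :3]
    out = alpha * colored + (1.0 - alpha) * grey
    untested = ~h.tested_mask
    out[untested] = grey[untested]
    return np.clip(out, 0.0, 1.0)


def select_species_subset(
    m: Manifest, target_species: str, subset: list[str]
) -> Manifest:
    """Restrict a manifest to a target species plus a comparison subset.

    Used for the sympatric analyses: classify the target against exactly the
    species it could encounter in the wild. ``SYMPATRIC_PRESETS`` ships the
    range-overlap subsets for *C. nictitans* and *C. mona*.
    """
    wanted = list(dict.fromkeys([target_species, *subset]))
    missing = [s for s in wanted if s not in m.species_index]
    if missing:
        raise ValueError(f"species not in manifest: {missing}")
    return m.subset_species(wanted)
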
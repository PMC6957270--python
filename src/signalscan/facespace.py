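"""Average faces, eigenface decomposition, and nearest-centroid classification.

The model follows the classic eigenface construction: species average faces
are centered on their grand mean and decomposed by PCA; each face is then a
point in "face space", the coordinate system of eigenface weights, whose
origin is the average face. A new image is classified as the species whose
average face (centroid) is nearest in Euclidean distance in that space.

Averaging is two-stage throughout: images -> individual average -> species
average. The species average is the mean of individual averages, NOT the
pooled mean over raw images, so individuals contribute equally regardless of
how many photographs each has.

Leave-one-out evaluation removes one individual at a time, rebuilds the
entire face space from the remaining individuals, and classifies the held-out
individual's images (or its average face) against that model, so no identity
information leaks from test into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import Manifest


@dataclass(frozen=True)
class AverageFaceSet:
    """Individual and species average faces (two-stage means)."""

    individual_averages: dict[str, np.ndarray]
    species_averages: dict[str, np.ndarray]
    individual_index: dict[str, str]  # individual -> species
    species_index: list[str]
    side: str = "whole"

    def individuals_of(self, species_id: str) -> list[str]:
        return [i for i, s in self.individual_index.items() if s == species_id]


@dataclass(frozen=True)
class FaceSpace:
    """An eigenface basis over flattened pixel space plus species centroids.

    ``eigenfaces`` has shape (k, D) with orthonormal rows; ``grand_mean`` is
    the mean of the species averages (shape H x W x 3), which projects to the
    zero weight vector. ``centroids`` maps species to its average face's
    weight vector. k <= n_species - 1.
    """

    grand_mean: np.ndarray
    eigenfaces: np.ndarray
    eigenvalues: np.ndarray
    centroids: dict[str, np.ndarray]
    species_index: list[str]

    @property
    def k(self) -> int:
        return self.eigenfaces.shape[0]

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return self.grand_mean.shape

    def centroid_matrix(self) -> np.ndarray:
        """Centroids stacked in species_index order, shape (n_species, k)."""
        return np.stack([self.centroids[s] for s in self.species_index])


@dataclass(frozen=True)
class ClassificationResult:
    image_id: str
    true_species: str | None
    predicted_species: str
    distances: dict[str, float]
    correct: bool | None
    tie: bool = False
    min_distance: float = float("nan")


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out evaluation output.

    ``table`` has one row per classified unit (image or individual average);
    ``folds`` caches the per-individual training model so the occlusion scan
    can reuse the exact face space that classified each image.
    """

    table: pd.DataFrame
    mode: str
    folds: dict[str, tuple[AverageFaceSet, FaceSpace]] = field(repr=False, default_factory=dict)

    @property
    def accuracy(self) -> float:
        return float(self.table["correct"].mean()) if len(self.table) else float("nan")

    @property
    def percent_correct(self) -> float:
        return 100.0 * self.accuracy

    def per_species_accuracy(self) -> pd.Series:
        return self.table.groupby("true_species", sort=False)["correct"].mean()


def compute_averages(m: Manifest) -> AverageFaceSet:
    """Two-stage averaging: per-individual means, then per-species means."""
    if len(m) == 0:
        raise ValueError("cannot average an empty manifest")
    sides = {r.side for r in m.records}
    if len(sides) > 1:
        raise ValueError(f"mixed sides in one averaging call: {sorted(sides)}")
    individual_averages: dict[str, np.ndarray] = {}
    ind_index: dict[str, str] = {}
    for r in m.records:
        ind_index.setdefault(r.individual_id, r.species_id)
    for ind in ind_index:
        imgs = [r.pixels for r in m.records if r.individual_id == ind]
        individual_averages[ind] = np.mean(imgs, axis=0)
    species_averages: dict[str, np.ndarray] = {}
    for sp in m.species_index:
        inds = [i for i, s in ind_index.items() if s == sp]
        species_averages[sp] = np.mean([individual_averages[i] for i in inds], axis=0)
    return AverageFaceSet(
        individual_averages=individual_averages,
        species_averages=species_averages,
        individual_index=ind_index,
        species_index=m.species_index,
        side=sides.pop(),
    )


def build_face_space(
    avg: AverageFaceSet, rank_tol: float = 1e-10
) -> FaceSpace:
    """PCA of the species average faces.

    Components with variance below ``rank_tol`` times the leading variance
    are dropped (at most n_species - 1 are kept). Eigenface sign convention:
    the largest-magnitude element of each eigenface is positive, so the
    serialized basis is reproducible.
    """
    species = avg.species_index
    if len(species) < 2:
        raise ValueError("face space requires at least 2 species")
    X = np.stack([avg.species_averages[s].ravel() for s in species])
    grand_mean_flat = X.mean(axis=0)
    Xc = X - grand_mean_flat
    # Thin SVD of the n_species x D centered matrix: the right singular
    # vectors are the eigenfaces; cost is governed by n_species, not D.
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / max(len(species) - 1, 1)
    if variances[0] <= 0.0:
        raise ValueError("all species averages are identical; face space undefined")
    keep = variances > rank_tol * variances[0]
    keep &= np.arange(len(variances)) < len(species) - 1
    eigenfaces = vt[keep]
    eigenvalues = variances[keep]
    # Deterministic sign: largest-|.| element positive.
    for j in range(eigenfaces.shape[0]):
        idx = np.argmax(np.abs(eigenfaces[j]))
        if eigenfaces[j, idx] < 0:
            eigenfaces[j] = -eigenfaces[j]
    grand_mean = grand_mean_flat.reshape(avg.species_averages[species[0]].shape)
    fs = FaceSpace(
        grand_mean=grand_mean,
        eigenfaces=eigenfaces,
        eigenvalues=eigenvalues,
        centroids={},
        species_index=list(species),
    )
    centroids = {s: project(avg.species_averages[s], fs) for s in species}
    return FaceSpace(
        grand_mean=grand_mean,
        eigenfaces=eigenfaces,
        eigenvalues=eigenvalues,
        centroids=centroids,
        species_index=list(species),
    )


def project(pixels: np.ndarray, fs: FaceSpace) -> np.ndarray:
    """Weights of an image in face space: inner products with each eigenface
    after subtracting the grand mean."""
    if pixels.shape != fs.image_shape:
        raise ValueError(
            f"pixel grid shape {pixels.shape} does not match face space "
            f"{fs.image_shape}"
        )
    return fs.eigenfaces @ (pixels.ravel() - fs.grand_mean.ravel())


def classify(
    w: np.ndarray,
    fs: FaceSpace,
    image_id: str = "",
    true_species: str | None = None,
) -> ClassificationResult:
    """Nearest species centroid by Euclidean distance in face space.

    Ties are broken by species_index order (first wins) and flagged.
    """
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (fs.k,):
        raise ValueError(f"weight vector has shape {w.shape}, expected ({fs.k},)")
    C = fs.centroid_matrix()
    dists = np.sqrt(np.sum((C - w) ** 2, axis=1))
    best = int(np.argmin(dists))  # argmin returns the first minimum
    dmin = dists[best]
    tie = bool(np.sum(np.isclose(dists, dmin, rtol=1e-12, atol=0.0)) > 1)
    predicted = fs.species_index[best]
    return ClassificationResult(
        image_id=image_id,
        true_species=true_species,
        predicted_species=predicted,
        distances={s: float(d) for s, d in zip(fs.species_index, dists)},
        correct=None if true_species is None else predicted == true_species,
        tie=tie,
        min_distance=float(dmin),
    )


def classify_exemplar(
    w: np.ndarray,
    fs: FaceSpace,
    avg: AverageFaceSet,
    n_neighbors: int = 1,
    image_id: str = "",
    true_species: str | None = None,
) -> ClassificationResult:
    """Exemplar-model classifier: nearest individual-average faces in face
    space, majority vote over their species (ties by species_index order).

    This is the alternative to the default average-face model; prior work on
    this classifier found the two give very similar results.
    """
    w = np.asarray(w, dtype=np.float64)
    inds = list(avg.individual_averages)
    E = np.stack([project(avg.individual_averages[i], fs) for i in inds])
    dists = np.sqrt(np.sum((E - w) ** 2, axis=1))
    order = np.argsort(dists, kind="stable")[: max(1, n_neighbors)]
    votes: dict[str, int] = {}
    for idx in order:
        sp = avg.individual_index[inds[idx]]
        votes[sp] = votes.get(sp, 0) + 1
    top = max(votes.values())
    winners = [s for s in fs.species_index if votes.get(s, 0) == top]
    predicted = winners[0]
    per_species = {
        s: float(min(dists[i] for i, ind in enumerate(inds) if avg.individual_index[ind] == s))
        for s in fs.species_index
        if any(avg.individual_index[ind] == s for ind in inds)
    }
    return ClassificationResult(
        image_id=image_id,
        true_species=true_species,
        predicted_species=predicted,
        distances=per_species,
        correct=None if true_species is None else predicted == true_species,
        tie=len(winners) > 1,
        min_distance=float(dists[order[0]]),
    )


def loo_folds(m: Manifest) -> dict[str, tuple[AverageFaceSet, FaceSpace]]:
    """Training model (averages + face space) per held-out individual."""
    folds = {}
    for ind in m.individual_index:
        sp = m.individual_index[ind]
        training = m.without_individual(ind)
        if sp not in training.species_index:
            raise ValueError(
                f"excluding individual {ind!r} empties species {sp!r}; every "
                "species needs >= 2 individuals for leave-one-out evaluation"
            )
        avg = compute_averages(training)
        folds[ind] = (avg, build_face_space(avg))
    return folds


def loo_evaluate(m: Manifest, mode: str = "distinct_images") -> LOOResult:
    """Leave-one-individual-out classification.

    mode='distinct_images' classifies each of the held-out individual's
    images; mode='individual_averages' classifies the individual's average
    face (one row per individual).
    """
    if mode not in ("distinct_images", "individual_averages"):
        raise ValueError(f"unknown mode {mode!r}")
    folds = loo_folds(m)
    rows = []
    for ind, (avg, fs) in folds.items():
        sp = m.individual_index[ind]
        records = m.images_of_individual(ind)
        if mode == "distinct_images":
            units = [(r.image_id, r.pixels) for r in records]
        else:
            units = [(ind, np.mean([r.pixels for r in records], axis=0))]
        for unit_id, pixels in units:
            res = classify(project(pixels, fs), fs, image_id=unit_id, true_species=sp)
            rows.append(
                {
                    "image_id": unit_id,
                    "individual_id": ind,
                    "true_species": sp,
                    "predicted_species": res.predicted_species,
                    "correct": res.correct,
                    "min_distance": res.min_distance,
                    "tie": res.tie,
                }
            )
    return LOOResult(table=pd.DataFrame(rows), mode=mode, folds=folds)
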
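"""Averaging, eigenface decomposition, classification, and leave-one-out."""

import numpy as np
import pytest

from signalscan.facespace import (
    FaceSpace,
    build_face_space,
    classify,
    compute_averages,
    loo_evaluate,
    loo_folds,
    project,
)
from signalscan.images import Manifest

from conftest import constant_image, make_record, separable_manifest


def avg_set_from_arrays(species_arrays):
    """AverageFaceSet with one individual per species, given pixel arrays."""
    records = [
        make_record(f"{sp}_img", f"{sp}_i0", sp, arr)
        for sp, arr in species_arrays.items()
    ]
    return compute_averages(Manifest(tuple(records)))


class TestComputeAverages:
    def test_single_image_individual_average_is_that_image(self, rng):
        px = rng.random((3, 3, 3))
        m = Manifest((make_record("a", "i1", "sp", px),
                      make_record("b", "i2", "sp2", rng.random((3, 3, 3)))))
        avg = compute_averages(m)
        np.testing.assert_array_equal(avg.individual_averages["i1"], px)

    def test_two_image_individual_average(self):
        m = Manifest((
            make_record("a", "i1", "sp", constant_image((1, 1), 0.2)),
            make_record("b", "i1", "sp", constant_image((1, 1), 0.4)),
        ))
        avg = compute_averages(m)
        np.testing.assert_allclose(avg.individual_averages["i1"], 0.3)

    def test_species_average_is_mean_of_individual_averages_not_pooled(self, rng):
        # individuals with 2 and 6 images: two-stage average differs from the
        # pooled 8-image mean; verify against direct two-stage summation
        imgs_a = [rng.random((2, 2, 3)) for _ in range(2)]
        imgs_b = [rng.random((2, 2, 3)) for _ in range(6)]
        records = [make_record(f"a{k}", "iA", "sp", px) for k, px in enumerate(imgs_a)]
        records += [make_record(f"b{k}", "iB", "sp", px) for k, px in enumerate(imgs_b)]
        avg = compute_averages(Manifest(tuple(records)))
        two_stage = (sum(imgs_a) / 2 + sum(imgs_b) / 6) / 2
        np.testing.assert_allclose(avg.species_averages["sp"], two_stage, atol=1e-12)
        pooled = sum(imgs_a + imgs_b) / 8
        assert not np.allclose(avg.species_averages["sp"], pooled)

    def test_mixed_sides_rejected(self, rng):
        with pytest.raises(Exception, match="side"):
            Manifest((
                make_record("a", "i1", "sp", rng.random((2, 2, 3)), side="left"),
                make_record("b", "i2", "sp", rng.random((2, 2, 3)), side="right"),
            ))


class TestBuildFaceSpace:
    def test_two_species_give_one_eigenface_along_their_difference(self, rng):
        v1, v2 = rng.random((2, 2, 3)), rng.random((2, 2, 3))
        fs = build_face_space(avg_set_from_arrays({"A": v1, "B": v2}))
        assert fs.k == 1
        direction = (v1 - v2).ravel()
        cos = np.dot(fs.eigenfaces[0], direction) / np.linalg.norm(direction)
        assert abs(abs(cos) - 1.0) < 1e-10
        # centroids symmetric about the origin of face space
        np.testing.assert_allclose(
            fs.centroids["A"], -fs.centroids["B"], atol=1e-10
        )

    def test_grand_mean_projects_to_zero(self, rng):
        arrays = {f"sp{i}": rng.random((3, 4, 3)) for i in range(4)}
        fs = build_face_space(avg_set_from_arrays(arrays))
        np.testing.assert_allclose(project(fs.grand_mean, fs), 0.0, atol=1e-10)

    def test_eigenfaces_orthonormal(self, rng):
        arrays = {f"sp{i}": rng.random((4, 4, 3)) for i in range(5)}
        fs = build_face_space(avg_set_from_arrays(arrays))
        gram = fs.eigenfaces @ fs.eigenfaces.T
        np.testing.assert_allclose(gram, np.eye(fs.k), atol=1e-8)
        assert np.all(np.diff(fs.eigenvalues) <= 1e-12)
        assert fs.k <= 4

    def test_full_rank_reconstruction_of_centered_averages(self, rng):
        # 5 random species averages of dimension ~50: weights reconstruct
        # each centered average with negligible residual
        arrays = {f"sp{i}": rng.random((4, 4, 3)) for i in range(5)}
        avg = avg_set_from_arrays(arrays)
        fs = build_face_space(avg)
        for sp, arr in arrays.items():
            centered = arr.ravel() - fs.grand_mean.ravel()
            recon = fs.centroids[sp] @ fs.eigenfaces
            assert np.linalg.norm(recon - centered) < 1e-8

    def test_single_species_rejected(self, rng):
        with pytest.raises(ValueError, match="2 species"):
            build_face_space(avg_set_from_arrays({"A": rng.random((2, 2, 3))}))

    def test_identical_averages_rejected(self):
        arrays = {"A": constant_image((2, 2), 0.5), "B": constant_image((2, 2), 0.5)}
        with pytest.raises(ValueError, match="identical"):
            build_face_space(avg_set_from_arrays(arrays))


class TestProject:
    @pytest.fixture
    def fs(self, rng):
        arrays = {f"sp{i}": rng.random((3, 3, 3)) for i in range(4)}
        return build_face_space(avg_set_from_arrays(arrays))

    def test_grand_mean_plus_eigenface_gives_unit_vector(self, fs):
        shifted = fs.grand_mean + fs.eigenfaces[0].reshape(fs.image_shape)
        w = project(shifted, fs)
        expected = np.zeros(fs.k)
        expected[0] = 1.0
        np.testing.assert_allclose(w, expected, atol=1e-10)

    def test_matches_explicit_inner_product_loop(self, fs, rng):
        px = rng.random(fs.image_shape)
        w = project(px, fs)
        centered = px.ravel() - fs.grand_mean.ravel()
        for j in range(fs.k):
            expected = float(np.sum(fs.eigenfaces[j] * centered))
            assert abs(w[j] - expected) < 1e-12

    def test_dimension_mismatch_rejected(self, fs, rng):
        with pytest.raises(ValueError, match="match"):
            project(rng.random((2, 2, 3)), fs)


class TestClassify:
    def test_centroid_classifies_to_its_species_with_zero_distance(self, rng):
        arrays = {f"sp{i}": rng.random((3, 3, 3)) for i in range(3)}
        fs = build_face_space(avg_set_from_arrays(arrays))
        res = classify(fs.centroids["sp1"], fs)
        assert res.predicted_species == "sp1"
        assert res.min_distance < 1e-10

    def test_argmin_matches_exhaustive_enumeration(self, rng):
        # 15 random centroids in a synthetic face space
        k, n = 7, 15
        names = [f"sp{i}" for i in range(n)]
        centroids = {s: rng.normal(size=k) for s in names}
        fs = FaceSpace(
            grand_mean=np.zeros((1, 1, 3)),
            eigenfaces=np.zeros((k, 3)),
            eigenvalues=np.ones(k),
            centroids=centroids,
            species_index=names,
        )
        for _ in range(20):
            w = rng.normal(size=k)
            res = classify(w, fs)
            brute = min(names, key=lambda s: float(np.linalg.norm(centroids[s] - w)))
            assert res.predicted_species == brute
            assert res.min_distance == pytest.approx(
                np.linalg.norm(centroids[brute] - w)
            )

    def test_equidistant_tie_goes_to_earlier_species_and_is_flagged(self):
        names = ["first", "second"]
        fs = FaceSpace(
            grand_mean=np.zeros((1, 1, 3)),
            eigenfaces=np.zeros((1, 3)),
            eigenvalues=np.ones(1),
            centroids={"first": np.array([1.0]), "second": np.array([-1.0])},
            species_index=names,
        )
        res = classify(np.array([0.0]), fs)
        assert res.predicted_species == "first"
        assert res.tie


class TestLeaveOneOut:
    def test_separable_dataset_fully_correct(self):
        m = separable_manifest()
        loo = loo_evaluate(m, mode="distinct_images")
        assert loo.accuracy == 1.0
        loo_avg = loo_evaluate(m, mode="individual_averages")
        assert loo_avg.accuracy == 1.0
        assert len(loo_avg.table) == len(m.individual_index)

    def test_contaminated_individual_is_the_only_misclassification(self):
        # one individual's images replaced by another species' constant value:
        # exactly those images misclassify, so accuracy = (N - n_i) / N
        m = separable_manifest()
        records = [
            make_record(r.image_id, r.individual_id, r.species_id,
                        constant_image((8, 8), 2 / 4))
            if r.individual_id == "sp0_i0"
            else r
            for r in m.records
        ]
        m2 = Manifest(tuple(records))
        loo = loo_evaluate(m2, mode="distinct_images")
        wrong = loo.table[~loo.table["correct"]]
        assert set(wrong["individual_id"]) == {"sp0_i0"}
        n_i = len(wrong)
        assert loo.accuracy == pytest.approx((len(m2) - n_i) / len(m2))

    def test_no_leakage_from_held_out_individual(self, rng):
        # arbitrarily perturbing a held-out individual's pixels must not
        # change the training model used to classify that individual
        m = separable_manifest(shape=(4, 4))
        target = "sp1_i2"
        noise = rng.random((4, 4, 3)) * 0.25
        records = [
            make_record(r.image_id, r.individual_id, r.species_id,
                        np.clip(r.pixels + noise, 0, 1))
            if r.individual_id == target
            else r
            for r in m.records
        ]
        m2 = Manifest(tuple(records))
        fold_a = loo_folds(m)[target]
        fold_b = loo_folds(m2)[target]
        np.testing.assert_array_equal(fold_a[1].eigenfaces, fold_b[1].eigenfaces)
        np.testing.assert_array_equal(fold_a[1].grand_mean, fold_b[1].grand_mean)
        for sp in fold_a[1].species_index:
            np.testing.assert_array_equal(
                fold_a[1].centroids[sp], fold_b[1].centroids[sp]
            )

    def test_every_fold_satisfies_face_space_invariants(self, default_dataset):
        manifest, _ = default_dataset
        for ind, (avg, fs) in loo_folds(manifest).items():
            gram = fs.eigenfaces @ fs.eigenfaces.T
            np.testing.assert_allclose(gram, np.eye(fs.k), atol=1e-8)
            np.testing.assert_allclose(project(fs.grand_mean, fs), 0.0, atol=1e-8)
            centroid_mean = np.mean(
                [fs.centroids[s] for s in fs.species_index], axis=0
            )
            np.testing.assert_allclose(centroid_mean, 0.0, atol=1e-8)

    def test_classification_invariant_to_basis_rotation(self, rng):
        # distances are preserved under any orthogonal rotation of the basis
        arrays = {f"sp{i}": rng.random((4, 4, 3)) for i in range(5)}
        avg = avg_set_from_arrays(arrays)
        fs = build_face_space(avg)
        q, _ = np.linalg.qr(rng.normal(size=(fs.k, fs.k)))
        rotated = FaceSpace(
            grand_mean=fs.grand_mean,
            eigenfaces=q @ fs.eigenfaces,
            eigenvalues=fs.eigenvalues,
            centroids={},
            species_index=fs.species_index,
        )
        rotated = FaceSpace(
            grand_mean=rotated.grand_mean,
            eigenfaces=rotated.eigenfaces,
            eigenvalues=rotated.eigenvalues,
            centroids={
                s: project(arrays[s], rotated) for s in fs.species_index
            },
            species_index=fs.species_index,
        )
        for _ in range(10):
            px = np.clip(rng.random((4, 4, 3)), 0, 1)
            a = classify(project(px, fs), fs)
            b = classify(project(px, rotated), rotated)
            assert a.predicted_species == b.predicted_species
            assert a.min_distance == pytest.approx(b.min_distance)

    def test_emptying_a_species_is_rejected(self):
        m = separable_manifest(n_individuals=1)
        with pytest.raises(ValueError, match="empties species"):
            loo_evaluate(m)
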
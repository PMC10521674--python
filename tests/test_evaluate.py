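"""Dice, volumes, Evans' index, slice profiles, fusion, SVM, PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from nphkit.errors import InvariantError
from nphkit.evaluate import (
    EvansMeasurement,
    class_volumes,
    classify_evans,
    cross_validated_svm,
    dice,
    evans_index,
    fuse_features,
    pca_2d,
    slice_profiles,
    volumetric_features,
)
from nphkit.netmetrics import assemble_features
from nphkit.synthetic import PhantomParams, inner_skull_mask, make_phantom
from nphkit.types import ConnectivityMatrix, LabelVolume, default_affine


class TestDice:
    def test_worked_values(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, :2] = True   # |X| = 2
        b[0, 1:3] = True  # |Y| = 2, overlap 1
        assert dice(a, b) == pytest.approx(0.5)
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0

    @settings(derandomize=True, max_examples=30)
    @given(hnp.arrays(bool, (5, 5, 5)), hnp.arrays(bool, (5, 5, 5)))
    def test_symmetry_and_bounds(self, x, y):
        d = dice(x, y)
        assert d == dice(y, x)
        assert 0.0 <= d <= 1.0
        assert dice(x, x) == 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(InvariantError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestClassVolumes:
    def test_thousand_unit_voxels_are_one_ml(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[:] = 1
        lab = LabelVolume(labels=labels, legend={1: "ventricle"}, spacing=(1, 1, 1),
                          affine=default_affine((10, 10, 10), (1, 1, 1)))
        assert class_volumes(lab)["ventricle"] == pytest.approx(1.0)

    def test_125_voxels_at_2mm_are_one_ml(self):
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        labels[:] = 1
        lab = LabelVolume(labels=labels, legend={1: "ventricle"}, spacing=(2, 2, 2),
                          affine=default_affine((5, 5, 5), (2, 2, 2)))
        assert class_volumes(lab)["ventricle"] == pytest.approx(1.0)

    def test_phantom_totals_match_brute_force_tally(self, phantom_normal):
        _, lab = phantom_normal
        out = class_volumes(lab)
        vox_ml = np.prod(lab.spacing) / 1000.0
        for label, name in lab.legend.items():
            assert out[name] == pytest.approx((lab.labels == label).sum() * vox_ml)
        brute_total = np.isin(lab.labels, [1, 2, 3, 4, 5]).sum() * vox_ml
        assert out["total"] == pytest.approx(brute_total)

    def test_volumetric_features_are_consistent(self, phantom_normal):
        _, lab = phantom_normal
        vf = volumetric_features(lab)
        cv = class_volumes(lab)
        assert vf["ventricle_ml"] == cv["ventricle"]
        assert vf["total_ml"] == cv["total"]


class TestEvans:
    def test_constructed_widths_recovered_within_one_voxel(self, phantom_normal):
        _, lab = phantom_normal
        e = evans_index(lab.labels == 1, inner_skull_mask(lab), lab.spacing)
        assert abs(e.A - 30.0) <= lab.spacing[0]
        assert abs(e.B - 100.0) <= 2 * lab.spacing[0]
        assert e.index == pytest.approx(0.30, abs=2 * lab.spacing[0] / e.B)

    def test_ventricle_equal_to_skull_gives_index_one(self, phantom_normal):
        _, lab = phantom_normal
        skull = inner_skull_mask(lab)
        e = evans_index(skull, skull, lab.spacing)
        assert e.index == 1.0
        assert classify_evans(e) == "NPH"

    def test_index_monotone_in_dilation(self):
        indices = []
        for d in (1.0, 1.2, 1.4, 1.6, 1.8):
            _, lab = make_phantom(PhantomParams(dilation=d, seed=0))
            e = evans_index(lab.labels == 1, inner_skull_mask(lab), lab.spacing)
            indices.append(e.index)
        assert all(a < b for a, b in zip(indices, indices[1:]))

    def test_empty_mask_rejected(self, phantom_normal):
        _, lab = phantom_normal
        with pytest.raises(InvariantError):
            evans_index(np.zeros(lab.shape, bool), inner_skull_mask(lab), lab.spacing)

    def test_measurement_invariants(self):
        with pytest.raises(InvariantError):
            EvansMeasurement(A=50.0, B=40.0)
        with pytest.raises(InvariantError):
            EvansMeasurement(A=0.0, B=40.0)

    @pytest.mark.parametrize("index,expected", [
        (0.30, "NPH"), (0.299, "non-NPH"), (1.0, "NPH"), (0.1, "non-NPH"),
    ])
    def test_threshold_rule(self, index, expected):
        e = EvansMeasurement(A=index * 100.0, B=100.0)
        assert classify_evans(e) == expected


class TestSliceProfiles:
    def test_single_subject_has_zero_sd(self, phantom_normal):
        _, lab = phantom_normal
        mean, sd = slice_profiles([lab], class_label=1)
        assert np.all(sd == 0)

    def test_profile_sums_to_mean_total_volume(self, phantom_normal, phantom_nph):
        labs = [phantom_normal[1], phantom_nph[1]]
        mean, _ = slice_profiles(labs, class_label=1)
        totals = [class_volumes(lab)["ventricle"] for lab in labs]
        assert mean.sum() == pytest.approx(np.mean(totals))

    def test_matches_per_slice_brute_force(self):
        labs = [make_phantom(PhantomParams(dilation=d, seed=1))[1]
                for d in (1.0, 1.3, 1.7)]
        mean, sd = slice_profiles(labs, class_label=2)
        vox_ml = np.prod(labs[0].spacing) / 1000.0
        for z in range(labs[0].shape[2]):
            per = [float((lab.labels[:, :, z] == 2).sum()) * vox_ml for lab in labs]
            assert mean[z] == pytest.approx(np.mean(per))
            assert sd[z] == pytest.approx(np.std(per))

    def test_empty_group_rejected(self):
        with pytest.raises(InvariantError):
            slice_profiles([], class_label=1)


@pytest.fixture(scope="module")
def net_features():
    rng = np.random.default_rng(4)
    W = rng.integers(0, 4, (20, 20)).astype(float)
    W = np.triu(W, 1)
    return assemble_features(ConnectivityMatrix(weights=W + W.T), seed=0)


class TestFuseFeatures:
    VOL = {"ventricle_ml": 30.0, "subarachnoid_ml": 90.0,
           "gray_white_ml": 900.0, "total_ml": 1100.0}

    def test_fused_vector_has_30_entries_in_fixed_order(self, net_features):
        v = fuse_features(self.VOL, net_features, mode="fused")
        assert v.shape == (30,)
        assert np.array_equal(v[:4], [30.0, 90.0, 900.0, 1100.0])
        assert np.array_equal(v[4:], net_features.to_array())

    def test_model1_and_model2_modes(self, net_features):
        assert fuse_features(self.VOL, None, mode="volumetric").shape == (4,)
        assert fuse_features(None, net_features, mode="network").shape == (26,)

    def test_missing_component_rejected(self, net_features):
        with pytest.raises(InvariantError):
            fuse_features(None, net_features, mode="fused")


def _separable_cohort(n_per_class=10, n_features=30, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b[:, :3] += 6.0  # a few strongly informative dimensions
    X = np.vstack([a, b])
    y = np.array(["normal"] * n_per_class + ["NPH"] * n_per_class)
    return X, y


class TestCrossValidatedSVM:
    def test_separable_features_score_high(self):
        X, y = _separable_cohort()
        rep = cross_validated_svm(X, y, folds=5, iterations=10, seed=0, positive="NPH")
        assert rep.precision_test[0] >= 95
        assert rep.recall_test[0] >= 95

    def test_shuffled_labels_score_near_prevalence(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 30))
        y = np.array(["NPH"] * 10 + ["normal"] * 10)
        rng.shuffle(y)
        rep = cross_validated_svm(X, y, folds=5, iterations=10, seed=1, positive="NPH")
        assert abs(rep.precision_test[0] - 50.0) <= 15.0

    def test_same_seed_reproduces_report(self):
        X, y = _separable_cohort(seed=2)
        a = cross_validated_svm(X, y, iterations=5, seed=7, positive="NPH")
        b = cross_validated_svm(X, y, iterations=5, seed=7, positive="NPH")
        assert a.as_dict() == b.as_dict()

    def test_too_few_subjects_per_class_rejected(self):
        X = np.zeros((6, 4))
        y = np.array(["NPH"] * 3 + ["normal"] * 3)
        with pytest.raises(InvariantError):
            cross_validated_svm(X, y, folds=5, iterations=1, positive="NPH")


class TestPCA:
    def test_two_components_with_ordered_variance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 26)) @ np.diag(np.linspace(3, 0.1, 26))
        Z = pca_2d(X)
        assert Z.shape == (15, 2)
        assert Z[:, 0].var() >= Z[:, 1].var()

    def test_full_rank_reconstruction_identity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        Xs = StandardScaler().fit_transform(X)
        pca = PCA(n_components=6).fit(Xs)
        back = pca.inverse_transform(pca.transform(Xs))
        assert np.abs(back - Xs).max() < 1e-8

    def test_too_few_subjects_rejected(self):
        with pytest.raises(InvariantError):
            pca_2d(np.zeros((2, 26)))
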
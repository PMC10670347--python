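"""Resampling, normalization, Pearson FC and manifest round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hilofuse.cohort_sim import SimParams, generate_cohort, write_cohort
from hilofuse.volume_io import (
    check_fc,
    load_manifest,
    normalize_volume,
    pearson_fc,
    resample_nearest,
)


class TestResampleNearest:
    def test_matches_bruteforce_floor_contract(self, rng):
        src = rng.standard_normal((5, 7, 6))
        out = resample_nearest(src, (8, 3, 4))
        expected = np.empty((8, 3, 4))
        for i in range(8):
            for j in range(3):
                for k in range(4):
                    expected[i, j, k] = src[i * 5 // 8, j * 7 // 3, k * 6 // 4]
        np.testing.assert_array_equal(out, expected)

    def test_upsampling_replicates_blocks(self):
        src = np.arange(1, 9, dtype=float).reshape(2, 2, 2)
        out = resample_nearest(src, (4, 4, 4))
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert out[i, j, k] == src[i // 2, j // 2, k // 2]

    def test_constant_volume_stays_constant(self):
        out = resample_nearest(np.full((3, 4, 5), 3.5), (7, 2, 9))
        assert out.shape == (7, 2, 9)
        assert np.all(out == 3.5)

    def test_paper_shapes(self, rng):
        fam = rng.standard_normal((91, 109, 91))
        assert resample_nearest(fam, (112, 112, 112)).shape == (112, 112, 112)
        smri = rng.standard_normal((113, 137, 113))
        assert resample_nearest(smri, (112, 112, 112)).shape == (112, 112, 112)

    def test_idempotent_at_same_shape(self, rng):
        v = rng.standard_normal((6, 5, 4))
        np.testing.assert_array_equal(resample_nearest(v, v.shape), v)

    def test_value_set_preserved(self, rng):
        v = rng.integers(0, 5, size=(4, 4, 4)).astype(float)
        out = resample_nearest(v, (9, 2, 6))
        assert set(np.unique(out)) <= set(np.unique(v))

    def test_rejects_bad_target(self, rng):
        with pytest.raises(ValueError):
            resample_nearest(rng.standard_normal((3, 3, 3)), (0, 4, 4))


class TestNormalizeVolume:
    def test_constant_volume_maps_to_zero(self):
        out = normalize_volume(np.full((3, 3, 3), 7.0))
        assert np.all(out == 0.0)

    def test_two_point_case(self):
        out = normalize_volume(np.array([[[0.0, 10.0]]]))
        assert out[0, 0, 0] == 0.0
        assert np.isclose(out[0, 0, 1], 10.0 / (10.0 + 1e-9), rtol=0, atol=1e-15)

    def test_range_contract(self, rng):
        out = normalize_volume(rng.standard_normal((5, 5, 5)) * 13 - 4)
        assert out.min() == 0.0
        assert out.max() < 1.0

    @given(scale=st.floats(0.1, 10.0), shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        v = np.random.default_rng(7).standard_normal((4, 4, 4))
        a = normalize_volume(v)
        b = normalize_volume(scale * v + shift)
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestPearsonFC:
    def test_matches_double_loop_oracle(self, rng):
        ts = rng.standard_normal((5, 10))
        fc = pearson_fc(ts)
        for i in range(5):
            for j in range(5):
                xi, xj = ts[i] - ts[i].mean(), ts[j] - ts[j].mean()
                r = (xi * xj).sum() / np.sqrt((xi ** 2).sum() * (xj ** 2).sum())
                assert abs(fc[i, j] - r) < 1e-12

    def test_identical_and_negated_series(self):
        base = np.array([1.0, 3.0, 2.0, 5.0])
        fc = pearson_fc(np.stack([base, base, -base]))
        assert np.isclose(fc[0, 1], 1.0)
        assert np.isclose(fc[0, 2], -1.0)

    def test_three_roi_hand_case(self):
        fc = pearson_fc(np.array([[1.0, 2, 3], [1, 2, 4], [3, 1, 2]]))
        check_fc(fc)
        def r(a, b):
            a, b = np.asarray(a, float), np.asarray(b, float)
            a, b = a - a.mean(), b - b.mean()
            return (a * b).sum() / np.sqrt((a ** 2).sum() * (b ** 2).sum())
        assert abs(fc[0, 1] - r([1, 2, 3], [1, 2, 4])) < 1e-12
        assert abs(fc[0, 2] - r([1, 2, 3], [3, 1, 2])) < 1e-12
        assert abs(fc[1, 2] - r([1, 2, 4], [3, 1, 2])) < 1e-12

    def test_constant_roi_rejected_naming_index(self, rng):
        ts = rng.standard_normal((4, 8))
        ts[2] = 5.0
        with pytest.raises(ValueError, match="ROI index 2"):
            pearson_fc(ts)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            pearson_fc(np.ones((3, 2)))


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    params = SimParams.tiny(n_mdd=3, n_hc=2, seed=3)
    cohort = generate_cohort(params)
    out = tmp_path_factory.mktemp("cohort")
    manifest = write_cohort(cohort, out)
    return params, cohort, manifest


class TestManifestIO:
    def test_round_trip(self, written):
        params, cohort, manifest = written
        records = load_manifest(manifest, normalize=False)
        assert [r.subject_id for r in records] == [r.subject_id for r in cohort.records]
        assert [r.label for r in records] == [r.label for r in cohort.records]
        for loaded, orig in zip(records, cohort.records):
            assert loaded.smri.shape == params.volume_shape
            np.testing.assert_allclose(loaded.smri, orig.smri, rtol=1e-6)
            np.testing.assert_allclose(loaded.fc, orig.fc, atol=1e-12)

    def test_missing_modality_excluded_with_log(self, written, caplog):
        _, cohort, manifest = written
        victim = manifest.parent / f"{cohort.records[1].subject_id}_fam.nii.gz"
        victim.rename(victim.with_suffix(".bak"))
        try:
            with caplog.at_level("WARNING"):
                records = load_manifest(manifest, normalize=False)
            assert len(records) == len(cohort.records) - 1
            assert any("missing modality" in m for m in caplog.messages)
        finally:
            victim.with_suffix(".bak").rename(victim)

    def test_empty_manifest_warns(self, tmp_path, caplog):
        p = tmp_path / "manifest.csv"
        p.write_text("subject_id,smri_path,fam_path,fc_path,label\n")
        with caplog.at_level("WARNING"):
            assert load_manifest(p) == []
        assert any("empty" in m for m in caplog.messages)

    def test_resample_and_normalize_on_load(self, written):
        _, _, manifest = written
        records = load_manifest(manifest, target_shape=(8, 8, 8), normalize=True)
        for r in records:
            assert r.smri.shape == (8, 8, 8)
            assert r.smri.min() == 0.0 and r.smri.max() < 1.0
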
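"""The 1025-descriptor contract, transforms, and descriptor invariances."""

import numpy as np
import pytest

from ramancharm.cube import CellMask
from ramancharm.features import (
    CHANNEL_ORDER,
    ConsistencyError,
    build_feature_table,
    build_manifest,
    compute_transforms,
    default_manifest,
    extract_cell_features,
    extract_features,
)
from ramancharm.features.families import zernike_magnitudes
from ramancharm.peaks import CompoundImage, PeakDefinition


@pytest.fixture(scope="module")
def cell_image(request) -> np.ndarray:
    rng = np.random.default_rng(42)
    yy, xx = np.mgrid[0:40, 0:40]
    blob = (np.hypot(yy - 19.5, xx - 19.5) <= 15).astype(float)
    img = blob * (0.5 + 0.2 * rng.random((40, 40)))
    for cy, cx in [(12, 14), (25, 22), (18, 28)]:
        img += 0.8 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 6.0)
    return img * blob


def _channels(img):
    return [
        CompoundImage(img, PeakDefinition(name, center))
        for name, center in zip(CHANNEL_ORDER, (750.0, 1687.0, 2850.0))
    ]


class TestManifest:
    def test_exactly_1025_unique_entries(self):
        m = build_manifest()
        assert len(m) == 1025
        assert len(set(m.names)) == 1025

    def test_order_stable_across_builds(self):
        assert build_manifest().names == build_manifest().names

    def test_json_export(self, tmp_path):
        import json

        p = tmp_path / "manifest.json"
        default_manifest().to_json(p)
        payload = json.loads(p.read_text())
        assert len(payload["entries"]) == 1025


class TestTransforms:
    def test_constant_image_fourier_concentrated_at_dc(self):
        t = compute_transforms(np.full((24, 24), 3.0))
        f = np.expm1(t["fourier"])  # undo log1p -> raw magnitudes
        dc = f[12, 12]
        f[12, 12] = 0.0
        assert f.max() <= 1e-9 * dc

    def test_deterministic_bit_for_bit(self, cell_image):
        a = compute_transforms(cell_image)
        b = compute_transforms(cell_image.copy())
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_sinusoid_fourier_peak_at_matching_frequency(self):
        xx = np.arange(64)
        img = np.tile(np.sin(2 * np.pi * xx / 8.0), (64, 1))
        t = compute_transforms(img)
        f = t["fourier"].copy()
        f[32, 32] = 0.0  # ignore DC
        peak = np.unravel_index(np.argmax(f), f.shape)
        # period 8 px -> frequency bin +-64/8 = 8 from center, along x
        assert peak in {(32, 32 + 8), (32, 32 - 8)}

    def test_small_images_padded_to_16(self):
        t = compute_transforms(np.ones((5, 7)))
        assert t["raw"].shape == (16, 16)

    def test_nonfinite_rejected(self):
        img = np.ones((20, 20))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_transforms(img)


class TestExtraction:
    def test_vector_length_is_1025(self, cell_image):
        fv = extract_features(cell_image)
        assert fv.values.size == 1025
        assert np.all(np.isfinite(fv.values))

    def test_deterministic(self, cell_image):
        a = extract_features(cell_image)
        b = extract_features(cell_image.copy())
        np.testing.assert_array_equal(a.values, b.values)

    def test_constant_image_degenerate_features(self):
        fv = extract_features(np.full((24, 24), 5.0))
        names = fv.manifest.names
        by_name = dict(zip(names, fv.values))
        # no texture contrast anywhere on the raw image
        assert by_name["raw.haralick_contrast_mean"] == 0.0
        assert by_name["raw.tamura_00"] == 0.0  # Tamura contrast
        assert by_name["raw.edge_statistics_00"] == 0.0  # edge area

    def test_translation_invariance_via_mask_crop(self, cell_image):
        field_a = np.zeros((64, 64))
        field_b = np.zeros((64, 64))
        mask_a = np.zeros((64, 64), dtype=bool)
        mask_b = np.zeros((64, 64), dtype=bool)
        field_a[2:42, 3:43] = cell_image
        mask_a[2:42, 3:43] = cell_image > 0
        field_b[20:60, 15:55] = cell_image
        mask_b[20:60, 15:55] = cell_image > 0
        fa = extract_features(field_a, CellMask(mask_a))
        fb = extract_features(field_b, CellMask(mask_b))
        np.testing.assert_array_equal(fa.values, fb.values)

    def test_intensity_rescaling_leaves_quantized_textures(self, cell_image):
        # quantization is min-max, so positive rescaling cancels wherever the
        # source transform is homogeneous (raw, wavelet, Chebyshev); the
        # log-magnitude Fourier transform is deliberately not
        a = extract_features(cell_image)
        b = extract_features(cell_image * 3.7)
        homogeneous = {"raw", "wavelet", "chebyshev"}
        pairs = np.array(
            [
                (va, vb)
                for entry, va, vb in zip(a.manifest.entries, a.values, b.values)
                if entry.family in ("haralick", "multiscale_histograms")
                and entry.transform in homogeneous
            ]
        )
        assert len(pairs) > 100
        np.testing.assert_allclose(pairs[:, 0], pairs[:, 1], rtol=1e-8)

    def test_zernike_90deg_rotation_invariance(self, cell_image):
        a = zernike_magnitudes(cell_image)
        b = zernike_magnitudes(np.rot90(cell_image))
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-12)


class TestCellFeatures:
    def test_three_channels_give_3075(self, cell_image, blob_mask_40):
        fv = extract_cell_features(_channels(cell_image), blob_mask_40)
        assert fv.values.size == 3075

    def test_identical_channels_give_identical_blocks(self, cell_image, blob_mask_40):
        fv = extract_cell_features(_channels(cell_image), blob_mask_40)
        v = fv.values.reshape(3, 1025)
        np.testing.assert_array_equal(v[0], v[1])
        np.testing.assert_array_equal(v[0], v[2])

    def test_channel_order_enforced(self, cell_image, blob_mask_40):
        chans = _channels(cell_image)
        with pytest.raises(ConsistencyError, match="order"):
            extract_cell_features(chans[::-1], blob_mask_40)


@pytest.fixture()
def blob_mask_40(cell_image) -> CellMask:
    return CellMask(cell_image > 0, "cell0")


class TestFeatureTable:
    def _dataset(self, n, rng, label_fn=None):
        out = []
        for i in range(n):
            yy, xx = np.mgrid[0:32, 0:32]
            img = (np.hypot(yy - 15.5, xx - 15.5) <= 12) * rng.random((32, 32))
            mask = CellMask(img > 0, f"m{i}")
            label = label_fn(i) if label_fn else ("a" if i % 2 else "b")
            out.append((_channels(img), mask, label))
        return out

    def test_full_width_3075_and_single_channel_1025(self, rng):
        ds = self._dataset(4, rng)
        full = build_feature_table(ds)
        assert full.data.shape == (4, 3075)
        single = build_feature_table(ds, channels_subset=("cytochrome",))
        assert single.data.shape == (4, 1025)
        assert single.data.columns[0].startswith("cytochrome.")

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_feature_table([])

    def test_duplicate_cell_ids_rejected(self, rng):
        ds = self._dataset(3, rng)
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(ds, cell_ids=["x", "x", "y"])

    def test_csv_roundtrip(self, rng, tmp_path):
        table = build_feature_table(
            self._dataset(3, rng), channels_subset=("lipid",)
        )
        p = tmp_path / "t.csv"
        table.to_csv(p)
        from ramancharm.features import FeatureTable

        back = FeatureTable.from_csv(p)
        np.testing.assert_allclose(back.data.values, table.data.values)
        assert list(back.labels) == list(table.labels)
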
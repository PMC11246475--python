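"""Raster application: bitmask products, nodata propagation, GeoTIFF I/O."""

import itertools

import numpy as np
import pytest

from conformap import (
    LacCalibration,
    Raster,
    RegressionCalibration,
    class_inclusion_mask,
    classify_raster,
    decode_bitmask,
    encode_bitmask,
    predict_set,
    read_geotiff,
    regress_raster,
    write_geotiff,
)
from conformap.raster import LENGTH_NODATA, SETMASK_NODATA


def lac(t, classes=(0, 1, 2)):
    return LacCalibration(thresholds={0.1: t}, classes=classes, n_cal=100)


@pytest.fixture
def small_prob_raster():
    data = np.zeros((3, 2, 2), dtype=np.float32)
    data[:, 0, 0] = (0.7, 0.2, 0.1)
    data[:, 0, 1] = (0.1, 0.1, 0.1)
    data[:, 1, 0] = (0.9, 0.05, 0.05)
    data[:, 1, 1] = (0.3, 0.3, 0.4)
    return Raster(data=data, nodata=-1.0)


class TestBitmask:
    def test_round_trip_exhaustive_small_roster(self):
        C = 4
        for bits in itertools.product([0, 1], repeat=C):
            member = np.array(bits, dtype=bool)
            assert np.array_equal(decode_bitmask(encode_bitmask(member), C), member)

    def test_round_trip_fuzzed_up_to_32_classes(self, rng):
        for C in (1, 7, 16, 31, 32):
            member = rng.random((50, C)) > 0.5
            codes = encode_bitmask(member)
            assert np.array_equal(decode_bitmask(codes, C), member)

    def test_full_32_class_set_is_all_ones(self):
        assert encode_bitmask(np.ones(32, dtype=bool)) == 0xFFFFFFFF

    def test_more_than_32_classes_rejected(self):
        with pytest.raises(ValueError):
            encode_bitmask(np.ones(33, dtype=bool))


class TestClassifyRaster:
    def test_known_pixels(self, small_prob_raster):
        sm = classify_raster(small_prob_raster, lac(0.15), 0.1)
        assert sm.bitmask.data[0, 0, 0] == 0b011  # classes 0 and 1
        assert sm.length.data[0, 0, 0] == 2
        assert sm.length.data[0, 0, 1] == 0  # all below threshold: empty set
        assert sm.length.data[0, 1, 0] == 1

    def test_nodata_in_any_band_propagates(self, small_prob_raster):
        small_prob_raster.data[1, 1, 1] = -1.0  # nodata in band 1 only
        sm = classify_raster(small_prob_raster, lac(0.15), 0.1)
        assert sm.bitmask.data[0, 1, 1] == SETMASK_NODATA
        assert sm.length.data[0, 1, 1] == LENGTH_NODATA

    def test_popcount_equals_length_band(self, rng):
        probs = rng.dirichlet(np.ones(5), size=(32, 17)).transpose(2, 0, 1)
        raster = Raster(probs.astype(np.float32))
        sm = classify_raster(raster, lac(0.2, classes=tuple(range(5))), 0.1)
        decoded = decode_bitmask(sm.bitmask.data[0], 5).sum(axis=-1)
        assert np.array_equal(decoded, sm.length.data[0])

    def test_matches_tabular_path_bit_exact(self, rng):
        probs = rng.dirichlet(np.ones(4), size=(40, 23)).astype(np.float32)
        raster = Raster(probs.transpose(2, 0, 1))
        cal = lac(0.22, classes=tuple(range(4)))
        sm = classify_raster(raster, cal, 0.1, tile=16)
        tabular = predict_set(probs.reshape(-1, 4).astype(float), cal, 0.1)
        assert np.array_equal(
            encode_bitmask(tabular.membership).reshape(40, 23), sm.bitmask.data[0]
        )

    def test_tile_size_does_not_change_result(self, rng):
        probs = rng.dirichlet(np.ones(6), size=(100, 90)).transpose(2, 0, 1)
        raster = Raster(probs.astype(np.float32), nodata=-1.0)
        raster.data[:, 10:12, :] = -1.0
        results = [
            classify_raster(raster, lac(0.1, classes=tuple(range(6))), 0.1, tile=t)
            for t in (16, 64, 256)
        ]
        for other in results[1:]:
            assert np.array_equal(results[0].bitmask.data, other.bitmask.data)
            assert np.array_equal(results[0].length.data, other.length.data)

    def test_band_roster_mismatch_rejected(self, small_prob_raster):
        with pytest.raises(ValueError, match="roster"):
            classify_raster(small_prob_raster, lac(0.1, classes=(0, 1)), 0.1)

    def test_oversized_roster_rejected(self, rng):
        raster = Raster(rng.random((33, 2, 2)).astype(np.float32))
        cal = LacCalibration(
            thresholds={0.1: 0.5}, classes=tuple(range(33)), n_cal=10
        )
        with pytest.raises(ValueError, match="32"):
            classify_raster(raster, cal, 0.1)


class TestClassInclusionMask:
    def test_bit_query_with_length_filters(self, small_prob_raster):
        sm = classify_raster(small_prob_raster, lac(0.15), 0.1)
        any_mask = class_inclusion_mask(sm, 0)
        assert any_mask.data[0, 0, 0] == 1  # in {0,1} set
        assert any_mask.data[0, 0, 1] == 0  # empty set -> never included
        single = class_inclusion_mask(sm, 0, length="singleton")
        assert single.data[0, 0, 0] == 0  # set length 2 fails the filter
        assert single.data[0, 1, 0] == 1
        multi = class_inclusion_mask(sm, 0, length="multi")
        assert multi.data[0, 0, 0] == 1

    def test_nodata_preserved_and_unknown_class_rejected(self, small_prob_raster):
        small_prob_raster.data[:, 1, 1] = -1.0
        sm = classify_raster(small_prob_raster, lac(0.15), 0.1)
        mask = class_inclusion_mask(sm, 2)
        assert mask.data[0, 1, 1] == LENGTH_NODATA
        with pytest.raises(ValueError, match="not in roster"):
            class_inclusion_mask(sm, "pine")


class TestRegressRaster:
    def test_point_band_interval(self):
        raster = Raster(np.full((1, 2, 2), 10.0, dtype=np.float32))
        cal = RegressionCalibration("absolute_residual", qhat=2.0, alpha=0.1, n_cal=9)
        out = regress_raster(raster, cal)
        assert out.data[0, 0, 0] == 8.0
        assert out.data[1, 0, 0] == 12.0
        assert out.data[2, 0, 0] == 4.0

    def test_nodata_pixel_becomes_nan_in_all_bands(self):
        data = np.full((1, 2, 2), 10.0, dtype=np.float32)
        data[0, 0, 1] = -9999.0
        raster = Raster(data, nodata=-9999.0)
        cal = RegressionCalibration("absolute_residual", qhat=1.0, alpha=0.1, n_cal=9)
        out = regress_raster(raster, cal)
        assert np.all(np.isnan(out.data[:, 0, 1]))
        assert np.isfinite(out.data[:, 0, 0]).all()

    def test_width_band_is_upper_minus_lower_everywhere(self, rng):
        data = np.stack([rng.uniform(2, 4, (20, 20)), rng.uniform(5, 8, (20, 20))])
        raster = Raster(data.astype(np.float32))
        cal = RegressionCalibration("cqr", qhat=0.3, alpha=0.1, n_cal=99)
        out = regress_raster(raster, cal, tile=7)
        assert np.allclose(out.data[2], out.data[1] - out.data[0])

    def test_band_method_mismatch_rejected(self):
        raster = Raster(np.zeros((2, 2, 2), dtype=np.float32))
        cal = RegressionCalibration("absolute_residual", qhat=1.0, alpha=0.1, n_cal=9)
        with pytest.raises(ValueError, match="expects 1 band"):
            regress_raster(raster, cal)


class TestGeoTiffIO:
    def test_round_trip_preserves_data_nodata_and_geo_tags(self, tmp_path, rng):
        data = rng.random((3, 40, 50)).astype(np.float32)
        geo = (
            (33550, 12, 3, (10.0, 10.0, 0.0), True),  # ModelPixelScale
            (33922, 12, 6, (0.0, 0.0, 0.0, 500000.0, 6200000.0, 0.0), True),
        )
        raster = Raster(data, nodata=-1.0, geo=geo)
        path = tmp_path / "probs.tif"
        write_geotiff(path, raster, tile=16)
        back = read_geotiff(path)
        assert np.array_equal(back.data, data)
        assert back.nodata == -1.0
        codes = {tag[0]: tag[3] for tag in back.geo}
        assert codes[33550] == (10.0, 10.0, 0.0)
        assert codes[33922][3:5] == (500000.0, 6200000.0)

    def test_geo_tags_copied_to_derived_products(self, tmp_path, rng):
        probs = rng.dirichlet(np.ones(3), size=(20, 20)).transpose(2, 0, 1)
        geo = ((33550, 12, 3, (30.0, 30.0, 0.0), True),)
        raster = Raster(probs.astype(np.float32), geo=geo)
        sm = classify_raster(raster, lac(0.2), 0.1)
        assert sm.length.geo == geo
        path = tmp_path / "length.tif"
        write_geotiff(path, sm.length)
        assert {t[0]: t[3] for t in read_geotiff(path).geo}[33550] == (30.0, 30.0, 0.0)

    def test_single_band_round_trip(self, tmp_path):
        raster = Raster(np.arange(12, dtype=np.uint8).reshape(1, 3, 4))
        path = tmp_path / "single.tif"
        write_geotiff(path, raster)
        assert np.array_equal(read_geotiff(path).data, raster.data)
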
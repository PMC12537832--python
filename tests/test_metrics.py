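"""ROI metrics: means, volume normalization, lesion filtering, log TLV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgmqsm.metrics import (
    extract_region_metrics,
    lesion_filter_tlv,
    log_tlv,
    normalize_volume,
    roi_mean,
)


class TestRoiMean:
    def test_constant_region(self):
        chi = np.zeros((8, 8, 8))
        labels = np.zeros((8, 8, 8), int)
        labels[2:5, 2:5, 2:5] = 3
        chi[labels == 3] = 0.05
        assert roi_mean(chi, labels, 3) == pytest.approx(0.05)

    def test_two_voxel_average(self):
        chi = np.zeros((4, 4, 4))
        labels = np.zeros((4, 4, 4), int)
        labels[0, 0, 0] = labels[0, 0, 1] = 1
        chi[0, 0, 1] = 0.1
        assert roi_mean(chi, labels, 1) == pytest.approx(0.05)

    def test_absent_label_named_in_error(self):
        with pytest.raises(ValueError, match="7"):
            roi_mean(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), int), 7)

    def test_invariant_to_voxel_order(self):
        rng = np.random.default_rng(0)
        chi = rng.standard_normal((6, 6, 6))
        labels = (rng.random((6, 6, 6)) < 0.3).astype(int)
        perm = rng.permutation(chi.size)
        assert roi_mean(chi, labels, 1) == pytest.approx(
            roi_mean(chi.ravel()[perm].reshape(chi.shape), labels.ravel()[perm].reshape(chi.shape), 1)
        )


class TestNormalizeVolume:
    def test_identity_at_mean_tiv(self):
        assert normalize_volume(13.0, 1540.0, 1540.0) == pytest.approx(13.0)

    def test_hand_value(self):
        assert normalize_volume(13.0, 1400.0, 1540.0) == pytest.approx(14.3)

    @given(st.floats(0.1, 100), st.floats(800, 2200), st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_joint_rescaling_invariance(self, raw, tiv, scale):
        a = normalize_volume(raw, tiv, 1540.0)
        b = normalize_volume(raw, tiv * scale, 1540.0 * scale)
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_tiv_rejected(self):
        with pytest.raises(ValueError):
            normalize_volume(13.0, 0.0, 1540.0)


from oracles import flood_fill_components as _flood_fill_oracle  # noqa: E402


class TestLesionFilterTlv:
    def test_below_threshold_component_removed(self):
        """33 voxels at 0.42 mm^3 each (13.9 mm^3) fall below 15 mm^3."""
        mask = np.zeros((12, 12, 12), bool)
        mask[2:5, 2:5, 2:5] = True  # 27 voxels
        mask[5, 2:5, 2] = True  # +3
        mask[5, 2:5, 3] = True  # +3 -> 33 voxels
        assert mask.sum() == 33
        filtered, tlv = lesion_filter_tlv(mask, voxel_volume_mm3=0.42)
        assert tlv == 0.0 and not filtered.any()

    def test_surviving_components_summed_in_ml(self):
        """Components of 20 and 30 mm^3 give TLV 0.050 mL."""
        mask = np.zeros((20, 20, 20), bool)
        mask[1:3, 1:3, 1:6] = True  # 20 voxels
        mask[10:13, 10:15, 10:12] = True  # 30 voxels
        _, tlv = lesion_filter_tlv(mask, voxel_volume_mm3=1.0)
        assert tlv == pytest.approx(0.050)

    def test_threshold_is_inclusive(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:4, 1:6, 1] = True  # 15 voxels at 1 mm^3
        filtered, tlv = lesion_filter_tlv(mask, voxel_volume_mm3=1.0)
        assert filtered.sum() == 15 and tlv == pytest.approx(0.015)

    def test_empty_mask(self):
        _, tlv = lesion_filter_tlv(np.zeros((5, 5, 5), bool), 1.0)
        assert tlv == 0.0

    def test_matches_flood_fill_oracle_on_random_masks(self):
        """Component counts and survivor sets equal a brute-force BFS."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            mask = rng.random((16, 16, 16)) < 0.12
            comps = _flood_fill_oracle(mask)
            vox = 2.0  # mm^3/voxel -> survive at >= 8 voxels
            surviving = [c for c in comps if len(c) * vox >= 15.0]
            filtered, tlv = lesion_filter_tlv(mask, voxel_volume_mm3=vox)
            assert filtered.sum() == sum(len(c) for c in surviving)
            assert tlv == pytest.approx(sum(len(c) for c in surviving) * vox / 1000.0)


class TestLogTlv:
    def test_zero_lesion_subject(self):
        assert log_tlv(0.0) == pytest.approx(np.log(0.01))

    def test_identity_point(self):
        assert log_tlv(1.0 - 0.01) == pytest.approx(0.0)

    @given(st.floats(0, 50), st.floats(0, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert log_tlv(lo) <= log_tlv(hi)
        if hi - lo > 1e-9:
            assert log_tlv(lo) < log_tlv(hi)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_tlv(-1.0)


def test_extract_region_metrics_pipeline(coarse_phantom):
    chi = coarse_phantom.chi  # use the truth map directly
    m = extract_region_metrics(
        chi,
        coarse_phantom.labels,
        coarse_phantom.label_names,
        coarse_phantom.brain_mask,
        coarse_phantom.lesion_mask,
        coarse_phantom.grid.voxel_volume_mm3,
    )
    assert set(m.table.region) == set(coarse_phantom.label_names.values())
    row = m.table.set_index("region").loc["pallidum"]
    assert row.qsm_ppm == pytest.approx(0.099)
    assert row.raw_volume_ml == pytest.approx(row.n_voxels * 1.5**3 / 1000.0)
    assert m.tlv_ml >= 0 and np.isfinite(m.log_tlv)
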
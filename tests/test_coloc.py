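"""3D segmentation, QC, selection, spot growing, volume overlap, summaries."""

import numpy as np
import pytest

from censtab import coloc
from censtab import synthetic as syn

VOX = (10.65 / 15, 0.1, 0.1)


def _stack_from_channels(channels, voxel=VOX):
    return coloc.VoxelStack(channels=dict(channels), voxel_size_zyx=voxel)


class TestSegmentNuclei3D:
    def test_two_level_stack_high_agreement(self, two_channel_stack):
        spec, data, truth = two_channel_stack
        stack = _stack_from_channels(data)
        mask, _ = coloc.segment_nuclei_3d(stack)
        agree = (mask == (truth.nucleus_labels > 0)).mean()
        assert agree >= 0.99

    def test_all_background_stack_gives_empty_mask(self):
        rng = np.random.default_rng(0)
        noise = np.abs(rng.normal(100.0, 8.0, size=(10, 64, 64)))
        stack = _stack_from_channels({"dna": noise})
        mask, _ = coloc.segment_nuclei_3d(stack)
        assert mask.mean() <= 0.01

    def test_masking_is_idempotent(self, two_channel_stack):
        _, data, _ = two_channel_stack
        stack = _stack_from_channels(data)
        mask1, masked = coloc.segment_nuclei_3d(stack)
        mask2, _ = coloc.segment_nuclei_3d(masked)
        assert np.array_equal(mask1, mask2)

    def test_constant_dna_channel_raises(self):
        stack = _stack_from_channels({"dna": np.full((5, 16, 16), 7.0)})
        with pytest.raises(ValueError, match="Otsu"):
            coloc.segment_nuclei_3d(stack)

    def test_channels_zeroed_outside_mask(self, two_channel_stack):
        _, data, _ = two_channel_stack
        stack = _stack_from_channels(data)
        mask, masked = coloc.segment_nuclei_3d(stack)
        for ch in masked.channels.values():
            assert np.all(ch[~mask] == 0)


class TestIndividualizeNuclei:
    def test_three_disjoint_nuclei_three_records(self):
        spec = syn.StackSpec(shape_zyx=(15, 200, 200), n_nuclei=3, seed=13)
        data, truth = syn.make_stack(spec)
        stack = _stack_from_channels(data)
        mask, masked = coloc.segment_nuclei_3d(stack)
        records = coloc.individualize_nuclei(masked, mask)
        assert len(records) == 3

    def test_crop_contains_full_truth_mask(self):
        spec = syn.StackSpec(shape_zyx=(15, 120, 120), n_nuclei=1, seed=14)
        data, truth = syn.make_stack(spec)
        stack = _stack_from_channels(data)
        mask, masked = coloc.segment_nuclei_3d(stack)
        rec = coloc.individualize_nuclei(masked, mask)[0]
        r0, c0, r1, c1 = rec.bbox
        outside = truth.nucleus_labels.copy()
        outside[:, r0:r1, c0:c1] = 0
        # the recorded crop holds (essentially) all truth voxels of its nucleus
        assert outside.sum() / max(1, (truth.nucleus_labels > 0).sum()) < 0.01

    def test_record_count_matches_2d_labeling_oracle(self):
        rng = np.random.default_rng(15)
        for trial in range(5):
            n = int(rng.integers(1, 5))
            spec = syn.StackSpec(
                shape_zyx=(11, 280, 280), n_nuclei=n, nucleus_radius_um=3.0,
                seed=100 + trial,
            )
            data, truth = syn.make_stack(spec)
            stack = _stack_from_channels(data)
            mask, masked = coloc.segment_nuclei_3d(stack)
            records = coloc.individualize_nuclei(masked, mask)
            # oracle: count connected footprints of the projected truth mask
            from scipy import ndimage as ndi
            _, n_oracle = ndi.label(
                truth.nucleus_labels.max(axis=0) > 0, structure=np.ones((3, 3))
            )
            assert len(records) == n_oracle

    def test_projected_area_uses_pixel_size(self):
        spec = syn.StackSpec(shape_zyx=(15, 120, 120), n_nuclei=1,
                             nucleus_radius_um=3.0, seed=16)
        data, _ = syn.make_stack(spec)
        stack = _stack_from_channels(data)
        mask, masked = coloc.segment_nuclei_3d(stack)
        rec = coloc.individualize_nuclei(masked, mask)[0]
        assert rec.projected_area_um2 == pytest.approx(np.pi * 3.0**2, rel=0.05)


def _mock_record(nucleus_id, area=150.0, edge=False):
    return coloc.NucleusRecord(
        nucleus_id=nucleus_id, crop={}, mask3d=np.zeros((1, 1, 1), bool),
        bbox=(0, 0, 1, 1), projected_area_um2=area, touches_edge=edge,
    )


class TestQcFilter:
    def test_oversized_nucleus_excluded_with_reason(self):
        kept, excluded = coloc.qc_filter([_mock_record(1, area=350.0)])
        assert not kept
        assert excluded[0].qc_flags == {"too_large"}

    def test_interior_normal_nucleus_kept(self):
        kept, excluded = coloc.qc_filter([_mock_record(1, area=150.0)])
        assert len(kept) == 1 and not excluded

    def test_edge_touching_excluded(self):
        kept, excluded = coloc.qc_filter([_mock_record(1, edge=True)])
        assert excluded[0].qc_flags == {"edge"}

    def test_manual_annotations_honored(self):
        kept, excluded = coloc.qc_filter(
            [_mock_record(1), _mock_record(2)], annotations={2: {"mitotic"}}
        )
        assert [r.nucleus_id for r in kept] == [1]
        assert excluded[0].qc_flags == {"mitotic"}

    def test_unknown_annotation_rejected(self):
        with pytest.raises(ValueError):
            coloc.qc_filter([_mock_record(1)], annotations={1: {"weird"}})

    def test_mixed_field_matches_rule_by_rule_oracle(self):
        records = [
            _mock_record(1, area=100.0),
            _mock_record(2, area=301.0),
            _mock_record(3, area=100.0, edge=True),
            _mock_record(4, area=350.0, edge=True),
            _mock_record(5, area=200.0),
        ]
        kept, excluded = coloc.qc_filter(records, annotations={5: {"apoptotic"}})
        assert [r.nucleus_id for r in kept] == [1]
        reasons = {r.nucleus_id: r.qc_flags for r in excluded}
        assert reasons == {
            2: {"too_large"},
            3: {"edge"},
            4: {"edge", "too_large"},
            5: {"apoptotic"},
        }


class TestSelectNuclei:
    def test_exactly_100_from_150(self):
        records = [_mock_record(i) for i in range(150)]
        chosen = coloc.select_nuclei(records, n=100, seed=3)
        assert len(chosen) == 100
        assert len({r.nucleus_id for r in chosen}) == 100

    def test_shortfall_returns_all_with_warning(self):
        records = [_mock_record(i) for i in range(40)]
        with pytest.warns(UserWarning, match="40"):
            chosen = coloc.select_nuclei(records, n=100, seed=3)
        assert len(chosen) == 40

    def test_same_seed_same_subset(self):
        records = [_mock_record(i) for i in range(150)]
        a = coloc.select_nuclei(records, n=100, seed=9)
        b = coloc.select_nuclei(records, n=100, seed=9)
        assert [r.nucleus_id for r in a] == [r.nucleus_id for r in b]


SPOT_PARAMS = coloc.SpotSegmentationParams(
    smooth_sigma=0.8, seed_threshold=600.0, include_threshold=350.0
)


def _gaussian_spot(shape, center, sigma=1.5, amp=1500.0, background=100.0):
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return background + amp * np.exp(-d2 / (2 * sigma**2))


class TestSegmentSpots:
    def test_single_spot_contains_peak_voxel(self):
        vol = _gaussian_spot((11, 32, 32), (5, 16, 16))
        spots = coloc.segment_spots(vol, SPOT_PARAMS, VOX)
        assert len(spots) == 1
        assert spots.labels[5, 16, 16] == spots.ids[0]

    def test_two_well_separated_spots(self):
        vol = _gaussian_spot((11, 48, 48), (5, 12, 12)) + _gaussian_spot(
            (11, 48, 48), (5, 36, 36), background=0.0
        )
        spots = coloc.segment_spots(vol, SPOT_PARAMS, VOX)
        assert len(spots) == 2

    def test_spot_count_matches_generator_truth(self):
        hits = 0
        trials = 8
        for seed in range(trials):
            spec = syn.StackSpec(
                shape_zyx=(15, 150, 150), n_nuclei=1,
                channels=(syn.ChannelSpec("c", n_spots=4, spot_radius_um=0.3),),
                seed=200 + seed,
            )
            data, truth = syn.make_stack(spec)
            spots = coloc.segment_spots(data["c"], SPOT_PARAMS, VOX)
            if len(spots) == len(truth.spots["c"]):
                hits += 1
        assert hits == trials

    def test_empty_volume_valid(self):
        spots = coloc.segment_spots(np.zeros((5, 16, 16)), SPOT_PARAMS, VOX)
        assert len(spots) == 0

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            coloc.SpotSegmentationParams(seed_threshold=100.0, include_threshold=200.0)


def _spotset_from_masks(masks, channel="c"):
    labels = np.zeros(masks[0].shape, dtype=np.int32)
    vol_vox, vol_um3, peaks = {}, {}, {}
    for i, m in enumerate(masks, start=1):
        labels[m] = i
        vol_vox[i] = int(m.sum())
        vol_um3[i] = float(m.sum())
        peaks[i] = 1.0
    return coloc.SpotSet(channel, labels, vol_vox, vol_um3, peaks)


class TestVolumeOverlap:
    def test_identical_sets_fraction_one(self):
        m = np.zeros((4, 8, 8), bool)
        m[1:3, 2:5, 2:5] = True
        events = coloc.volume_overlap(_spotset_from_masks([m]), _spotset_from_masks([m]))
        assert len(events) == 1
        assert events[0].overlap_fraction == 1.0

    def test_disjoint_sets_no_events(self):
        a = np.zeros((4, 8, 8), bool)
        b = np.zeros((4, 8, 8), bool)
        a[0, 0:2, 0:2] = True
        b[3, 6:8, 6:8] = True
        assert coloc.volume_overlap(_spotset_from_masks([a]), _spotset_from_masks([b])) == []

    def test_quarter_overlap_equals_voxel_counting(self):
        ref = np.zeros((2, 4, 4), bool)
        ref[0, 0:2, 0:4] = True  # 8 voxels
        par = np.zeros((2, 4, 4), bool)
        par[0, 1:2, 2:4] = True  # intersects 2 voxels
        events = coloc.volume_overlap(_spotset_from_masks([ref]), _spotset_from_masks([par]))
        assert events[0].overlap_fraction == pytest.approx(0.25)

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            shape = (4, 10, 10)
            a = rng.random(shape) < 0.2
            b = rng.random(shape) < 0.2
            if not a.any() or not b.any():
                continue
            events = coloc.volume_overlap(
                _spotset_from_masks([a]), _spotset_from_masks([b])
            )
            brute = (a & b).sum() / a.sum()
            if brute == 0:
                assert events == []
            else:
                assert events[0].overlap_fraction == pytest.approx(brute)


def test_overlap_fraction_stable_under_grid_refinement():
    """Voxel-counted overlap of two spheres at fixed physical geometry moves
    by < 5% when the grid is refined 2x in every axis (scale-free score)."""
    from censtab.synthetic import _ball_offsets, _overlap_fraction_sets

    radius_um, offset_um = 0.3, 0.25
    fracs = []
    for v in (0.05, 0.025):
        a = _ball_offsets(radius_um, (v, v, v))
        b = a + np.array([0, 0, int(round(offset_um / v))])
        fracs.append(_overlap_fraction_sets(a, b))
    assert abs(fracs[0] - fracs[1]) < 0.05


class TestFilterEvents:
    @staticmethod
    def _evts(fractions):
        return [coloc.OverlapEvent(1, i, f) for i, f in enumerate(fractions)]

    def test_below_threshold_removed(self):
        kept = coloc.filter_events(self._evts([0.05, 0.15]))
        assert [e.overlap_fraction for e in kept] == [0.15]

    def test_empty_input(self):
        assert coloc.filter_events([]) == []

    def test_boundary_ten_percent_kept(self):
        kept = coloc.filter_events(self._evts([0.05, 0.10, 0.30]))
        assert [e.overlap_fraction for e in kept] == [0.10, 0.30]

    def test_exact_voxel_ratio_boundary(self):
        # a fraction computed as 2/20 voxels must survive the 0.10 filter
        kept = coloc.filter_events(self._evts([2 / 20]))
        assert len(kept) == 1


class TestSummarize:
    def test_no_events(self):
        s = coloc.summarize({}, [1, 2, 3])
        assert s.fraction_with_event == 0.0
        assert s.mean_events_per_nucleus == 0.0

    def test_every_nucleus_one_event(self):
        events = {i: [coloc.OverlapEvent(1, 1, 0.5, nucleus_id=i)] for i in (1, 2)}
        s = coloc.summarize(events, [1, 2])
        assert s.fraction_with_event == 1.0
        assert s.mean_events_per_nucleus == 1.0

    def test_hand_computed_cohort(self):
        events = {
            1: [coloc.OverlapEvent(1, 1, 0.5), coloc.OverlapEvent(2, 1, 0.2)],
            2: [],
            3: [coloc.OverlapEvent(1, 2, 0.9)],
            4: [],
        }
        s = coloc.summarize(events, [1, 2, 3, 4], {"c": {1: 3, 2: 0, 3: 1, 4: 2}})
        assert s.fraction_with_event == pytest.approx(0.5)
        assert s.mean_events_per_nucleus == pytest.approx(0.75)
        assert sorted(s.overlap_fractions) == [0.2, 0.5, 0.9]
        assert s.focus_counts["n_foci"].sum() == 6


class TestEndToEnd:
    def test_engineered_cohort_recovered(self, two_channel_stack):
        spec, data, truth = two_channel_stack
        stack = _stack_from_channels(data)
        mask, masked = coloc.segment_nuclei_3d(stack)
        records = coloc.individualize_nuclei(masked, mask)
        kept, _ = coloc.qc_filter(records)
        summary, events = coloc.analyze_cohort(
            kept, "cenpb", "halo",
            {"cenpb": SPOT_PARAMS, "halo": SPOT_PARAMS}, spec.voxel_size_zyx,
        )
        # one engineered 0.5-overlap pair per nucleus; random spots disjoint
        assert summary.n_nuclei == 2
        assert summary.fraction_with_event == 1.0
        assert summary.mean_events_per_nucleus == 1.0

    def test_partner_depletion_drives_events_to_zero(self, two_channel_stack):
        spec, data, truth = two_channel_stack
        depleted = dict(data)
        # protein degradation: partner channel collapses to background
        rng = np.random.default_rng(0)
        depleted["halo"] = np.clip(
            rng.normal(100.0, 8.0, size=data["halo"].shape), 0, None
        )
        stack = _stack_from_channels(depleted)
        mask, masked = coloc.segment_nuclei_3d(stack)
        kept, _ = coloc.qc_filter(coloc.individualize_nuclei(masked, mask))
        summary, _ = coloc.analyze_cohort(
            kept, "cenpb", "halo",
            {"cenpb": SPOT_PARAMS, "halo": SPOT_PARAMS}, spec.voxel_size_zyx,
        )
        assert summary.mean_events_per_nucleus == 0.0
        assert summary.fraction_with_event == 0.0

    def test_pipeline_determinism(self, two_channel_stack):
        spec, data, truth = two_channel_stack
        results = []
        for _ in range(2):
            stack = _stack_from_channels(data)
            mask, masked = coloc.segment_nuclei_3d(stack)
            kept, _ = coloc.qc_filter(coloc.individualize_nuclei(masked, mask))
            chosen = coloc.select_nuclei(kept, n=100, seed=5)
            summary, _ = coloc.analyze_cohort(
                chosen, "cenpb", "halo",
                {"cenpb": SPOT_PARAMS, "halo": SPOT_PARAMS}, spec.voxel_size_zyx,
            )
            results.append(summary)
        assert results[0].fraction_with_event == results[1].fraction_with_event
        assert np.array_equal(results[0].overlap_fractions, results[1].overlap_fractions)
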
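"""Region arithmetic, patient-space geometry, identity rewriting."""

import numpy as np
import pytest

from mousehotel import (
    GridPlan,
    PhantomSpec,
    SplitError,
    UidGenerator,
    compute_regions,
    label_orientation,
    make_phantom_volume,
    rewrite_identity,
    shift_position,
    split_series,
)
from mousehotel.splitter import Provenance, SeriesVolume, VolumeGeometry


def brute_force_tiling(rows, cols, n_rows, n_cols):
    """Independent oracle: enumerate every region pixel-by-pixel."""
    rr, rc = rows // n_rows, cols // n_cols
    cells = {}
    for r in range(rows):
        for c in range(cols):
            i, j = r // rr, c // rc
            if i < n_rows and j < n_cols:
                cells.setdefault((i, j), []).append((r, c))
    return {k: (min(p[0] for p in v), min(p[1] for p in v), len(v)) for k, v in cells.items()}


class TestComputeRegions:
    def test_exact_halving(self):
        regions = compute_regions(256, 256, GridPlan(n_rows=1, n_cols=2))
        assert len(regions) == 2
        assert {(r.r0, r.c0, r.region_rows, r.region_cols) for r in regions} == {
            (0, 0, 256, 128), (0, 128, 256, 128)}

    def test_identity_grid(self):
        (region,) = compute_regions(100, 100, GridPlan())
        assert (region.r0, region.c0, region.region_rows, region.region_cols) == (
            0, 0, 100, 100)

    def test_non_divisible_matches_brute_force(self):
        plan = GridPlan(n_rows=2, n_cols=2)
        regions = compute_regions(255, 255, plan)
        oracle = brute_force_tiling(255, 255, 2, 2)
        assert all(r.region_rows == 127 and r.region_cols == 127 for r in regions)
        for region in regions:
            _, i, j = plan.cell_of(region.slot_index)
            r0, c0, count = oracle[(i, j)]
            assert (region.r0, region.c0) == (r0, c0)
            assert region.region_rows * region.region_cols == count

    def test_grid_larger_than_matrix_rejected(self):
        with pytest.raises(SplitError):
            compute_regions(3, 3, GridPlan(n_rows=4, n_cols=1))

    def test_occupied_subset(self):
        regions = compute_regions(64, 64, GridPlan(n_rows=2, n_cols=2,
                                                   occupied=frozenset({1, 4})))
        assert [r.slot_index for r in regions] == [1, 4]


def _geometry(orientation, spacing=(0.5, 0.5), position=(0.0, 0.0, 0.0)):
    return VolumeGeometry(rows=128, cols=128, pixel_spacing=spacing,
                          orientation=orientation, positions=(position,))


class TestShiftPosition:
    def test_zero_offset_is_identity(self):
        geom = _geometry((1, 0, 0, 0, 1, 0))
        assert np.allclose(shift_position((1.0, 2.0, 3.0), geom, 0, 0), (1, 2, 3))

    def test_axial_half_shift(self):
        geom = _geometry((1, 0, 0, 0, 1, 0))
        new = shift_position((0.0, 0.0, 0.0), geom, 0, 128)
        assert np.allclose(new, (64.0, 0.0, 0.0))  # 128 * 0.5 mm along x

    def test_oblique_matches_full_affine_oracle(self):
        from mousehotel.fixtures import ORIENTATION_PRESETS

        orient = ORIENTATION_PRESETS["oblique"]
        geom = _geometry(orient, spacing=(0.7, 0.4), position=(5.0, -3.0, 2.0))
        r0, c0 = 37, 59
        shifted = shift_position((5.0, -3.0, 2.0), geom, r0, c0)
        # independent full affine: position + c·Δc·u + r·Δr·v at voxel (r0, c0)
        u, v = np.asarray(orient[:3]), np.asarray(orient[3:])
        oracle = np.asarray([5.0, -3.0, 2.0]) + c0 * 0.4 * u + r0 * 0.7 * v
        assert np.max(np.abs(shifted - oracle)) < 1e-6

    def test_degenerate_orientation_rejected(self):
        with pytest.raises(ValueError):
            _geometry((1, 0, 0, 1, 0, 0))  # parallel row/col directions


class TestLabelOrientation:
    @pytest.mark.parametrize("orientation, label", [
        ((1, 0, 0, 0, 1, 0), "trans-axial"),
        ((1, 0, 0, 0, 0, -1), "coronal"),
        ((0, 1, 0, 0, 0, -1), "sagittal"),
    ])
    def test_canonical_orientations(self, orientation, label):
        assert label_orientation(orientation) == label

    def test_degenerate_normal_rejected(self):
        with pytest.raises(ValueError):
            label_orientation((1, 0, 0, 1, 0, 0))


class TestSplitSeries:
    def test_blob_centroids_land_in_their_own_series(self, phantom):
        volume, truth = phantom
        result = split_series(volume, GridPlan(n_rows=2, n_cols=2), UidGenerator(1))
        for entry in truth:
            own = np.stack([d.pixel_array for d in result.subjects[entry["slot"]].datasets])
            assert own.max() == entry["intensity"]
            for other_slot, subject in result.subjects.items():
                if other_slot != entry["slot"]:
                    arr = np.stack([d.pixel_array for d in subject.datasets])
                    assert entry["intensity"] not in arr

    def test_pixel_conservation(self, phantom):
        volume, _ = phantom
        result = split_series(volume, GridPlan(n_rows=2, n_cols=2), UidGenerator(1))
        source = volume.pixel_stack()
        for subject in result.subjects.values():
            region = subject.region
            derived = np.stack([d.pixel_array for d in subject.datasets])
            crop = source[:, region.r0:region.r0 + region.region_rows,
                          region.c0:region.c0 + region.region_cols]
            assert np.array_equal(derived, crop)

    def test_slice_counts_preserved(self, phantom):
        volume, _ = phantom
        result = split_series(volume, GridPlan(n_rows=2, n_cols=2), UidGenerator(1))
        for subject in result.subjects.values():
            assert len(subject.datasets) == len(volume)

    def test_spacing_and_orientation_bit_identical(self, phantom):
        volume, _ = phantom
        result = split_series(volume, GridPlan(n_rows=2, n_cols=2), UidGenerator(1))
        src = volume.datasets[0]
        for subject in result.subjects.values():
            for ds in subject.datasets:
                assert list(map(str, ds.PixelSpacing)) == list(map(str, src.PixelSpacing))
                assert list(map(str, ds.ImageOrientationPatient)) == list(
                    map(str, src.ImageOrientationPatient))

    def test_uid_freshness(self, phantom):
        volume, _ = phantom
        result = split_series(volume, GridPlan(n_rows=2, n_cols=2), UidGenerator(1))
        derived = set()
        for subject in result.subjects.values():
            derived |= {subject.study_uid, subject.series_uid}
            derived |= {str(d.SOPInstanceUID) for d in subject.datasets}
            derived |= {str(d.StorageMediaFileSetUID) for d in subject.datasets}
        assert derived.isdisjoint(result.source_uids)
        sop_uids = [u for s in result.subjects.values() for u in s.sop_map]
        assert len(set(sop_uids)) == len(sop_uids)

    def test_geometry_oracle_per_voxel(self):
        volume, _ = make_phantom_volume(
            PhantomSpec(orientation="oblique", matrix=(64, 64), n_slices=4, seed=8))
        geom = volume.geometry
        result = split_series(volume, GridPlan(n_rows=2, n_cols=2), UidGenerator(3))
        for subject in result.subjects.values():
            region = subject.region
            for k, ds in enumerate(subject.datasets):
                der = VolumeGeometry(
                    rows=int(ds.Rows), cols=int(ds.Columns),
                    pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
                    orientation=tuple(float(x) for x in ds.ImageOrientationPatient),
                    positions=(tuple(float(x) for x in ds.ImagePositionPatient),),
                )
                for r in (0, der.rows - 1):
                    for c in (0, der.cols - 1):
                        got = der.voxel_to_patient(0, r, c)
                        want = geom.voxel_to_patient(k, r + region.r0, c + region.c0)
                        assert np.max(np.abs(got - want)) < 1e-6

    def test_heterogeneous_geometry_rejected(self, phantom):
        volume, _ = phantom
        volume.datasets[3].PixelSpacing = ["0.6", "0.5"]
        with pytest.raises(SplitError, match="heterogeneous"):
            SeriesVolume(volume.datasets)

    def test_multiframe_rejected(self, phantom):
        volume, _ = phantom
        volume.datasets[0].NumberOfFrames = 4
        with pytest.raises(SplitError, match="multi-frame"):
            SeriesVolume(volume.datasets)

    def test_stack_axis_splitting(self):
        volume, _ = make_phantom_volume(
            PhantomSpec(n_rows=1, n_cols=1, matrix=(32, 32), n_slices=8, seed=2))
        plan = GridPlan(n_rows=1, n_cols=1, n_stacks=2)
        result = split_series(volume, plan, UidGenerator(4))
        assert sorted(result.subjects) == [1, 2]
        assert result.subjects[1].slice_range == (0, 4)
        assert result.subjects[2].slice_range == (4, 8)
        src = volume.pixel_stack()
        assert np.array_equal(
            np.stack([d.pixel_array for d in result.subjects[2].datasets]), src[4:])

    def test_identity_split_reproduces_source(self):
        volume, _ = make_phantom_volume(
            PhantomSpec(n_rows=1, n_cols=1, matrix=(32, 32), n_slices=4, seed=2))
        result = split_series(volume, GridPlan(), UidGenerator(5))
        assert np.array_equal(
            np.stack([d.pixel_array for d in result.subjects[1].datasets]),
            volume.pixel_stack())


class TestRewriteIdentity:
    def _provenance(self):
        return Provenance(orig_name="MM_CAGE7", orig_id="MM007",
                          sop_class_uid="1.2.840.10008.5.1.4.1.1.4",
                          sop_instance_uid="2.25.4242")

    def _slice(self, phantom):
        volume, _ = phantom
        import copy
        return copy.deepcopy(volume.datasets[0])

    def test_default_naming_template(self, phantom):
        ds = self._slice(phantom)
        rewrite_identity(ds, 3, GridPlan(n_rows=2, n_cols=2), self._provenance(),
                         UidGenerator(6), "2.25.10", "2.25.11")
        assert str(ds.PatientID) == "MM007_3"
        assert str(ds.PatientName) == "MM_CAGE7_3"

    def test_series_number_rule(self, phantom):
        ds = self._slice(phantom)
        ds.SeriesNumber = 5
        rewrite_identity(ds, 2, GridPlan(n_rows=2, n_cols=2), self._provenance(),
                         UidGenerator(6), "2.25.10", "2.25.11")
        assert int(ds.SeriesNumber) == 502

    def test_group_item_holds_original_identity(self, phantom):
        ds = self._slice(phantom)
        rewrite_identity(ds, 1, GridPlan(n_rows=2, n_cols=2), self._provenance(),
                         UidGenerator(6), "2.25.10", "2.25.11")
        item = ds.SourcePatientGroupIdentificationSequence[0]
        assert str(item.PatientName) == "MM_CAGE7"
        assert str(item.PatientID) == "MM007"
        ref = ds.DerivationImageSequence[0].SourceImageSequence[0]
        assert str(ref.ReferencedSOPInstanceUID) == "2.25.4242"
        assert str(ref.ReferencedSOPClassUID) == "1.2.840.10008.5.1.4.1.1.4"
        assert list(ds.ImageType)[0] == "DERIVED"

    def test_unknown_placeholder_is_config_error(self, phantom):
        ds = self._slice(phantom)
        plan = GridPlan(naming_template="{cage}_{slot}")
        with pytest.raises(SplitError, match="cage"):
            rewrite_identity(ds, 1, plan, self._provenance(), UidGenerator(6),
                             "2.25.10", "2.25.11")
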
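"""I/O, rasterization and resampling tests, with shapely as the independent
point-in-polygon oracle."""

import numpy as np
import pytest

import contoureval as ce
from conftest import make_mask


def _write_nifti(tmp_path, data, zooms_mm=(1.0, 1.0, 1.0), origin_mm=(0, 0, 0), name="vol.nii.gz"):
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(zooms_mm)
    affine[:3, 3] = origin_mm
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(zooms_mm)
    path = tmp_path / name
    nib.save(img, str(path))
    return path


class TestNiftiMasks:
    def test_mm_header_converted_to_cm(self, tmp_path):
        path = _write_nifti(tmp_path, np.ones((10, 10, 10), dtype=np.uint8))
        mask = ce.read_mask_volume(path)
        assert mask.voxel_count == 1000
        assert mask.geometry.spacing == (0.1, 0.1, 0.1)
        assert mask.volume_cm3 == pytest.approx(1.0)

    def test_all_zero_volume_is_valid_empty_mask(self, tmp_path):
        path = _write_nifti(tmp_path, np.zeros((4, 4, 4), dtype=np.uint8))
        mask = ce.read_mask_volume(path)
        assert mask.is_empty()

    def test_nonzero_values_become_one(self, tmp_path):
        data = np.zeros((3, 3, 3), dtype=np.uint8)
        data[0, 0, 0], data[1, 1, 1], data[2, 2, 2] = 0, 2, 255
        mask = ce.read_mask_volume(_write_nifti(tmp_path, data))
        assert mask.voxel_count == 2
        assert mask.voxels[1, 1, 1] and mask.voxels[2, 2, 2]

    def test_non_3d_volume_rejected(self, tmp_path):
        import nibabel as nib

        path = tmp_path / "vol2d.nii.gz"
        nib.save(nib.Nifti1Image(np.ones((4, 4), dtype=np.uint8), np.eye(4)), str(path))
        with pytest.raises(ce.ShapeError):
            ce.read_mask_volume(path)

    def test_oblique_affine_rejected(self, tmp_path):
        import nibabel as nib

        affine = np.eye(4)
        affine[0, 1] = 0.3  # shear -> oblique
        img = nib.Nifti1Image(np.ones((4, 4, 4), dtype=np.uint8), affine)
        path = tmp_path / "oblique.nii.gz"
        nib.save(img, str(path))
        with pytest.raises(ce.GeometryError):
            ce.read_mask_volume(path)

    def test_unreadable_file_raises_ioerror(self, tmp_path):
        bad = tmp_path / "junk.nii"
        bad.write_text("not a nifti")
        with pytest.raises(IOError):
            ce.read_mask_volume(bad)

    def test_round_trip_preserves_mask_and_geometry(self, tmp_path, rng):
        arr = rng.random((9, 7, 5)) < 0.4
        mask = make_mask(arr, spacing=(0.12, 0.08, 0.25), origin=(-1.0, 2.0, 0.5))
        ce.write_mask_volume(mask, tmp_path / "m.nii.gz")
        back = ce.read_mask_volume(tmp_path / "m.nii.gz")
        np.testing.assert_array_equal(back.voxels, mask.voxels)
        np.testing.assert_allclose(back.geometry.spacing, mask.geometry.spacing, atol=1e-6)
        np.testing.assert_allclose(back.geometry.origin, mask.geometry.origin, atol=1e-6)


class TestRasterization:
    def test_square_polygon_voxel_count(self):
        # 4x4 cm square on a 0.1 cm grid: 40x40 centers strictly inside
        geom = ce.ImageGeometry((60, 60, 3), (0.1, 0.1, 0.3))
        square = np.array(
            [[0.95, 0.95, 0.3], [4.95, 0.95, 0.3], [4.95, 4.95, 0.3], [0.95, 4.95, 0.3]]
        )
        mask = ce.rasterize_planar_contours([square], geom)
        assert mask.voxel_count == 40 * 40
        assert mask.voxels[:, :, 1].sum() == 40 * 40

    @pytest.mark.parametrize("poly_idx", range(5))
    def test_matches_shapely_covers_oracle(self, poly_idx, rng):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, Polygon

        geom = ce.ImageGeometry((20, 20, 1), (0.1, 0.1, 0.1))
        local = np.random.default_rng(100 + poly_idx)
        # random star-shaped polygon around the grid center
        angles = np.sort(local.uniform(0, 2 * np.pi, size=7))
        radii = local.uniform(0.2, 0.9, size=7)
        pts2 = np.column_stack(
            [1.0 + radii * np.cos(angles), 1.0 + radii * np.sin(angles)]
        )
        poly3 = np.column_stack([pts2, np.zeros(len(pts2))])
        mask = ce.rasterize_planar_contours([poly3], geom)
        sh_poly = Polygon(pts2)
        for i, x in enumerate(geom.voxel_centers(0)):
            for j, y in enumerate(geom.voxel_centers(1)):
                p = Point(x, y)
                if mask.voxels[i, j, 0] != sh_poly.covers(p):
                    # disagreement only permitted within float noise of an edge
                    assert sh_poly.exterior.distance(p) < 1e-9

    def test_triangle_vertices_on_voxel_centers(self):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import Point, Polygon

        geom = ce.ImageGeometry((12, 12, 1), (0.1, 0.1, 0.1))
        tri = np.array([[0.2, 0.2, 0.0], [0.9, 0.3, 0.0], [0.4, 1.0, 0.0]])
        mask = ce.rasterize_planar_contours([tri], geom)
        sh = Polygon(tri[:, :2])
        for i, x in enumerate(geom.voxel_centers(0)):
            for j, y in enumerate(geom.voxel_centers(1)):
                p = Point(x, y)
                if mask.voxels[i, j, 0] != sh.covers(p):
                    assert sh.exterior.distance(p) < 1e-9

    def test_empty_contour_list_gives_empty_mask(self):
        geom = ce.ImageGeometry((5, 5, 5), (0.1, 0.1, 0.1))
        assert ce.rasterize_planar_contours([], geom).is_empty()

    def test_translation_equivariance(self):
        shift = np.array([0.37, -0.21, 0.5])
        geom = ce.ImageGeometry((15, 15, 2), (0.1, 0.1, 0.25))
        geom2 = ce.ImageGeometry((15, 15, 2), (0.1, 0.1, 0.25), origin=tuple(shift))
        poly = np.array([[0.3, 0.3, 0.0], [1.1, 0.35, 0.0], [0.8, 1.2, 0.0]])
        m1 = ce.rasterize_planar_contours([poly], geom)
        m2 = ce.rasterize_planar_contours([poly + shift], geom2)
        np.testing.assert_array_equal(m1.voxels, m2.voxels)

    def test_plane_not_matching_slice_raises(self):
        geom = ce.ImageGeometry((5, 5, 2), (0.1, 0.1, 0.2))
        poly = np.array([[0.1, 0.1, 5.0], [0.3, 0.1, 5.0], [0.2, 0.3, 5.0]])
        with pytest.raises(ce.GeometryError):
            ce.rasterize_planar_contours([poly], geom)

    def test_self_intersecting_polygon_warns_but_fills(self):
        geom = ce.ImageGeometry((20, 20, 1), (0.1, 0.1, 0.1))
        bowtie = np.array(
            [[0.2, 0.2, 0.0], [1.6, 1.6, 0.0], [1.6, 0.2, 0.0], [0.2, 1.6, 0.0]]
        )
        with pytest.warns(UserWarning, match="self-intersecting"):
            mask = ce.rasterize_planar_contours([bowtie], geom)
        assert mask.voxel_count > 0


class TestDoseResampling:
    def test_identity_resampling_is_exact(self, rng):
        geom = ce.ImageGeometry((8, 8, 8), (0.1, 0.1, 0.2))
        dose = ce.DoseGrid(geom, rng.random((8, 8, 8)) * 70)
        out, frac = ce.resample_dose(dose, geom)
        np.testing.assert_allclose(out.dose, dose.dose, atol=1e-12)
        assert frac == 0.0

    def test_constant_field_resamples_to_constant(self):
        src = ce.ImageGeometry((10, 10, 10), (0.2, 0.2, 0.2))
        dose = ce.DoseGrid(src, np.full((10, 10, 10), 60.0))
        fine = ce.ImageGeometry((12, 12, 12), (0.1, 0.1, 0.1), origin=(0.2, 0.2, 0.2))
        out, frac = ce.resample_dose(dose, fine)
        np.testing.assert_allclose(out.dose, 60.0)
        assert frac == 0.0

    def test_linear_ramp_matches_closed_form_on_shifted_grid(self):
        src = ce.ImageGeometry((50, 4, 4), (0.1, 0.1, 0.1))
        x = src.voxel_centers(0)[:, None, None]
        dose = ce.DoseGrid(src, np.broadcast_to(x, (50, 4, 4)).copy())  # d(x) = x Gy/cm
        tgt = ce.ImageGeometry((30, 4, 4), (0.1, 0.1, 0.1), origin=(1.03, 0.0, 0.0))
        out, _ = ce.resample_dose(dose, tgt)
        expected = tgt.voxel_centers(0)[:, None, None]
        np.testing.assert_allclose(out.dose, np.broadcast_to(expected, (30, 4, 4)), atol=1e-9)

    def test_outside_voxels_zero_and_counted(self):
        src = ce.ImageGeometry((10, 10, 10), (0.1, 0.1, 0.1))
        dose = ce.DoseGrid(src, np.full((10, 10, 10), 60.0))
        tgt = ce.ImageGeometry((20, 10, 10), (0.1, 0.1, 0.1))
        out, frac = ce.resample_dose(dose, tgt)
        assert frac == pytest.approx(0.5, abs=0.06)
        assert (out.dose[12:] == 0).all()

    def test_zero_overlap_raises(self):
        src = ce.ImageGeometry((5, 5, 5), (0.1, 0.1, 0.1))
        dose = ce.DoseGrid(src, np.zeros((5, 5, 5)))
        tgt = ce.ImageGeometry((5, 5, 5), (0.1, 0.1, 0.1), origin=(50.0, 0, 0))
        with pytest.raises(ce.GeometryError):
            ce.resample_dose(dose, tgt)


class TestDicom:
    def _rtdose_dataset(self):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        arr = (np.arange(2 * 3 * 4).reshape(2, 3, 4)).astype(np.uint32)  # (z, y, x)
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = generate_uid()
        ds.Rows, ds.Columns, ds.NumberOfFrames = 3, 4, 2
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 32, 32, 31
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.DoseGridScaling = 0.5
        ds.PixelSpacing = [2.0, 1.0]  # row (y) = 2 mm, col (x) = 1 mm
        ds.GridFrameOffsetVector = [0.0, 2.5]
        ds.ImagePositionPatient = [10.0, 20.0, 30.0]
        ds.PixelData = arr.tobytes()
        return ds, arr

    def test_rtdose_reader_scaling_and_axes(self):
        ds, arr = self._rtdose_dataset()
        dose = ce.read_rtdose(ds)
        assert dose.geometry.shape == (4, 3, 2)
        np.testing.assert_allclose(dose.geometry.spacing, (0.1, 0.2, 0.25))
        np.testing.assert_allclose(dose.geometry.origin, (1.0, 2.0, 3.0))
        np.testing.assert_allclose(dose.dose, arr.transpose(2, 1, 0) * 0.5)

    def test_rtstruct_rasterization(self):
        from pydicom.dataset import Dataset

        ds = Dataset()
        roi = Dataset()
        roi.ROIName = "M-R"
        roi.ROINumber = 1
        ds.StructureSetROISequence = [roi]
        contour = Dataset()
        # 10x10 mm square at z = 0 (mm coordinates)
        contour.ContourData = [2.5, 2.5, 0.0, 12.5, 2.5, 0.0, 12.5, 12.5, 0.0, 2.5, 12.5, 0.0]
        rc = Dataset()
        rc.ReferencedROINumber = 1
        rc.ContourSequence = [contour]
        ds.ROIContourSequence = [rc]
        geom = ce.ImageGeometry((20, 20, 1), (0.1, 0.1, 0.1))
        mask = ce.rasterize_rtstruct(ds, "M-R", geom)
        # square spans 0.25..1.25 cm; centers 0.3..1.2 in both axes -> 10x10
        assert mask.voxel_count == 10 * 10

    def test_rtstruct_unknown_roi_raises(self):
        from pydicom.dataset import Dataset

        ds = Dataset()
        roi = Dataset()
        roi.ROIName = "M-R"
        roi.ROINumber = 1
        ds.StructureSetROISequence = [roi]
        ds.ROIContourSequence = []
        with pytest.raises(KeyError):
            ce.rasterize_rtstruct(ds, "nope", ce.ImageGeometry((2, 2, 2), (0.1, 0.1, 0.1)))
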
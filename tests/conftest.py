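import numpy as np
import pytest

import voxelmap as vx


@pytest.fixture(scope="session")
def phantom_noise_free():
    """Two-branch phantom (72^3, 0.5 mm iso) with one 120 HU plaque on RMA layer +2."""
    spec = vx.default_spec(shape=(72, 72, 72))
    vol, truth = vx.generate_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def segmented_phantom(phantom_noise_free):
    """The noise-free phantom taken through segmentation and the Voxel-Map."""
    _, vol, truth = phantom_noise_free
    mask = vx.region_grow(vx.threshold_lumen(vol), vx.default_seed(vol))
    vmap = vx.build_voxel_map(mask)
    wall = vx.build_cawm(vol, vmap)
    return vol, truth, mask, vmap, wall


@pytest.fixture(scope="session")
def tube():
    """Straight z-aligned tube, radius 3 voxels at 1 mm isotropic spacing."""
    vol, truth = vx.generate_phantom(vx.tube_spec())
    mask = vx.region_grow(vx.threshold_lumen(vol), vx.default_seed(vol))
    return vol, truth, mask


def random_mask(shape=(16, 16, 16), p=0.15, seed=0):
    rng = np.random.default_rng(seed)
    return rng.random(shape) < p


def write_dicom_series(directory, array_zyx, spacing=(0.5, 0.4, 0.75), origin=(1.0, 2.0, 3.0),
                       z_positions=None):
    """Write a minimal synthetic CT DICOM series; array is (z, rows, cols) HU."""
    import pydicom
    from pydicom.dataset import Dataset, FileDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    dx, dy, dz = spacing
    series = generate_uid()
    nz = array_zyx.shape[0]
    if z_positions is None:
        z_positions = [origin[2] + dz * z for z in range(nz)]
    for z in range(nz):
        meta = Dataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        path = str(directory / f"slice{z:03d}.dcm")
        ds = FileDataset(path, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series
        ds.Modality = "CT"
        ds.Rows, ds.Columns = array_zyx.shape[1], array_zyx.shape[2]
        ds.PixelSpacing = [str(dy), str(dx)]  # row spacing, column spacing
        ds.ImagePositionPatient = [str(origin[0]), str(origin[1]), str(z_positions[z])]
        ds.ImageOrientationPatient = ["1", "0", "0", "0", "1", "0"]
        ds.SliceThickness = str(dz)
        ds.RescaleSlope = "1"
        ds.RescaleIntercept = "-1024"
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.PixelData = (array_zyx[z] + 1024).astype(np.int16).tobytes()
        ds.save_as(path, enforce_file_format=True)
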
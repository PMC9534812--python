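import numpy as np
import pytest

from pentafluct import AcquisitionGeometry, ImageSeries


@pytest.fixture
def raster_geometry():
    """Paper-grade confocal raster geometry (50 nm px, 8.19 µs / 4.92 ms)."""
    return AcquisitionGeometry(pixel_size=0.05, focal_waist=0.2,
                               modality="raster", pixel_dwell=8.19e-6,
                               line_time=4.92e-3)


@pytest.fixture
def camera_geometry():
    """TIRF camera geometry (150 nm px, 80 ms frames)."""
    return AcquisitionGeometry(pixel_size=0.15, focal_waist=0.3,
                               modality="camera", frame_time=0.08)


@pytest.fixture
def dual_camera_geometry():
    return AcquisitionGeometry(pixel_size=0.15, focal_waist=0.3,
                               modality="camera", frame_time=0.08,
                               n_channels=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(rng, n_frames=6, shape=(16, 16), geometry=None, n_channels=1,
                offset=10.0):
    """Small positive random series for I/O and estimator plumbing tests."""
    if geometry is None:
        geometry = AcquisitionGeometry(
            pixel_size=0.05, focal_waist=0.2, modality="raster",
            pixel_dwell=8.19e-6, line_time=4.92e-3, n_channels=n_channels)
    data = [offset + rng.random((n_frames, *shape)) for _ in range(n_channels)]
    return ImageSeries(data=data, geometry=geometry)
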
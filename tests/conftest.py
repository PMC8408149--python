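import numpy as np
import pytest

from lensxct import PhantomConfig, PrecipitateRecord


@pytest.fixture
def tiny_config():
    """Factory for small, fast phantom configurations (~125^3 voxels)."""
    def make(**overrides):
        params = dict(
            lens_radius_um=300.0,
            voxel_pitch_um=5.0,
            shell_radii_um=(200.0,),
            shell_sd_um=15.0,
            n_precipitates=15,
            length_max_um=60.0,
            mfd_log_sd=0.5,
            frac_below_40um=0.8,
            noise_sd=0.0,
            seed=7,
        )
        params.update(overrides)
        return PhantomConfig(**params)
    return make


def make_records(centroids_um, **common):
    """Minimal measurement records at given (z, y, x) centroids (µm)."""
    records = []
    for i, c in enumerate(np.atleast_2d(centroids_um)):
        records.append(PrecipitateRecord(
            id=i + 1,
            voxel_count=common.get("voxel_count", 10),
            volume_um3=common.get("volume_um3", 1250.0),
            centroid_um=tuple(float(v) for v in c),
            mfd_um=common.get("mfd_um", 20.0),
            min_extent_um=common.get("min_extent_um", 10.0),
            aspect_ratio=common.get("aspect_ratio", 0.5),
            mean_absorption_per_cm=common.get("mean_absorption_per_cm", 20.0),
        ))
    return records
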
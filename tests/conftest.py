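import numpy as np
import pytest

import embryograd as eg


@pytest.fixture(scope="session")
def wt_scene():
    """Noise-free wild-type-like surface scene (NC12 defaults)."""
    cfg = eg.SceneConfig(nc_stage="NC12", seed=11)
    return eg.render_embryo(cfg)


@pytest.fixture(scope="session")
def sagittal_scene():
    cfg = eg.SceneConfig(nc_stage="NC12", view="sagittal", seed=11)
    return eg.render_embryo(cfg)


def ap_ztsh2_profile(scene, truth, **kwargs):
    """Standard receptor-channel pipeline up to background subtraction."""
    prof = eg.ap_line_profile(
        scene, truth.geometry, channel="ztsh2", exclude_mask=truth.exclusion_mask(), **kwargs
    )
    return eg.subtract_center_background(prof)


def make_profile(values, **kwargs):
    return eg.BinnedProfile(values=np.asarray(values, dtype=float), **kwargs)
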
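import numpy as np
import pytest
from hypothesis import settings

from coarckit import hemodynamics as hd
from coarckit import io as ckio
from coarckit.arch_synth import ArchParams, build_arch, voxelize

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: gothic arch at the published group means (A/T, chord angles, Di/AOA)
GOTHIC_MEAN = dict(
    arch_type="gothic", height_A=0.70148 * 36.0, width_T=36.0,
    aao_dao_angle=26.74, tao_dao_angle=109.81,
    level_diameters={"AOA": 12.0, "D1": 7.56, "D2": 6.41, "D3": 3.48,
                     "D4": 8.52, "D5": 7.70})


@pytest.fixture(scope="session")
def gothic_mean_arch():
    return build_arch(ArchParams(**GOTHIC_MEAN))


@pytest.fixture(scope="session")
def gothic_voxel_case(gothic_mean_arch):
    """0.4 mm voxelization of the gothic mean arch + extracted centerline."""
    from coarckit.morphometry import extract_centerline

    mask = voxelize(gothic_mean_arch, 0.4)
    return mask, extract_centerline(mask)


@pytest.fixture(scope="session")
def published_cohort():
    return ckio.load_published_cohort()


@pytest.fixture(scope="session")
def calibrated_case():
    """Default gothic network calibrated to the 57.2 mmHg Doppler PSPG."""
    return hd.calibrate_stenosis(hd.default_coa_network(), target_pspg=57.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230627)
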
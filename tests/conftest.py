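import numpy as np
import pytest

from trendkit import CTVolume, MaskSet, StructureMask
from trendkit.phantom_fixtures import EllipsoidSpec, PhantomSpec, StructureChange


def make_ct(values, affine=None, patient_id="p1", condition="pre"):
    values = np.asarray(values, dtype=float)
    if affine is None:
        affine = np.eye(4)
    return CTVolume(voxels=values, affine=affine, patient_id=patient_id, condition=condition)


def make_mask(values, name="mask"):
    return StructureMask(voxels=np.asarray(values), structure_name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ramp_ct():
    """A 20x20x20 volume whose HU values sweep -300..+299 along one axis pattern."""
    vals = np.arange(-300, 300, dtype=float)[:400]
    grid = np.resize(np.arange(-300, 300, dtype=float), 20 * 20 * 20).reshape(20, 20, 20)
    return make_ct(grid)


@pytest.fixture
def cohort_base_spec():
    """Two-structure phantom: a C3 body region plus an anatomical 'lesion'."""
    return PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing_mm=(1.0, 1.0, 1.0),
        structures=(
            EllipsoidSpec(name="C3", center=(24, 24, 24), semi_axes=(10, 10, 10),
                          hu_mean=-20.0, hu_sd=40.0),
            EllipsoidSpec(name="lesion", center=(7, 7, 7), semi_axes=(4, 4, 4),
                          hu_mean=50.0, hu_sd=5.0),
        ),
        background_hu=-1000.0,
        seed=7,
    )


@pytest.fixture
def cohort_change():
    return {
        "C3": StructureChange(volume_change_pct=-15.0, hu_shift=-10.0),
        "lesion": StructureChange(),
    }


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory):
    """A 2-patient paired phantom cohort written in the CLI's input layout."""
    from trendkit.phantom_fixtures import write_paired_cohort

    base = PhantomSpec(
        grid_shape=(40, 40, 40),
        structures=(
            EllipsoidSpec(name="C3", center=(24, 24, 24), semi_axes=(10, 10, 10),
                          hu_mean=-20.0, hu_sd=40.0),
            EllipsoidSpec(name="lesion", center=(7, 7, 7), semi_axes=(4, 4, 4),
                          hu_mean=50.0, hu_sd=5.0),
        ),
        seed=7,
    )
    change = {"C3": StructureChange(volume_change_pct=-15.0, hu_shift=-10.0)}
    root = tmp_path_factory.mktemp("cohort")
    layout = write_paired_cohort(root, base, change, n_patients=2, seed=11)
    return layout
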
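import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


TOY_PDB_2MODEL = """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       0.000   0.000   1.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.500   0.000   1.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   1.000  1.00  0.00           C
ENDMDL
END
"""

TOY_PDB_ALTLOC = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AGLY A   1       1.500   0.000   0.000  0.60  0.00           C
ATOM      3  CA BGLY A   1       1.700   0.000   0.000  0.40  0.00           C
ATOM      4  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""

TOY_PDB_INSCODE = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1A      1.500   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""


@pytest.fixture(scope="session")
def toy_pdb_text():
    return TOY_PDB_2MODEL


@pytest.fixture(scope="session")
def apo_small():
    """Small apo-preset ensemble reused across tests (seed fixed)."""
    from mntrdyn.synthdata import generate_ensemble, preset_params

    return generate_ensemble(preset_params("apo", n_frames=150, seed=101))


@pytest.fixture(scope="session")
def mn_small():
    from mntrdyn.synthdata import generate_ensemble, preset_params

    return generate_ensemble(preset_params("mn", n_frames=150, seed=102))


@pytest.fixture(scope="session")
def apo_3000():
    """Apo preset at the sample size used for distribution-recovery checks."""
    from mntrdyn.synthdata import generate_ensemble, preset_params

    return generate_ensemble(preset_params("apo", n_frames=3000, seed=1))


@pytest.fixture(scope="session")
def mn_3000():
    from mntrdyn.synthdata import generate_ensemble, preset_params

    return generate_ensemble(preset_params("mn", n_frames=3000, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t
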
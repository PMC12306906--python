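import numpy as np
import pytest

import osteovox as ov


@pytest.fixture(scope="session")
def db():
    return ov.default_db()


@pytest.fixture(scope="session")
def densities(db):
    return db.densities


@pytest.fixture()
def small_cube():
    """5 mm marrow cube at 0.1 mm voxels."""
    return ov.voxelize(ov.ShapeDef("box", {"a": 5, "b": 5, "c": 5}), 0.1)


def lattice_membership_oracle(shape, voxel_mm, t, p):
    """Brute-force voxel-centre membership of the undeformed rod lattice.

    Independent of the rasteriser: a centre is bone iff at least two of its
    coordinates lie within t/2 of a lattice plane (multiples of p).
    """
    cs = [(np.arange(n) + 0.5) * voxel_mm for n in shape]

    def near(c):
        return np.abs(c - np.round(c / p) * p) < t / 2

    nx = near(cs[0])[:, None, None]
    ny = near(cs[1])[None, :, None]
    nz = near(cs[2])[None, None, :]
    return (nx & ny) | (nx & nz) | (ny & nz)
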
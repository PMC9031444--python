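import numpy as np
import pytest

from breastdro.grid import VoxelGrid
from breastdro.mri import ScanProtocol
from breastdro.phantom import PhantomSpec, generate_breast_phantom


@pytest.fixture(scope="session")
def grid():
    return VoxelGrid((64, 64, 32), (160.0, 160.0, 64.0))


@pytest.fixture(scope="session")
def phantom(grid):
    """One shared desk-scale phantom; tests must not mutate it."""
    return generate_breast_phantom(PhantomSpec(grid=grid, seed=7))


@pytest.fixture()
def fresh_phantom(grid):
    """A private phantom copy for tests that mutate the anatomy."""
    return generate_breast_phantom(PhantomSpec(grid=grid, seed=7))


@pytest.fixture(scope="session")
def protocol():
    return ScanProtocol(field_strength_T=1.5, tr_ms=7.8, flip_deg=10.0, te_ms=(2.2,))


def bloch_spgr_steady_state(flip_deg, tr_ms, t1_ms, tol=1e-12, max_iter=200000):
    """Independent SPGR oracle: iterate Mz' = 1 + (Mz cos(a) - 1) e^(-TR/T1)
    to convergence and return Mz sin(a)."""
    a = np.deg2rad(flip_deg)
    e = np.exp(-tr_ms / t1_ms)
    mz = 1.0
    for _ in range(max_iter):
        nxt = 1.0 + (mz * np.cos(a) - 1.0) * e
        if abs(nxt - mz) < tol:
            mz = nxt
            break
        mz = nxt
    return mz * np.sin(a)
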
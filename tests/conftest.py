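import warnings

import numpy as np
import pytest

import fvforge as fx
from fvforge import synthetic as syn


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def defs():
    return fx.CdrDefinitionTable.load("north")


@pytest.fixture(scope="session")
def ideal_fv():
    return syn.make_idealized_fv(seed=1)


@pytest.fixture(scope="session")
def family():
    """Small synthetic template family with recorded ground truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        members, truth = syn.make_template_family(
            syn.FixtureSpec(n_structures=10, seed=7))
    return members, truth


@pytest.fixture(scope="session")
def store(family):
    members, _truth = family
    return fx.build_template_store(members)


@pytest.fixture(scope="session")
def fragment_stores(family):
    members, _truth = family
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fx.build_fragment_stores(members)


@pytest.fixture(scope="session")
def rotamer_library():
    return fx.RotamerLibrary.load()


@pytest.fixture(scope="session")
def vdw_table():
    return fx.VdwRadiusTable()


def quaternion_superpose(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent rigid-fit RMSD via the Horn quaternion eigenvalue method."""
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    x = mobile - mobile.mean(axis=0)
    y = reference - reference.mean(axis=0)
    s = x.T @ y
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k)[-1]
    sq = max((x ** 2).sum() + (y ** 2).sum() - 2.0 * lam, 0.0)
    return float(np.sqrt(sq / len(mobile)))
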
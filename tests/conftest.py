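import numpy as np
import pytest

import picsfit as pf


def bisect_root(f, lo, hi, iters=200):
    """Hand-rolled bisection, independent of scipy, for oracle checks."""
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


@pytest.fixture(scope="session")
def proteome100():
    """100-protein random proteome, the standard screen-scale fixture."""
    return pf.generate_proteome(100, (200, 400), seed=1)


@pytest.fixture(scope="session")
def tryptic_library(proteome100):
    return pf.digest_proteome(proteome100, pf.TRYPSIN)


@pytest.fixture(scope="session")
def planted_f_protease():
    """Strict P1 = F specificity, fully efficient."""
    return pf.ProteaseSpec(preference={"P1": {"F": 1.0}}, efficiency=1.0)


@pytest.fixture(scope="session")
def noiseless():
    return pf.NoiseSettings(n_background=0)


@pytest.fixture(scope="session")
def noisy():
    return pf.NoiseSettings(n_background=200)


@pytest.fixture
def rvp_uba_protocol():
    """Printed single-site titration protocol: 9 uL x 30 of 796 uM ligand
    into 1.43 mL of 64.8 uM protein."""
    return pf.InjectionProtocol.uniform(30, 9.0, 1.43, 64.8, 796.0)


@pytest.fixture
def full_length_protocol():
    """Printed full-length titration protocol: 1.42 mM ligand into 97 uM cell."""
    return pf.InjectionProtocol.uniform(30, 9.0, 1.43, 97.0, 1420.0)
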
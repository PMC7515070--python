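import numpy as np
import pytest

import mfhrv as M


@pytest.fixture(scope="session")
def qgrid():
    return M.QGrid()


@pytest.fixture(scope="session")
def binom_spec():
    """Deterministic binomial cascade (0.6, 0.4), 16 levels."""
    return M.CascadeSpec(base=2, weights=(0.6, 0.4), levels=16)


@pytest.fixture(scope="session")
def binom_measure(binom_spec):
    return M.make_cascade(binom_spec)


@pytest.fixture(scope="session")
def binom_spectrum(binom_measure):
    """Estimated spectrum of the binomial cascade on the default grid."""
    return M.compute_spectrum(binom_measure, source_id="binomial-0.6")


@pytest.fixture(scope="session")
def binom_analytic(binom_spec, qgrid):
    return M.analytic_spectrum(binom_spec, qgrid)


@pytest.fixture(scope="session")
def trinom_spec():
    """Asymmetric trinomial cascade (0.5, 0.3, 0.2), base 3."""
    return M.CascadeSpec(base=3, weights=(0.5, 0.3, 0.2), levels=9)


@pytest.fixture(scope="session")
def trinom_spectrum(trinom_spec):
    return M.compute_spectrum(M.make_cascade(trinom_spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def write_rr(path, values, meta=None):
    """Write an RR file (and optional sidecar) for I/O tests."""
    with open(path, "w") as fh:
        for v in values:
            fh.write(f"{v}\n")
    if meta is not None:
        with open(str(path) + ".meta", "w") as fh:
            fh.write(meta)
    return path
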
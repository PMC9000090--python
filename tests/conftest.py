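import numpy as np
import pytest

from actogel.gel1d import Field1D, GelParams
from actogel.kinetics import ChemistryParams
from actogel.local_model import LocalMechanicsParams


@pytest.fixture
def chem() -> ChemistryParams:
    return ChemistryParams()


@pytest.fixture
def mech() -> LocalMechanicsParams:
    return LocalMechanicsParams()


@pytest.fixture
def gel() -> GelParams:
    return GelParams()


def empty_cortex_1d(gp: GelParams, seed: int = 0, trace: float = 1e-4) -> Field1D:
    """Bare-cortex 1D start: trace RhoA noise, no actomyosin, no flow."""
    rng = np.random.default_rng(seed)
    return Field1D(
        x=gp.grid(),
        r=trace * np.abs(rng.standard_normal(gp.N)),
        m=np.zeros(gp.N),
        v=np.zeros(gp.N),
    )


def rho_bump_1d(gp: GelParams, p: ChemistryParams, amp: float = 0.5,
                centers=(0.5,), width: float | None = None) -> Field1D:
    """Low homogeneous state plus localized RhoA bump(s) to trigger a pulse."""
    from actogel.gel1d import initial_field_1d

    f = initial_field_1d(gp, p, seed=0, noise_amplitude=0.0)
    w = width if width is not None else gp.lam / 4
    for c in centers:
        f.r = f.r + amp * np.exp(-0.5 * ((f.x - c * gp.L) / w) ** 2)
    return f
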
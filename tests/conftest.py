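"""Shared fixtures: heavy simulation results are session-scoped so the
module tests and the acceptance suite measure the same runs."""

from __future__ import annotations

import numpy as np
import pytest

from tavrom import circulation as circ
from tavrom import hgo, ib2d, stent


@pytest.fixture(scope="session")
def porcine():
    return hgo.PORCINE_PERICARDIUM


@pytest.fixture(scope="session")
def native():
    return hgo.NATIVE_LEAFLET


@pytest.fixture(scope="session")
def rom_default():
    """Closed-loop run with the shipped parameter set and the 1.50 cm^2
    orifice surrogate, at the standard settings (RK4, dt = 1e-4 s,
    20-cycle cap, 0.5 mmHg cycle-to-cycle tolerance)."""
    return circ.CirculationModel().simulate()


@pytest.fixture(scope="session")
def rom_tight():
    """Tightly converged periodic orbit (0.02 mmHg cycle-to-cycle residual)
    for invariants that hold only on the exact periodic solution."""
    return circ.CirculationModel().simulate(n_cycles=60,
                                            convergence_tol_mmHg=0.02)


@pytest.fixture(scope="session")
def small_frame():
    return stent.synthesize_frame(n_circumferential=8, n_rows=3,
                                  diameter_mm=26.0, height_mm=30.0)


@pytest.fixture(scope="session")
def crimped_expanded():
    """Full crimp of the 26 mm lattice to the capsule scale (17.25 Fr
    commanded) followed by release and self-expansion."""
    frame = stent.synthesize_frame()
    crimper = stent.Crimper(stop_radius_cm=17.25 / 3.0 / 20.0)
    crimped = stent.crimp(frame, crimper)
    expanded = stent.release_and_expand(crimped.frame, t_max_s=30.0)
    return frame, crimped, expanded


@pytest.fixture(scope="session")
def ring_result():
    return ib2d.demo_elastic_ring()


@pytest.fixture(scope="session")
def leaflet_results():
    """Pressurized-leaflet channel demo: closed-valve run plus the open
    channel at the same driving gradient."""
    open_ch = ib2d.demo_pressurized_leaflets(with_leaflets=False, t_end=0.4)
    closed = ib2d.demo_pressurized_leaflets(t_end=0.4)
    return open_ch, closed


@pytest.fixture(scope="session")
def poiseuille():
    """Open-channel flux at two resolutions with Richardson extrapolation."""
    return ib2d.poiseuille_verification()


@pytest.fixture(scope="session")
def taylor_green():
    return ib2d.taylor_green_error()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)
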
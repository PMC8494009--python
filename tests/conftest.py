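"""Shared fixtures: the heavier simulation movies are built once per session."""

import warnings

import numpy as np
import pytest

from phasedefect import (Movie, get_kinetics, hilbert_phase, lat_series,
                         arrival_phase_series, make_fixture)


@pytest.fixture(scope="session")
def fk_rotor():
    """Sustained linear-core rotor (FK MLR-I), S1-S2 initiated."""
    return make_fixture("fk_linear_rotor")


@pytest.fixture(scope="session")
def fk_rotor_windowed(fk_rotor):
    """Rotor movie cropped to start just before S2, with LAT bookkeeping
    restarted there (the induction-episode analysis regime), plus the
    arrival-time phase and the Hilbert phase of the cropped segment."""
    t_s2 = fk_rotor.meta["t_s2"]
    rec = fk_rotor.dt_frame
    k0 = int(round((t_s2 - 2 * rec) / rec))
    sub = Movie(V=fk_rotor.V[k0:], R=fk_rotor.R[k0:], dt_frame=rec,
                dx=fk_rotor.dx, meta=dict(fk_rotor.meta, t_offset=k0 * rec))
    kin = get_kinetics("fk", "mlr1")
    lat = lat_series(sub, kin.V_star)
    parr = arrival_phase_series(sub, float(kin.defaults["tau"]), kin.V_star)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        phih = hilbert_phase(sub)
    return {"movie": sub, "lat": lat, "phi_arr": parr, "phi_hilbert": phih,
            "kin": kin, "t_s2_rel": 2 * rec}


@pytest.fixture(scope="session")
def ap_rotor():
    """S1-S2 initiated circular-core spiral (Aliev-Panfilov)."""
    return make_fixture("ap_circular_rotor")


@pytest.fixture(scope="session")
def bocf_block():
    """BOCF S1-S2 run with unidirectional conduction block."""
    return make_fixture("s1s2_block")


@pytest.fixture(scope="session")
def scroll3d():
    """Reduced 3D FK-MBR slab with a transmural block surface."""
    return make_fixture("fk_scroll_3d_small")


@pytest.fixture(scope="session")
def sinusoid():
    return make_fixture("sinusoid_movie")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
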
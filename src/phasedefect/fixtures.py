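"""Canned simulation scenarios used throughout the test suite and docs.

Each fixture is a deterministic movie produced by the monodomain
simulator (or, for ``sinusoid_movie``, analytically):

* ``ap_circular_rotor`` -- S1-S2 cross-field initiation of a rigidly
  rotating spiral with a circular core (Aliev-Panfilov kinetics).  The
  premature S2 quadrant blocks against the S1 refractory tail, forming
  a conduction block line that heals into a single phase singularity.
* ``fk_linear_rotor`` -- S1-S2 initiation of a sustained linear-core
  rotor (Fenton-Karma MLR-I), whose core is a phase defect line on
  which detected phase singularities reside.
* ``bocf_linear_rotor`` -- S1-S2 block and turning wave in the minimal
  human ventricular model (EPI set).  The reduced domain is far smaller
  than this model's wavelength, so reentry is not sustained; the
  fixture captures the initiation phase: an extended conduction block
  line around whose endpoints the wave turns, with no phase singularity
  at the free end (the hallmark of a linear-core medium).
* ``s1s2_block`` -- a shorter BOCF S1-S2 run showing unidirectional
  block and the resulting conduction block line.
* ``fk_scroll_3d_small`` -- a reduced 3D slab (FK MBR) in which a
  half-wall-thickness S2 undergoes transmural block, forming a phase
  defect surface that intersects the bottom (epicardial-view) surface.
* ``sinusoid_movie`` -- analytic ``V = 0.5 + 0.4*sin(2*pi*f*t)`` for
  frequency / Hilbert-phase tests.

Grids are reduced and (for FK/BOCF) coarsened to dx = 0.5 mm relative
to published full-scale simulations to keep runtimes short; the Euler
step keeps the diffusion stability bound satisfied.  S2 onset times
were placed once per kinetics just after the S1 wave back clears the
S2 quadrant boundary, so the S2 wave blocks unidirectionally in the
refractory tail; they are recorded in ``movie.meta['t_s2']``.
"""

from __future__ import annotations

import numpy as np

from .kinetics import get_kinetics
from .movie import Movie
from .simulate import Grid, Protocol, Stimulus, run

__all__ = ["FIXTURE_NAMES", "make_fixture", "random_phase_field",
           "straddle_field"]

FIXTURE_NAMES = (
    "ap_circular_rotor",
    "fk_linear_rotor",
    "bocf_linear_rotor",
    "s1s2_block",
    "fk_scroll_3d_small",
    "sinusoid_movie",
)


def _edge_mask(shape, width: int) -> np.ndarray:
    """Strip of the first ``width`` columns (S1 plane-wave electrode)."""
    m = np.zeros(shape, dtype=bool)
    m[:, :width] = True
    return m


def _quadrant_mask(shape, y_half: str = "lower", x_half: str = "left") -> np.ndarray:
    """One quadrant of a 2D grid (S2 cross-field electrode)."""
    ny, nx = shape[:2]
    m = np.zeros(shape, dtype=bool)
    ys = slice(0, ny // 2) if y_half == "upper" else slice(ny // 2, None)
    xs = slice(0, nx // 2) if x_half == "left" else slice(nx // 2, None)
    m[ys, xs] = True
    return m


def _s1s2_fixture(name, model, param_set, nx, ny, dx, dt, t_s2, stim_dur,
                  duration, record_every, seed):
    kin = get_kinetics(model, param_set)
    grid = Grid(nx=nx, ny=ny, dx=dx, dt=dt)
    shape = grid.spatial_shape
    protocol = Protocol([
        Stimulus(t_on=0.0, duration=stim_dur, mask=_edge_mask(shape, 3)),
        Stimulus(t_on=t_s2, duration=stim_dur, mask=_quadrant_mask(shape)),
    ])
    movie = run(kin, grid, protocol, duration, record_every=record_every)
    movie.meta.update(fixture=name, seed=seed, t_s2=t_s2)
    return movie


def make_fixture(name: str, seed: int = 0) -> Movie:
    """Build a named fixture movie; deterministic for given arguments."""
    if name == "sinusoid_movie":
        return _sinusoid_movie(seed)
    if name == "ap_circular_rotor":
        return _s1s2_fixture(name, "ap", "standard", nx=100, ny=100,
                             dx=0.5, dt=0.0029, t_s2=44.0, stim_dur=0.5,
                             duration=100.0, record_every=0.5, seed=seed)
    if name == "fk_linear_rotor":
        return _s1s2_fixture(name, "fk", "mlr1", nx=150, ny=150,
                             dx=0.5, dt=0.16, t_s2=280.0, stim_dur=2.0,
                             duration=700.0, record_every=1.6, seed=seed)
    if name == "bocf_linear_rotor":
        return _s1s2_fixture(name, "bocf", "epi", nx=120, ny=120,
                             dx=0.5, dt=0.1, t_s2=330.0, stim_dur=2.0,
                             duration=550.0, record_every=5.0, seed=seed)
    if name == "s1s2_block":
        return _s1s2_fixture(name, "bocf", "epi", nx=100, ny=100,
                             dx=0.5, dt=0.1, t_s2=325.0, stim_dur=2.0,
                             duration=450.0, record_every=5.0, seed=seed)
    if name == "fk_scroll_3d_small":
        kin = get_kinetics("fk", "mbr")
        grid = Grid(nx=48, ny=48, nz=8, dx=0.31, dt=0.1)
        shape = grid.spatial_shape
        s1 = np.zeros(shape, dtype=bool)
        s1[:, :3, :] = True
        s2 = np.zeros(shape, dtype=bool)
        s2[24:, :24, :4] = True  # half wall thickness: transmural block
        protocol = Protocol([Stimulus(0.0, 2.0, s1), Stimulus(160.0, 2.0, s2)])
        movie = run(kin, grid, protocol, duration=210.0, record_every=1.6)
        movie.meta.update(fixture=name, seed=seed, t_s2=160.0)
        return movie
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def random_phase_field(
    rng: np.random.Generator,
    shape: tuple[int, int] = (24, 24),
    n_vortices: int | None = None,
    smooth_modes: int = 3,
    max_smooth_grad: float = 0.3,
) -> tuple[np.ndarray, list[tuple[float, float, int]]]:
    """Random smooth-plus-vortex phase field with known topological charges.

    The field is the sum of ``n_vortices`` point-vortex angle fields
    ``charge * atan2(y - yv, x - xv)`` and a smooth low-order Fourier
    perturbation whose per-pixel gradient is bounded by
    ``max_smooth_grad``.  Vortex centres are kept at least 4 px apart,
    at least 2 px inside the border, and away from integer coordinates,
    so each vortex charges exactly one grid-cell corner and no corner
    sees more than one super-pi cyclic difference.

    Returns
    -------
    phi : ndarray
        Wrapped phase field in ``[-pi, pi)``.
    vortices : list of (y, x, charge)
        Continuous vortex positions and their winding charges.
    """
    ny, nx = shape
    if n_vortices is None:
        n_vortices = int(rng.integers(0, 4))
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    phi = np.zeros(shape)
    vortices: list[tuple[float, float, int]] = []
    tries = 0
    while len(vortices) < n_vortices and tries < 200:
        tries += 1
        yv = rng.uniform(2.2, ny - 3.2) + rng.uniform(0.2, 0.8)
        xv = rng.uniform(2.2, nx - 3.2) + rng.uniform(0.2, 0.8)
        if any(max(abs(yv - y0), abs(xv - x0)) < 4.0 for y0, x0, _ in vortices):
            continue
        charge = int(rng.choice([-1, 1]))
        vortices.append((yv, xv, charge))
        phi += charge * np.arctan2(yy - yv, xx - xv)
    for _ in range(smooth_modes):
        ky, kx = rng.uniform(-1.0, 1.0, size=2) * 2.0 * np.pi / max(ny, nx)
        amp = rng.uniform(0, max_smooth_grad / (abs(ky) + abs(kx) + 1e-9))
        phi += amp * np.cos(ky * yy + kx * xx + rng.uniform(0, 2 * np.pi))
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi, vortices


def straddle_field(
    rng: np.random.Generator, shape: tuple[int, int] = (24, 24)
) -> np.ndarray:
    """Two-region field with a super-pi step and zero winding everywhere.

    Emulates a plaquette straddling a phase defect line: the raw jump
    across the (randomly oriented) straight interface exceeds pi but is
    not a multiple of 2*pi, so every straddling 2x2 ring has exactly two
    large cyclic differences and no topological charge.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    theta = rng.uniform(0, np.pi)
    c = rng.uniform(0.3, 0.7)
    side = (np.cos(theta) * (xx / nx - c) + np.sin(theta) * (yy / ny - c)) > 0
    # two stored values in [-pi, pi) whose raw difference exceeds pi
    jump = rng.uniform(np.pi + 0.1, 1.9 * np.pi)
    lo = rng.uniform(-np.pi, np.pi - jump - 0.05)
    if rng.random() < 0.5:
        side = ~side
    return np.where(side, lo + jump, lo)


def _sinusoid_movie(seed: int, f: float = 0.02, n_frames: int = 1000,
                    shape=(20, 20), dt_frame: float = 1.0) -> Movie:
    """Analytic sinusoid ``V = 0.5 + 0.4*sin(2*pi*f*t)``.

    Defaults emulate a 20 Hz signal sampled at 1 kHz (time unit ms,
    ``f = 0.02`` cycles/ms).
    """
    t = dt_frame * np.arange(n_frames)
    trace = 0.5 + 0.4 * np.sin(2.0 * np.pi * f * t)
    V = np.broadcast_to(trace[:, None, None], (n_frames, *shape)).copy()
    return Movie(V=V, dt_frame=dt_frame, dx=1.0,
                 meta={"fixture": "sinusoid_movie", "seed": seed,
                       "frequency": f, "kinetics": "analytic"})
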
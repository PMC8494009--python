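"""Monodomain reaction-diffusion simulator.

Solves ``du/dt = P * Laplacian(u) + F(u)`` with explicit Euler stepping on a
regular 2D or 3D grid.  Only the first (voltage-like) state variable
diffuses; boundaries are no-flux (mirrored ghost nodes).  Stimulation is
expressed as a :class:`Protocol` of clamps of the voltage variable over
spatial masks, which covers S1-S2 cross-field and premature-stimulus
block scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import Kinetics
from .movie import Movie

__all__ = [
    "Grid",
    "Stimulus",
    "Protocol",
    "step_euler",
    "run",
    "cable_front_speed",
    "front_crossing_times",
]


@dataclass(frozen=True)
class Grid:
    """Regular simulation grid with explicit-Euler step size.

    ``nz is None`` selects a 2D sheet.  The explicit diffusion stability
    bound ``dt < dx**2 / (2 * dim * P11)`` is checked against the
    kinetics when a simulation starts.
    """

    nx: int
    ny: int
    dx: float
    dt: float
    nz: int | None = None

    def __post_init__(self):
        if min(self.nx, self.ny) < 3 or (self.nz is not None and self.nz < 3):
            raise ValueError("grid must be at least 3 pixels in every dimension")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")

    @property
    def dim(self) -> int:
        return 2 if self.nz is None else 3

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        # (y, x) or (y, x, z), matching movie frame layout
        return (self.ny, self.nx) if self.nz is None else (self.ny, self.nx, self.nz)

    def check_stability(self, P11: float) -> None:
        if P11 > 0:
            bound = self.dx**2 / (2.0 * self.dim * P11)
            if self.dt >= bound:
                raise ValueError(
                    f"dt={self.dt:g} violates the explicit-Euler diffusion "
                    f"stability bound dt < dx^2/(2*dim*P11) = {bound:g}"
                )


@dataclass(frozen=True)
class Stimulus:
    """Clamp of the voltage variable over a spatial mask.

    The first state variable is held at ``value`` on ``mask`` for
    ``t_on <= t < t_on + duration``.
    """

    t_on: float
    duration: float
    mask: np.ndarray
    value: float = 1.0

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_on + self.duration


@dataclass
class Protocol:
    """Ordered list of stimuli; onsets must be non-decreasing."""

    stimuli: list[Stimulus] = field(default_factory=list)

    def __post_init__(self):
        onsets = [s.t_on for s in self.stimuli]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onset times must be non-decreasing")

    def validate(self, grid: Grid) -> None:
        for s in self.stimuli:
            if s.mask.shape != grid.spatial_shape:
                raise ValueError(
                    f"stimulus mask shape {s.mask.shape} does not match "
                    f"grid {grid.spatial_shape}"
                )

    def apply(self, state: np.ndarray, t: float) -> None:
        for s in self.stimuli:
            if s.active(t):
                state[0][s.mask] = s.value


def _laplacian(u: np.ndarray, dx: float) -> np.ndarray:
    """5-point (2D) / 7-point (3D) Laplacian with no-flux boundaries."""
    p = np.pad(u, 1, mode="edge")
    if u.ndim == 2:
        lap = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
               - 4.0 * u)
    else:
        lap = (p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
               + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
               + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:]
               - 6.0 * u)
    return lap / dx**2


def step_euler(state: np.ndarray, kinetics: Kinetics, grid: Grid) -> np.ndarray:
    """Advance the state one explicit-Euler step.

    Parameters
    ----------
    state : ndarray, shape (m, ny, nx[, nz])
        Current state; must be finite.
    """
    new = state + grid.dt * kinetics.reaction(state)
    new[0] += grid.dt * kinetics.P11 * _laplacian(state[0], grid.dx)
    return new


def run(
    kinetics: Kinetics,
    grid: Grid,
    protocol: Protocol,
    duration: float,
    record_every: float | None = None,
    initial: np.ndarray | None = None,
    record_R: bool = True,
) -> Movie:
    """Integrate the monodomain model and record a movie.

    Frames (the ``V`` observable, and ``R`` unless ``record_R=False``)
    are recorded every ``record_every`` time units (default: the model's
    LAT frame interval ``dt_lat``).  The run is deterministic: identical
    inputs give bit-identical movies.

    Raises
    ------
    FloatingPointError
        On numerical blow-up (non-finite state), reporting the step index.
    """
    grid.check_stability(kinetics.P11)
    protocol.validate(grid)
    if record_every is None:
        record_every = float(kinetics.defaults["dt_lat"])
    if record_every < grid.dt:
        raise ValueError("record_every must be at least one Euler step dt")

    n_steps = int(round(duration / grid.dt))
    rec_steps = max(1, int(round(record_every / grid.dt)))

    if initial is None:
        state = np.empty((kinetics.m, *grid.spatial_shape))
        state[:] = kinetics.rest_state.reshape((kinetics.m,) + (1,) * grid.dim)
    else:
        state = np.array(initial, dtype=float)
        if state.shape != (kinetics.m, *grid.spatial_shape):
            raise ValueError("initial state shape mismatch")

    frames_V: list[np.ndarray] = []
    frames_R: list[np.ndarray] = []
    for step in range(n_steps + 1):
        t = step * grid.dt
        protocol.apply(state, t)
        if step % rec_steps == 0:
            if not np.all(np.isfinite(state)):
                raise FloatingPointError(f"numerical blow-up at step {step}")
            V, R = kinetics.observables(state)
            frames_V.append(V.copy())
            if record_R:
                frames_R.append(np.asarray(R).copy())
        if step < n_steps:
            state = step_euler(state, kinetics, grid)

    V = np.stack(frames_V)
    R = np.stack(frames_R) if record_R else None
    movie = Movie(
        V=V,
        R=R,
        dt_frame=rec_steps * grid.dt,
        dx=grid.dx,
        meta={
            "kinetics": kinetics.name,
            "param_set": kinetics.param_set,
            "duration": duration,
            "n_stimuli": len(protocol.stimuli),
        },
    )
    movie.meta["final_state"] = state
    v_star = kinetics.V_star
    crossed = np.any((V[:-1] < v_star) & (V[1:] >= v_star)) if len(V) > 1 else False
    if not crossed:
        warnings.warn(
            f"dead run: no pixel ever crossed V_star={v_star:g}", RuntimeWarning,
            stacklevel=2,
        )
    return movie


# ---------------------------------------------------------------------------
# Conduction-velocity measurement helpers


def front_crossing_times(
    trace: np.ndarray, times: np.ndarray, v_star: float
) -> np.ndarray:
    """Sub-frame times of upward crossings of ``v_star`` in a single trace.

    Linear interpolation between the bracketing frames.
    """
    trace = np.asarray(trace, float)
    idx = np.nonzero((trace[:-1] < v_star) & (trace[1:] >= v_star))[0]
    frac = (v_star - trace[idx]) / (trace[idx + 1] - trace[idx])
    return times[idx] + frac * (times[idx + 1] - times[idx])


def cable_front_speed(
    kinetics: Kinetics,
    dx: float | None = None,
    dt: float | None = None,
    length: float | None = None,
    stim_width: float = 2.0,
) -> float:
    """Plane-wave conduction velocity from a 1D cable simulation.

    An independently coded fine-grid cable integrator: a single row of
    tissue is stimulated at one end and the front passage time is
    interpolated at two probes in the middle stretch of the cable.  By
    default the spatial step is half the model's 2D default and the
    cable is long enough for the front to reach a steady shape.

    Returns
    -------
    float
        Front speed in model space/time units.
    """
    dx = dx if dx is not None else float(kinetics.defaults["dx"]) / 2.0
    dt = dt if dt is not None else min(float(kinetics.defaults["dt"]),
                                       0.4 * dx**2 / (2.0 * kinetics.P11))
    if length is None:
        length = 80.0 * float(kinetics.defaults["dx"])
    n = int(round(length / dx))
    state = np.tile(kinetics.rest_state[:, None], (1, n))
    v_star = kinetics.V_star
    n_stim = max(2, int(round(stim_width / dx)))

    i1, i2 = int(0.45 * n), int(0.75 * n)
    t_hit = {i1: None, i2: None}
    prev_u = state[0].copy()
    inv_dx2 = kinetics.P11 / dx**2
    t = 0.0
    max_steps = int(5e6)
    for step in range(max_steps):
        u = state[0]
        for i, hit in t_hit.items():
            if hit is None and prev_u[i] < v_star <= u[i]:
                frac = (v_star - prev_u[i]) / (u[i] - prev_u[i])
                t_hit[i] = t - dt + frac * dt
        if all(v is not None for v in t_hit.values()):
            break
        prev_u = u.copy()
        deriv = kinetics.reaction(state)
        lap = np.empty_like(u)
        lap[1:-1] = u[:-2] + u[2:] - 2.0 * u[1:-1]
        lap[0] = 2.0 * (u[1] - u[0])        # no-flux ghost
        lap[-1] = 2.0 * (u[-2] - u[-1])
        state = state + dt * deriv
        state[0] += dt * inv_dx2 * lap
        t += dt
        if t < 2.0 * float(kinetics.defaults["dt_lat"]):
            state[0, :n_stim] = 1.0
    else:
        raise RuntimeError("front never reached the distal probe")
    return (i2 - i1) * dx / (t_hit[i2] - t_hit[i1])
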
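"""Phase constructions for excitation movies.

Three phases are supported, all stored in ``[-pi, pi)`` with ``NaN``
marking undefined pixels (background, never-activated, or degenerate):

* the *activation phase* ``phi_act = atan2(R - R_star, V - V_star) + b``,
  the polar angle of the state around a reference point inside the
  action-potential cycle in the ``(V, R)`` plane;
* the *Hilbert phase*, the analytic-signal angle of the mean-subtracted
  voltage trace, for single-observable (optical) recordings;
* the *arrival-time phase* ``phi_arr = 2*pi*tanh(3*t_elapsed/tau)``, a
  saturating transform of the time elapsed since the most recent local
  activation.  Because freshly excited and fully recovered tissue both
  map near phase 0 (mod 2*pi), wave fronts and wave backs are invisible
  to ``phi_arr``; only conduction block lines remain as phase defects.

The module also provides local-activation-time (LAT) bookkeeping, the
wrapped phase gradient, the mean upstroke/downstroke phase levels, wave
front / wave back extraction, and the diffusive boundary-layer estimate
of the phase-defect thickness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert as _hilbert

from .movie import Movie

__all__ = [
    "unwrap",
    "wrap",
    "activation_phase",
    "hilbert_phase",
    "update_lat",
    "lat_series",
    "elapsed_time",
    "arrival_phase",
    "arrival_phase_series",
    "phase_gradient",
    "PhaseLevels",
    "phase_levels",
    "FrontSet",
    "fronts",
    "defect_thickness",
]


def unwrap(x):
    """Map an angle difference to its representative in ``[-pi, pi)``.

    ``unwrap(x) = mod(x + pi, 2*pi) - pi`` is congruent to ``x`` modulo
    ``2*pi`` and minimal in magnitude.  The boundary ``x = pi (mod 2*pi)``
    maps to ``-pi`` (tie convention of the half-open storage range).
    """
    return np.mod(np.asarray(x) + np.pi, 2.0 * np.pi) - np.pi


wrap = unwrap  # wrapping an absolute angle is the same arithmetic


def activation_phase(V, R, V_star: float, R_star: float, b: float = 0.0):
    """Activation phase ``atan2(R - R_star, V - V_star) + b`` in ``[-pi, pi)``.

    Pixels exactly at the reference point ``(V_star, R_star)`` have no
    polar angle and are flagged ``NaN``.  ``(V_star, R_star)`` is assumed
    to lie inside the trajectory cycle in the ``(V, R)`` plane (not
    checked).
    """
    V = np.asarray(V, float)
    R = np.asarray(R, float)
    if V.shape != R.shape:
        raise ValueError("V and R must have the same shape")
    dv, dr = V - V_star, R - R_star
    phi = wrap(np.arctan2(dr, dv) + b)
    degenerate = (dv == 0) & (dr == 0)
    if np.any(degenerate):
        phi = np.where(degenerate, np.nan, phi)
    return phi


def hilbert_phase(movie: Movie, b: float = np.pi) -> np.ndarray:
    """Per-frame phase from the analytic signal of each pixel's V trace.

    The per-pixel mean is subtracted before the Hilbert transform.  With
    the default offset ``b = pi`` a pixel resting near its trace minimum
    (analytic angle ``±pi``) is mapped near phase 0, matching the
    resting-state convention of the activation phase.  Constant traces
    have no analytic angle and are flagged ``NaN``.

    Returns an array of shape ``movie.V.shape`` in ``[-pi, pi)``.
    """
    V = movie.V
    centered = V - V.mean(axis=0, keepdims=True)
    phi = wrap(np.angle(_hilbert(centered, axis=0)) + b)
    flat = np.ptp(V, axis=0) == 0
    if np.any(flat):
        phi = np.where(flat[None], np.nan, phi)
    return phi


# ---------------------------------------------------------------------------
# Local activation time


def update_lat(lat, prev_frame, new_frame, t_new: float, V_star: float):
    """Record upward crossings of ``V_star`` between two frames.

    Pixels with ``prev < V_star <= new`` get their LAT overwritten with
    ``t_new`` (the "newest LAT" rule); all other pixels keep their
    previous value.  The sentinel for never-activated pixels is 0, so
    ``t_new`` must be positive.
    """
    lat = np.asarray(lat, float)
    prev_frame = np.asarray(prev_frame, float)
    new_frame = np.asarray(new_frame, float)
    crossed = (prev_frame < V_star) & (new_frame >= V_star)
    return np.where(crossed, t_new, lat)


def lat_series(movie: Movie, V_star: float = 0.5) -> np.ndarray:
    """LAT field after every frame of a movie.

    Returns an array of shape ``movie.V.shape``; entry ``[k]`` is the
    latest activation time known at frame ``k``.  Never-activated pixels
    carry the sentinel 0; recording starts at ``t = dt_frame`` so every
    valid LAT is positive (a crossing needs two frames).
    """
    V = movie.V
    t = movie.times
    if movie.t0 <= 0 and len(t) > 1 and t[1] <= 0:
        raise ValueError("frame times must become positive for valid LATs")
    crossed = np.zeros(V.shape, dtype=bool)
    crossed[1:] = (V[:-1] < V_star) & (V[1:] >= V_star)
    stamped = np.where(crossed, t.reshape((-1,) + (1,) * (V.ndim - 1)), 0.0)
    return np.maximum.accumulate(stamped, axis=0)


def elapsed_time(t_now: float, lat) -> np.ndarray:
    """``t_elapsed = t_now - t_activation``; NaN for never-activated pixels."""
    lat = np.asarray(lat, float)
    return np.where(lat > 0, t_now - lat, np.nan)


def arrival_phase(t_now: float, lat, tau: float) -> np.ndarray:
    """Arrival-time phase ``2*pi*tanh(3*t_elapsed/tau)`` in ``[-pi, pi)``.

    ``tau`` is a characteristic recovery time of the medium (e.g. the
    mean action-potential duration, or the inverse dominant frequency).
    Just-activated pixels sit at phase 0; as ``t_elapsed`` grows the
    phase saturates at ``2*pi``, i.e. back to 0 after wrapping — a fully
    recovered pixel is indistinguishable from a resting one.
    Never-activated pixels (``lat == 0``) are flagged ``NaN``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    te = elapsed_time(t_now, lat)
    return wrap(2.0 * np.pi * np.tanh(3.0 * te / tau))


def arrival_phase_series(
    movie: Movie, tau: float, V_star: float = 0.5
) -> np.ndarray:
    """Arrival-time phase at every frame, from the movie's own LAT."""
    lat = lat_series(movie, V_star)
    t = movie.times
    out = np.empty(movie.V.shape)
    for k in range(movie.n_frames):
        out[k] = arrival_phase(t[k], lat[k], tau)
    return out


# ---------------------------------------------------------------------------
# Spatial structure


def phase_gradient(phi, dx: float) -> np.ndarray:
    """Magnitude of the wrapped forward-difference phase gradient.

    Each forward difference is passed through :func:`unwrap`, so jumps
    of exactly ``2*pi`` are invisible; the magnitude is the Euclidean
    norm over axes.  Pixels whose forward neighbor is missing (last
    slice of each axis) or undefined propagate ``NaN``.
    """
    phi = np.asarray(phi, float)
    if any(s < 2 for s in phi.shape):
        raise ValueError("phase field must be at least 2 pixels per axis")
    sq = np.zeros(phi.shape)
    for ax in range(phi.ndim):
        d = np.full(phi.shape, np.nan)
        sl = [slice(None)] * phi.ndim
        sl[ax] = slice(0, -1)
        d[tuple(sl)] = unwrap(np.diff(phi, axis=ax)) / dx
        sq = sq + d**2
    return np.sqrt(sq)


def _circular_mean(angles: np.ndarray) -> float:
    z = np.exp(1j * angles).mean()
    return float(np.angle(z))


@dataclass(frozen=True)
class PhaseLevels:
    """Mean phase in the middle of the upstroke (phi1) and downstroke (phi2)."""

    phi1: float
    phi2: float


def phase_levels(movie: Movie, phases: np.ndarray, V_star: float = 0.5) -> PhaseLevels:
    """Circular-mean phase of pixels crossing ``V_star`` up (phi1) / down (phi2).

    A crossing is a sign change of ``V - V_star`` between consecutive
    frames; the phase is sampled at the later frame.  The sign of
    ``dV/dt`` is the backward finite difference, so upward crossings
    feed phi1 and downward crossings feed phi2.
    """
    V = movie.V
    if phases.shape != V.shape:
        raise ValueError("phases must be sampled on every movie frame")
    up = (V[:-1] < V_star) & (V[1:] >= V_star)
    down = (V[:-1] >= V_star) & (V[1:] < V_star)
    ph = phases[1:]
    up_vals = ph[up]
    down_vals = ph[down]
    up_vals = up_vals[np.isfinite(up_vals)]
    down_vals = down_vals[np.isfinite(down_vals)]
    if up_vals.size == 0:
        raise ValueError("phi1 undefined: no upward crossings of V_star")
    if down_vals.size == 0:
        raise ValueError("phi2 undefined: no downward crossings of V_star")
    return PhaseLevels(phi1=_circular_mean(up_vals), phi2=_circular_mean(down_vals))


@dataclass(frozen=True)
class FrontSet:
    """Wave front / wave back pixel masks (disjoint by construction)."""

    WF: np.ndarray
    WB: np.ndarray


def fronts(prev_frame, new_frame, V_star: float = 0.5) -> FrontSet:
    """Level-set pixels of ``V = V_star`` split by the sign of ``dV/dt``.

    The wave front (WF) collects pixels crossing ``V_star`` upward
    between the two frames, the wave back (WB) those crossing downward.
    """
    prev_frame = np.asarray(prev_frame, float)
    new_frame = np.asarray(new_frame, float)
    wf = (prev_frame < V_star) & (new_frame >= V_star)
    wb = (prev_frame >= V_star) & (new_frame < V_star)
    return FrontSet(WF=wf, WB=wb)


def defect_thickness(
    D_cm2_per_s: float, tau_ms: float, anisotropy_ratio: float = 1.0
) -> float:
    """Diffusive boundary-layer thickness of a phase defect line, in mm.

    Voltage diffusion smears the ideally sharp phase discontinuity at a
    conduction block line over a layer ``d = sqrt(D * tau)``, scaled by
    the conduction-velocity anisotropy ratio when the line runs parallel
    to the fibers.

    Parameters
    ----------
    D_cm2_per_s : float
        Voltage diffusion coefficient perpendicular to the line, cm^2/s.
    tau_ms : float
        Action-potential duration, ms.
    anisotropy_ratio : float
        Conduction-velocity ratio c1/c2 >= 1 (default 1, isotropic).
    """
    if D_cm2_per_s < 0 or tau_ms < 0:
        raise ValueError("D and tau must be non-negative")
    if anisotropy_ratio < 1:
        raise ValueError("anisotropy_ratio must be >= 1")
    d_mm2 = 0.1 * D_cm2_per_s * tau_ms  # 1 cm^2/s = 0.1 mm^2/ms
    return float(np.sqrt(d_mm2) * anisotropy_ratio)
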
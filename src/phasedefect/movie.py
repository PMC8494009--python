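"""Dense spatiotemporal voltage movies — the universal input of the package.

A :class:`Movie` holds normalized transmembrane potential frames
``V[t, y, x]`` (optionally ``V[t, y, x, z]``), an optional second
observable ``R`` of the same shape, the frame interval ``dt_frame`` and
pixel spacing ``dx``, plus free-form metadata.  Movies are produced by
the built-in simulator (:mod:`phasedefect.simulate`), imported from
optical-mapping recordings (:mod:`phasedefect.io`), or constructed
directly from arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Movie"]


@dataclass
class Movie:
    """A voltage movie on a regular grid.

    Parameters
    ----------
    V : ndarray, shape (T, ny, nx) or (T, ny, nx, nz)
        Voltage-like observable per frame.
    dt_frame : float
        Time between consecutive frames (model time units).
    dx : float
        Grid spacing (model space units).
    R : ndarray, optional
        Second observable, same shape as ``V``.
    t0 : float
        Time of the first frame (default 0).
    meta : dict
        Provenance: kinetics name, parameter set, protocol, seed, ...
    """

    V: np.ndarray
    dt_frame: float
    dx: float
    R: np.ndarray | None = None
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim not in (3, 4):
            raise ValueError("V must have shape (T, ny, nx) or (T, ny, nx, nz)")
        if self.R is not None:
            self.R = np.asarray(self.R, dtype=float)
            if self.R.shape != self.V.shape:
                raise ValueError("R must have the same shape as V")
        if self.dt_frame <= 0:
            raise ValueError("dt_frame must be positive")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def n_frames(self) -> int:
        return self.V.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.V.shape[1:]

    @property
    def ndim_space(self) -> int:
        return self.V.ndim - 1

    @property
    def times(self) -> np.ndarray:
        """Frame times ``t0 + k * dt_frame``."""
        return self.t0 + self.dt_frame * np.arange(self.n_frames)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        shape = "x".join(map(str, self.V.shape))
        extra = " +R" if self.R is not None else ""
        return (f"Movie({shape}{extra}, dt_frame={self.dt_frame:g}, "
                f"dx={self.dx:g}, kinetics={self.meta.get('kinetics', '?')})")
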
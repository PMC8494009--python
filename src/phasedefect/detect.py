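"""Frame-wise detection of phase singularities and phase defects.

Phase singularities (PSs) are found with ring methods on the phase
field: around each grid-cell corner the cyclic *raw* phase differences
are computed on the 2x2 ring of surrounding pixels (optionally also an
8-pixel outer ring), and a PS is flagged iff exactly one difference
exceeds ``pi`` in magnitude.  Conduction block lines (CBLs) are edges
whose endpoint activation times differ by more than a threshold;
phase defect lines (PDLs) are edges whose wrapped phase difference
exceeds a threshold.  In 3D the same edge rule yields phase defect
surfaces (PDSs).  Flagged edge midpoints live on half-integer
coordinates and are grouped into connected components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .phase import unwrap

__all__ = [
    "PsDetection",
    "DefectSet",
    "detect_ps",
    "winding_number",
    "detect_cbl",
    "detect_pdl",
    "detect_pdl_cos",
    "detect_pds",
    "associate_ps_pdl",
]

#: PSs are associated to a PDL when the PDL passes through a node of the
#: PS's own grid cell; corner-to-node distance is then sqrt(2)/2.
ON_PDL_DISTANCE = np.sqrt(0.5) + 1e-9


@dataclass(frozen=True)
class PsDetection:
    """A phase singularity at a grid-cell corner.

    ``position`` is in (y, x) order at half-integer coordinates;
    ``chirality`` is the sign (+1/-1) of the phase winding around the
    corner.
    """

    position: tuple[float, float]
    chirality: int
    frame: int = 0
    method: str = "ring2x2"


@dataclass
class DefectSet:
    """Flagged edge midpoints of one frame, grouped into components.

    ``edges`` holds the integer endpoint pairs of every flagged
    4-neighbor (6-neighbor in 3D) edge, shape ``(n, 2, ndim)`` in
    (y, x[, z]) axis order; ``labels`` assigns each edge to a connected
    component (midpoints within Chebyshev distance 1 are connected,
    i.e. 8-connectivity in 2D / 26-connectivity in 3D).
    """

    frame: int
    edges: np.ndarray
    labels: np.ndarray
    source: str = "pdl_phase"
    threshold: float | None = None

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        return 0 if self.n_edges == 0 else int(self.labels.max()) + 1

    @property
    def midpoints(self) -> np.ndarray:
        """Half-integer edge midpoints, shape (n, ndim)."""
        if self.n_edges == 0:
            return np.zeros((0, self.edges.shape[2] if self.edges.ndim == 3 else 2))
        return self.edges.mean(axis=1)

    def nodes(self) -> np.ndarray:
        """Unique integer grid nodes belonging to the defect."""
        if self.n_edges == 0:
            return np.zeros((0, self.edges.shape[2] if self.edges.ndim == 3 else 2))
        return np.unique(self.edges.reshape(-1, self.edges.shape[2]), axis=0)

    def component(self, label: int) -> np.ndarray:
        """Midpoints of one connected component."""
        return self.midpoints[self.labels == label]


def _label_components(midpoints: np.ndarray) -> np.ndarray:
    """Connected components of midpoints under Chebyshev distance <= 1."""
    n = len(midpoints)
    if n == 0:
        return np.zeros(0, dtype=int)
    pairs = cKDTree(midpoints).query_pairs(1.0 + 1e-9, p=np.inf, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def _flag_edges(field: np.ndarray, edge_test) -> np.ndarray:
    """Collect endpoint pairs of axis-aligned edges where ``edge_test`` holds.

    ``edge_test(a, b)`` receives the two endpoint-value arrays of all
    edges along one axis and returns a boolean array; NaN endpoints
    never flag (NaN comparisons are False).
    """
    ndim = field.ndim
    all_edges = []
    for ax in range(ndim):
        lo = [slice(None)] * ndim
        hi = [slice(None)] * ndim
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        hit = edge_test(field[tuple(lo)], field[tuple(hi)])
        idx = np.argwhere(hit)
        if len(idx):
            a = idx
            b = idx.copy()
            b[:, ax] += 1
            all_edges.append(np.stack([a, b], axis=1))
    if not all_edges:
        return np.zeros((0, 2, ndim), dtype=int)
    return np.concatenate(all_edges)


def _make_defect_set(field, edge_test, frame, source, threshold) -> DefectSet:
    edges = _flag_edges(np.asarray(field, float), edge_test)
    labels = _label_components(edges.mean(axis=1)) if len(edges) else np.zeros(0, int)
    return DefectSet(frame=frame, edges=edges, labels=labels,
                     source=source, threshold=threshold)


# ---------------------------------------------------------------------------
# Phase singularities


def _ring_stats(rings: np.ndarray):
    """Cyclic raw-difference statistics along the first axis.

    Returns (valid, single_large, big_sign): corners where all ring
    phases are defined, where exactly one cyclic raw difference exceeds
    pi in magnitude, and the sign of that difference.
    """
    diffs = np.diff(rings, axis=0, append=rings[:1])
    large = np.abs(diffs) > np.pi
    count = large.sum(axis=0)
    valid = np.all(np.isfinite(rings), axis=0)
    big_sign = np.sign(np.where(large, np.sign(diffs), 0.0).sum(axis=0))
    return valid, count == 1, big_sign


def _inner_rings(phi: np.ndarray) -> np.ndarray:
    """2x2 rings (4, ny-1, nx-1), counter-traversal order fixed."""
    return np.stack([phi[:-1, :-1], phi[:-1, 1:], phi[1:, 1:], phi[1:, :-1]])


def _outer_rings(phi: np.ndarray) -> np.ndarray:
    """8-pixel octagonal rings of the 4x4 neighborhood, (8, ny-3, nx-3).

    Ring around corner (i+0.5, j+0.5) for i, j >= 1: the perimeter of
    the 4x4 block minus its corner pixels, traversed cyclically.
    """
    offs = [(-1, 0), (-1, 1), (0, 2), (1, 2), (2, 1), (2, 0), (1, -1), (0, -1)]
    ny, nx = phi.shape
    out = np.empty((8, ny - 3, nx - 3))
    for k, (dy, dx) in enumerate(offs):
        out[k] = phi[1 + dy: ny - 2 + dy, 1 + dx: nx - 2 + dx]
    return out


def winding_number(phi: np.ndarray) -> np.ndarray:
    """Topological charge at every grid-cell corner.

    Independent oracle: the sum of *unwrapped* cyclic differences around
    each 2x2 ring, divided by 2*pi.  Values are integers in {-1, 0, +1}
    wherever all four phases are defined; NaN elsewhere.
    """
    rings = _inner_rings(np.asarray(phi, float))
    diffs = unwrap(np.diff(rings, axis=0, append=rings[:1]))
    w = diffs.sum(axis=0) / (2.0 * np.pi)
    w = np.where(np.all(np.isfinite(rings), axis=0), np.round(w), np.nan)
    return w


def detect_ps(phi: np.ndarray, method: str = "ring2x2", frame: int = 0
              ) -> list[PsDetection]:
    """Detect phase singularities with the ring method.

    A PS sits at corner ``(i+0.5, j+0.5)`` iff exactly one cyclic *raw*
    phase difference around the 2x2 ring of surrounding pixels exceeds
    ``pi`` in magnitude; the ``"ring2x2_4x4"`` variant additionally
    requires the same single-large-jump condition on the octagonal
    8-pixel outer ring.  Chirality is the winding sign, i.e. the
    negative of the sign of the unique super-pi raw difference.  Corners
    with undefined (NaN) ring pixels are skipped.
    """
    phi = np.asarray(phi, float)
    if method not in ("ring2x2", "ring2x2_4x4"):
        raise ValueError(f"unknown PS method {method!r}")
    if phi.ndim != 2:
        raise ValueError("detect_ps expects a 2D phase field")
    min_size = 4 if method == "ring2x2_4x4" else 2
    if min(phi.shape) < min_size:
        raise ValueError(f"{method} needs a grid of at least "
                         f"{min_size}x{min_size} pixels")

    valid, single, big_sign = _ring_stats(_inner_rings(phi))
    hit = valid & single
    if method == "ring2x2_4x4":
        ovalid, osingle, _ = _ring_stats(_outer_rings(phi))
        outer_hit = np.zeros_like(hit)
        outer_hit[1:-1, 1:-1] = ovalid & osingle
        hit &= outer_hit
    out = []
    for i, j in np.argwhere(hit):
        out.append(PsDetection(
            position=(i + 0.5, j + 0.5),
            chirality=int(-big_sign[i, j]),
            frame=frame,
            method=method,
        ))
    return out


# ---------------------------------------------------------------------------
# Edge-based defect detectors


def detect_cbl(lat: np.ndarray, dt_c: float, frame: int = 0) -> DefectSet:
    """Conduction block lines from a LAT field.

    An edge is flagged iff both endpoints have activated (LAT > 0) and
    their activation times differ by more than ``dt_c``; the positivity
    conditions exclude the wave front against still-resting tissue.
    """
    if dt_c <= 0:
        raise ValueError("dt_c must be positive")
    lat = np.asarray(lat, float)

    def test(a, b):
        return (a > 0) & (b > 0) & (np.abs(a - b) > dt_c)

    return _make_defect_set(lat, test, frame, "cbl_lat", dt_c)


def detect_pdl(phi: np.ndarray, dphi_crit: float = 2.22, frame: int = 0,
               source: str = "pdl_phase") -> DefectSet:
    """Phase defect lines: edges with wrapped phase jump above ``dphi_crit``.

    Differences are unwrapped first, so jumps of ``2*pi`` (ordinary
    continuity of the angle) never flag.  Thresholds ``>= pi`` can never
    fire on wrapped differences and trigger a warning.
    """
    if dphi_crit <= 0:
        raise ValueError("dphi_crit must be positive")
    if dphi_crit >= np.pi:
        warnings.warn(
            "dphi_crit >= pi can never fire on wrapped phase differences",
            RuntimeWarning, stacklevel=2,
        )

    def test(a, b):
        return np.abs(unwrap(a - b)) > dphi_crit

    return _make_defect_set(phi, test, frame, source, dphi_crit)


def detect_pdl_cos(phi: np.ndarray, A: float, frame: int = 0,
                   printed_inequality: bool = False) -> DefectSet:
    """Cosine-threshold PDL variant: flag edges with ``cos(dphi) < A``.

    Across a phase defect the phase jump approaches ``pi`` so the cosine
    of the difference is near -1, while in smooth tissue it is near +1;
    hence the ``<`` comparison, which makes this detector exactly
    equivalent to :func:`detect_pdl` with ``dphi_crit = arccos(A)``.
    ``printed_inequality=True`` flips the comparison to ``>`` (which
    flags smooth tissue instead) for strict reproduction of the
    published formula.
    """
    if not -1.0 <= A <= 1.0:
        raise ValueError("A must lie in [-1, 1]")

    if printed_inequality:
        def test(a, b):
            return np.cos(a - b) > A
    else:
        def test(a, b):
            return np.cos(a - b) < A

    return _make_defect_set(phi, test, frame, "pdl_cos", A)


def detect_pds(phi: np.ndarray, dphi_crit: float = 2.22, frame: int = 0
               ) -> DefectSet:
    """Phase defect surface in 3D: the PDL edge rule on all axis-aligned
    edges of a volume, with components by 26-connectivity of midpoints."""
    phi = np.asarray(phi, float)
    if phi.ndim != 3:
        raise ValueError("detect_pds expects a 3D phase field")
    return detect_pdl(phi, dphi_crit, frame=frame, source="pds_phase")


def associate_ps_pdl(ps: list[PsDetection], pdl: DefectSet) -> np.ndarray:
    """Label each PS as lying on the PDL or not.

    A PS is *on* a PDL when the defect passes through a node of the
    PS's own grid cell, i.e. when the minimal Euclidean distance from
    the PS corner to any PDL node is at most ``sqrt(2)/2``.

    Returns a boolean array aligned with ``ps``.
    """
    if not ps:
        return np.zeros(0, dtype=bool)
    nodes = pdl.nodes()
    if len(nodes) == 0:
        return np.zeros(len(ps), dtype=bool)
    pos = np.array([p.position for p in ps], dtype=float)
    dist, _ = cKDTree(nodes).query(pos, k=1)
    return dist <= ON_PDL_DISTANCE
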
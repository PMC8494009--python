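"""Temporal linking of detections and per-recording summary statistics.

Phase singularities are linked frame-to-frame into tracks when they move
at most one pixel in the horizontal, vertical or diagonal direction
(Chebyshev distance <= 1) while keeping their chirality; unmatched
detections start new tracks.  Phase-defect-line components are linked
into *families* whenever any pair of their points is at most one pixel
apart; families may branch and merge, so a family is a connected
component of the frame-to-frame link graph.  The summary statistics
(counts per frame, association fractions, lifespans, dominant
frequency) mirror the quantities commonly reported for optical-mapping
recordings of ventricular tachycardia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .detect import DefectSet, PsDetection, associate_ps_pdl
from .movie import Movie

__all__ = [
    "PsTrack",
    "PdlFamily",
    "SummaryStats",
    "track_ps",
    "track_pdl",
    "dominant_frequency",
    "summarize",
]

#: "at most 1 pixel in the horizontal, vertical, or diagonal direction"
_LINK_RADIUS = 1.0 + 1e-9


@dataclass
class PsTrack:
    """A linked sequence of PS detections with constant chirality."""

    detections: list[PsDetection] = field(default_factory=list)

    @property
    def birth(self) -> int:
        return self.detections[0].frame

    @property
    def death(self) -> int:
        return self.detections[-1].frame

    @property
    def chirality(self) -> int:
        return self.detections[0].chirality

    def lifespan(self, dt_frame: float) -> float:
        """Inclusive lifespan ``(death - birth + 1) * dt_frame``."""
        return (self.death - self.birth + 1) * dt_frame


@dataclass
class PdlFamily:
    """PDL components linked over time, allowing branching and merging.

    ``members`` maps frame index -> list of component labels of that
    frame's :class:`~phasedefect.detect.DefectSet` belonging to the
    family.
    """

    members: dict[int, list[int]] = field(default_factory=dict)

    @property
    def birth(self) -> int:
        return min(self.members)

    @property
    def death(self) -> int:
        return max(self.members)

    @property
    def n_components(self) -> int:
        return sum(len(v) for v in self.members.values())

    def lifespan(self, dt_frame: float) -> float:
        """Inclusive lifespan ``(death - birth + 1) * dt_frame``."""
        return (self.death - self.birth + 1) * dt_frame


def track_ps(detections_per_frame: list[list[PsDetection]],
             dt_frame: float = 1.0) -> list[PsTrack]:
    """Greedy frame-to-frame linking of PS detections into tracks.

    Candidate links require Chebyshev distance <= 1 pixel and equal
    chirality; competing candidates are resolved by smallest Euclidean
    distance, then lowest (y, x) position of the detection.  Unmatched
    detections start new tracks.
    """
    tracks: list[PsTrack] = []
    open_tracks: list[PsTrack] = []
    for dets in detections_per_frame:
        dets = sorted(dets, key=lambda d: d.position)
        candidates = []
        for ti, tr in enumerate(open_tracks):
            last = tr.detections[-1]
            for di, d in enumerate(dets):
                if d.chirality != last.chirality:
                    continue
                dy = d.position[0] - last.position[0]
                dx = d.position[1] - last.position[1]
                if max(abs(round(dy)), abs(round(dx))) <= 1:
                    candidates.append((np.hypot(dy, dx), d.position, ti, di))
        used_t: set[int] = set()
        used_d: set[int] = set()
        for _, _, ti, di in sorted(candidates, key=lambda c: (c[0], c[1])):
            if ti in used_t or di in used_d:
                continue
            open_tracks[ti].detections.append(dets[di])
            used_t.add(ti)
            used_d.add(di)
        next_open = [tr for ti, tr in enumerate(open_tracks) if ti in used_t]
        for di, d in enumerate(dets):
            if di not in used_d:
                tr = PsTrack([d])
                tracks.append(tr)
                next_open.append(tr)
        open_tracks = next_open
    return tracks


def _components_points(ds: DefectSet) -> list[np.ndarray]:
    return [ds.component(lbl) for lbl in range(ds.n_components)]


def track_pdl(defects_per_frame: list[DefectSet],
              dt_frame: float = 1.0) -> list[PdlFamily]:
    """Link per-frame PDL components into families (union over links).

    Components in consecutive frames are linked when any pair of their
    midpoints is at most 1 pixel apart (Chebyshev); families are the
    connected components of the link graph over the whole recording,
    which makes branching and merging automatic.
    """
    # assign a global id to every (frame, component)
    ids: dict[tuple[int, int], int] = {}
    for f, ds in enumerate(defects_per_frame):
        for lbl in range(ds.n_components):
            ids[(f, lbl)] = len(ids)
    parent = list(range(len(ids)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for f in range(len(defects_per_frame) - 1):
        cur = _components_points(defects_per_frame[f])
        nxt = _components_points(defects_per_frame[f + 1])
        if not cur or not nxt:
            continue
        trees = [cKDTree(pts) for pts in nxt]
        for la, pts_a in enumerate(cur):
            for lb, tree in enumerate(trees):
                d, _ = tree.query(pts_a, k=1, p=np.inf,
                                  distance_upper_bound=_LINK_RADIUS)
                if np.any(np.isfinite(d) & (d <= _LINK_RADIUS)):
                    union(ids[(f, la)], ids[(f + 1, lb)])

    families: dict[int, PdlFamily] = {}
    for (f, lbl), gid in ids.items():
        root = find(gid)
        fam = families.setdefault(root, PdlFamily())
        fam.members.setdefault(f, []).append(lbl)
    return list(families.values())


def dominant_frequency(movie: Movie) -> float:
    """Dominant activation frequency of a recording.

    Frequency of the largest spectral peak (zero bin excluded) of the
    spatially averaged, mean-subtracted voltage trace.  Units are the
    inverse of the movie's time unit.
    """
    trace = np.nanmean(movie.V.reshape(movie.n_frames, -1), axis=1)
    trace = trace - trace.mean()
    if np.ptp(trace) == 0:
        raise ValueError("flat signal: dominant frequency undefined")
    spec = np.abs(np.fft.rfft(trace))
    freqs = np.fft.rfftfreq(movie.n_frames, d=movie.dt_frame)
    return float(freqs[1:][np.argmax(spec[1:])])


@dataclass
class SummaryStats:
    """Per-recording PS / PDL statistics."""

    n_ps_per_frame: float
    n_pdl_per_frame: float
    frac_ps_not_on_pdl: float
    n_pdl_without_ps_per_frame: float
    new_ps_per_frame: float
    new_pdl_per_frame: float
    frac_ps_never_on_pdl: float
    frac_pdl_never_hosting_ps: float
    dominant_frequency: float | None
    dominant_period: float | None
    mean_ps_lifespan: float
    mean_pdl_lifespan: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(
    ps_per_frame: list[list[PsDetection]],
    defects_per_frame: list[DefectSet],
    dt_frame: float,
    movie: Movie | None = None,
    ps_tracks: list[PsTrack] | None = None,
    pdl_families: list[PdlFamily] | None = None,
) -> SummaryStats:
    """Compute the per-recording summary statistics.

    Tracks/families are computed from the detections when not supplied.
    ``frac_ps_never_on_pdl`` evaluates the PS/PDL association over each
    track's whole life; a track never associated in any of its frames
    counts as "never on a PDL".
    """
    n_frames = len(ps_per_frame)
    if len(defects_per_frame) != n_frames:
        raise ValueError("PS and PDL detections must cover the same frames")
    if ps_tracks is None:
        ps_tracks = track_ps(ps_per_frame, dt_frame)
    if pdl_families is None:
        pdl_families = track_pdl(defects_per_frame, dt_frame)

    on_per_frame = [associate_ps_pdl(ps, ds)
                    for ps, ds in zip(ps_per_frame, defects_per_frame)]
    n_ps = sum(len(p) for p in ps_per_frame)
    n_on = sum(int(on.sum()) for on in on_per_frame)

    # which PDL components host a PS, per frame
    pdl_without_ps = 0
    hosted: set[tuple[int, int]] = set()
    for f, (ps, ds) in enumerate(zip(ps_per_frame, defects_per_frame)):
        hosts: set[int] = set()
        if ps and ds.n_edges:
            pos = np.array([p.position for p in ps])
            nodes = ds.nodes()
            node_label = {}
            for lbl in range(ds.n_components):
                for nd in ds.edges[ds.labels == lbl].reshape(-1, ds.edges.shape[2]):
                    node_label[tuple(nd)] = lbl
            tree = cKDTree(nodes)
            dist, idx = tree.query(pos, k=1)
            from .detect import ON_PDL_DISTANCE
            for d, i in zip(dist, idx):
                if d <= ON_PDL_DISTANCE:
                    hosts.add(node_label[tuple(nodes[i])])
        pdl_without_ps += ds.n_components - len(hosts)
        hosted.update((f, lbl) for lbl in hosts)

    # track-level association
    det_on: dict[tuple[int, float, float], bool] = {}
    for ps, on in zip(ps_per_frame, on_per_frame):
        for d, flag in zip(ps, on):
            det_on[(d.frame, *d.position)] = bool(flag)
    never_on = sum(
        1 for tr in ps_tracks
        if not any(det_on.get((d.frame, *d.position), False)
                   for d in tr.detections)
    )
    fam_never_host = sum(
        1 for fam in pdl_families
        if not any((f, lbl) in hosted
                   for f, lbls in fam.members.items() for lbl in lbls)
    )

    freq = period = None
    if movie is not None:
        try:
            freq = dominant_frequency(movie)
            period = 1.0 / freq if freq > 0 else None
        except ValueError:
            pass

    return SummaryStats(
        n_ps_per_frame=n_ps / n_frames,
        n_pdl_per_frame=sum(ds.n_components for ds in defects_per_frame) / n_frames,
        frac_ps_not_on_pdl=(n_ps - n_on) / n_ps if n_ps else 1.0,
        n_pdl_without_ps_per_frame=pdl_without_ps / n_frames,
        new_ps_per_frame=len(ps_tracks) / n_frames,
        new_pdl_per_frame=len(pdl_families) / n_frames,
        frac_ps_never_on_pdl=never_on / len(ps_tracks) if ps_tracks else 1.0,
        frac_pdl_never_hosting_ps=(
            fam_never_host / len(pdl_families) if pdl_families else 1.0),
        dominant_frequency=freq,
        dominant_period=period,
        mean_ps_lifespan=(
            float(np.mean([t.lifespan(dt_frame) for t in ps_tracks]))
            if ps_tracks else 0.0),
        mean_pdl_lifespan=(
            float(np.mean([f.lifespan(dt_frame) for f in pdl_families]))
            if pdl_families else 0.0),
    )
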
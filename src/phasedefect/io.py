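"""Movie container I/O, optical preprocessing and tabular exports.

Movies are persisted in an HDF5 container with datasets ``/V`` (frames
``[t, y, x(, z)]``), optional ``/R``, optional derived fields
(``/phi_act``, ``/phi_arr``, ``/lat``) and the attributes ``dt_frame``
and ``dx`` plus free-form scalar metadata.  Raw optical recordings
(integer intensity movies) are normalized per pixel against the minimal
and maximal intensity over the recording, with background removed by a
range threshold.  Detections and tracks are exported as CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .detect import DefectSet, PsDetection
from .movie import Movie
from .track import PsTrack, SummaryStats

__all__ = [
    "SchemaError",
    "write_movie",
    "read_movie",
    "normalize_optical",
    "movie_from_array",
    "read_array_with_sidecar",
    "detections_to_frame",
    "tracks_to_frame",
    "summary_to_frame",
]

_DERIVED = ("phi_act", "phi_arr", "lat")


class SchemaError(ValueError):
    """A movie container is missing a required dataset or attribute."""


def write_movie(movie: Movie, path, fields: dict | None = None) -> None:
    """Write a movie (and optional derived fields) to an HDF5 container.

    ``fields`` may map any of ``phi_act``, ``phi_arr``, ``lat`` to
    arrays of shape ``movie.V.shape``.  Non-scalar metadata entries
    (e.g. the simulator's final state) are stored as datasets.
    """
    path = Path(path)
    # track_times=False keeps outputs byte-identical across runs
    with h5py.File(path, "w") as f:
        f.create_dataset("V", data=movie.V, track_times=False)
        if movie.R is not None:
            f.create_dataset("R", data=movie.R, track_times=False)
        f.attrs["dt_frame"] = movie.dt_frame
        f.attrs["dx"] = movie.dx
        f.attrs["t0"] = movie.t0
        for key, val in sorted(movie.meta.items()):
            if isinstance(val, np.ndarray):
                f.create_dataset(f"meta/{key}", data=val, track_times=False)
            elif val is not None:
                f.attrs[key] = val
        for key, val in sorted((fields or {}).items()):
            if key not in _DERIVED:
                raise ValueError(f"unknown derived field {key!r}")
            f.create_dataset(key, data=val, track_times=False)


def read_movie(path) -> Movie:
    """Read a movie container; raises :class:`SchemaError` when invalid.

    Derived fields present in the file are attached under
    ``movie.meta['fields']``.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "V" not in f:
            raise SchemaError(f"{path}: missing dataset '/V'")
        for attr in ("dt_frame", "dx"):
            if attr not in f.attrs:
                raise SchemaError(f"{path}: missing attribute {attr!r}")
        V = f["V"][()]
        R = f["R"][()] if "R" in f else None
        meta = {k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in f.attrs.items()
                if k not in ("dt_frame", "dx", "t0")}
        if "meta" in f:
            for k in f["meta"]:
                meta[k] = f["meta"][k][()]
        fields = {k: f[k][()] for k in _DERIVED if k in f}
        if fields:
            meta["fields"] = fields
        return Movie(V=V, R=R, dt_frame=float(f.attrs["dt_frame"]),
                     dx=float(f.attrs["dx"]), t0=float(f.attrs.get("t0", 0.0)),
                     meta=meta)


# ---------------------------------------------------------------------------
# Optical-mapping preprocessing


def normalize_optical(raw: np.ndarray, dt_frame: float, dx: float = 1.0,
                      background_threshold: float = 0.0) -> Movie:
    """Normalize a raw intensity movie per pixel to [0, 1].

    Each pixel's trace is mapped through
    ``(I - I_min) / (I_max - I_min)`` over the full recording.  Pixels
    whose full-trace range is at or below ``background_threshold`` (in
    raw intensity counts) are flagged background and set to NaN.
    """
    raw = np.asarray(raw, float)
    if raw.ndim not in (3, 4):
        raise ValueError("raw movie must be (T, ny, nx[, nz])")
    if raw.shape[0] < 2:
        raise ValueError("need at least 2 frames to normalize")
    if np.any(raw < 0):
        raise ValueError("raw intensities must be non-negative")
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    rng = hi - lo
    background = rng <= background_threshold
    if np.all(background):
        raise ValueError("all pixels classified as background")
    with np.errstate(invalid="ignore", divide="ignore"):
        V = (raw - lo) / rng
    V[:, background] = np.nan
    return Movie(V=V, dt_frame=dt_frame, dx=dx,
                 meta={"source": "optical", "n_background": int(background.sum())})


def movie_from_array(V: np.ndarray, dt_frame: float, dx: float,
                     R: np.ndarray | None = None, **meta) -> Movie:
    """Wrap a plain array (plus metadata) as a Movie."""
    return Movie(V=np.asarray(V, float), R=R, dt_frame=dt_frame, dx=dx, meta=meta)


def read_array_with_sidecar(array_path, sidecar_path=None) -> Movie:
    """Import a plain ``.npy`` 3D/4D array with a JSON or YAML sidecar.

    The sidecar must provide ``dt_frame`` and ``dx``; all other keys go
    into the movie metadata.
    """
    array_path = Path(array_path)
    if sidecar_path is None:
        for ext in (".json", ".yaml", ".yml"):
            cand = array_path.with_suffix(ext)
            if cand.exists():
                sidecar_path = cand
                break
        else:
            raise SchemaError(f"no sidecar metadata file found for {array_path}")
    sidecar_path = Path(sidecar_path)
    text = sidecar_path.read_text()
    meta = json.loads(text) if sidecar_path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(meta, dict) or "dt_frame" not in meta or "dx" not in meta:
        raise SchemaError(f"{sidecar_path}: sidecar must define dt_frame and dx")
    V = np.load(array_path)
    dt_frame = float(meta.pop("dt_frame"))
    dx = float(meta.pop("dx"))
    return Movie(V=V, dt_frame=dt_frame, dx=dx, meta=meta)


# ---------------------------------------------------------------------------
# Tabular exports


def detections_to_frame(
    ps_per_frame: list[list[PsDetection]] | None = None,
    defects_per_frame: list[DefectSet] | None = None,
    dt_frame: float = 1.0,
) -> pd.DataFrame:
    """Flatten PS and defect detections into one tidy table."""
    rows = []
    for ps_list in ps_per_frame or []:
        for p in ps_list:
            rows.append(dict(frame=p.frame, t=p.frame * dt_frame,
                             y=p.position[0], x=p.position[1], kind="ps",
                             chirality=p.chirality, component_id=-1,
                             method=p.method, threshold=np.nan))
    kind_of = {"cbl_lat": "cbl", "pdl_phase": "pdl",
               "pdl_cos": "pdl", "pds_phase": "pds"}
    for ds in defects_per_frame or []:
        kind = kind_of.get(ds.source, "pdl")
        for mp, lbl in zip(ds.midpoints, ds.labels):
            row = dict(frame=ds.frame, t=ds.frame * dt_frame,
                       y=mp[0], x=mp[1], kind=kind, chirality=0,
                       component_id=int(lbl), method=ds.source,
                       threshold=ds.threshold)
            if len(mp) == 3:
                row["z"] = mp[2]
            rows.append(row)
    cols = ["frame", "t", "y", "x", "kind", "chirality",
            "component_id", "method", "threshold"]
    return pd.DataFrame(rows, columns=cols + (["z"] if any("z" in r for r in rows) else []))


def tracks_to_frame(tracks: list[PsTrack], dt_frame: float = 1.0) -> pd.DataFrame:
    rows = []
    for tid, tr in enumerate(tracks):
        for d in tr.detections:
            rows.append(dict(track_id=tid, frame=d.frame, t=d.frame * dt_frame,
                             y=d.position[0], x=d.position[1],
                             chirality=d.chirality))
    return pd.DataFrame(rows, columns=["track_id", "frame", "t", "y", "x", "chirality"])


def summary_to_frame(stats: SummaryStats) -> pd.DataFrame:
    """One-row table of the per-recording summary statistics."""
    return pd.DataFrame([stats.as_dict()])
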
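"""Hand-landmark time series and the index–thumb distance waveform.

The pipeline tracks two fingertip landmarks (index tip, thumb tip) per video
frame, as produced by markerless hand-pose backends.  Everything upstream of
this module (video decoding, pose estimation) is isolated behind a plain
long-format CSV: one row per landmark per frame, columns
``frame,time_s,landmark,x,y,confidence``.  Coordinates are image-normalized
(origin top-left, x rightward, y downward, both in [0, 1]); distances derived
from them are therefore in normalized image units, conventionally labelled
"px" in clinical reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError

INDEX_TIP = "INDEX_TIP"
THUMB_TIP = "THUMB_TIP"
_KNOWN_LANDMARKS = (INDEX_TIP, THUMB_TIP)

_HAND_LABELS = ("left", "right", "dominant", "most_affected")


@dataclass(frozen=True)
class LandmarkSeries:
    """Per-frame 2-D positions of the two tracked fingertips of one hand.

    Frames where either landmark is missing are retained in the arrays (as
    NaN) but flagged in ``dropped`` so that quality control can account for
    them.
    """

    frame_index: np.ndarray  # (n,) int, strictly increasing
    time_s: np.ndarray  # (n,) float seconds
    index_xy: np.ndarray  # (n, 2) normalized coordinates
    thumb_xy: np.ndarray  # (n, 2)
    confidence: np.ndarray  # (n,) min confidence across landmarks, NaN if absent
    dropped: np.ndarray  # (n,) bool, True if either landmark missing
    fps: float
    hand_label: str = "most_affected"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidArgumentError(f"fps must be positive, got {self.fps}")
        if self.hand_label not in _HAND_LABELS:
            raise InvalidArgumentError(
                f"hand_label must be one of {_HAND_LABELS}, got {self.hand_label!r}"
            )
        fi = np.asarray(self.frame_index)
        if fi.size and np.any(np.diff(fi) <= 0):
            raise FormatError("frame_index must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frame_index.size)

    @property
    def dropped_fraction(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(np.mean(self.dropped))


@dataclass(frozen=True)
class DistanceWaveform:
    """Scalar index–thumb aperture trace with preprocessing provenance.

    ``provenance`` is append-only: every conditioning step adds exactly one
    entry describing the transform and its parameters.
    """

    t: np.ndarray  # (n,) seconds, strictly increasing
    d: np.ndarray  # (n,) aperture in normalized image units
    sample_rate_hz: float
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        d = np.asarray(self.d, dtype=float)
        if t.shape != d.shape or t.ndim != 1:
            raise InvalidArgumentError("t and d must be 1-D arrays of equal length")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("t must be strictly increasing")
        if d.size and not np.all(np.isfinite(d)):
            raise InvalidArgumentError("d must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d", d)

    def __len__(self) -> int:
        return int(self.t.size)

    def with_samples(self, t: np.ndarray, d: np.ndarray, step: str,
                     sample_rate_hz: float | None = None) -> "DistanceWaveform":
        """Return a copy with new samples and one appended provenance entry."""
        return replace(
            self,
            t=np.asarray(t, dtype=float),
            d=np.asarray(d, dtype=float),
            sample_rate_hz=self.sample_rate_hz if sample_rate_hz is None else sample_rate_hz,
            provenance=self.provenance + (step,),
        )


def write_landmark_table(series: LandmarkSeries, path: str | Path) -> None:
    """Write a series in the long-format landmark CSV dialect.

    Rows for dropped landmarks are omitted, which is how missingness is
    represented on disk.  A JSON sidecar ``<path>.meta.json`` stores fps and
    hand metadata.
    """
    path = Path(path)
    rows = []
    for k in range(len(series)):
        for name, xy in ((INDEX_TIP, series.index_xy), (THUMB_TIP, series.thumb_xy)):
            if np.all(np.isfinite(xy[k])):
                rows.append(
                    (int(series.frame_index[k]), float(series.time_s[k]), name,
                     float(xy[k, 0]), float(xy[k, 1]),
                     float(series.confidence[k]) if np.isfinite(series.confidence[k]) else "")
                )
    df = pd.DataFrame(rows, columns=["frame", "time_s", "landmark", "x", "y", "confidence"])
    df.to_csv(path, index=False)
    meta = {"fps": series.fps, "hand_label": series.hand_label}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_landmark_table(path: str | Path, fps: float | None = None,
                        hand_label: str | None = None,
                        clamp: bool = False) -> LandmarkSeries:
    """Read the landmark CSV dialect into a validated :class:`LandmarkSeries`.

    Frames where either fingertip row is absent are flagged as dropped.
    Coordinates outside [0, 1] raise a :class:`FormatError` unless ``clamp``
    is set, in which case they are clamped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such landmark table: {path}")
    df = pd.read_csv(path)
    required = {"frame", "time_s", "landmark", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"landmark table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    unknown = set(df["landmark"].unique()) - set(_KNOWN_LANDMARKS)
    if unknown:
        raise FormatError(f"unknown landmark ids: {sorted(unknown)}")
    bad = (df[["x", "y"]].to_numpy() < 0) | (df[["x", "y"]].to_numpy() > 1)
    if bad.any():
        if clamp:
            warnings.warn("coordinates outside [0,1] clamped", stacklevel=2)
            df[["x", "y"]] = df[["x", "y"]].clip(0.0, 1.0)
        else:
            raise FormatError("coordinates outside [0,1]; pass clamp=True to coerce")

    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if fps is None:
        fps = meta.get("fps")
    if fps is None:
        # fall back to the median frame interval
        t_by_frame = df.drop_duplicates("frame").sort_values("frame")["time_s"].to_numpy()
        if t_by_frame.size < 2:
            raise FormatError("fps not given and cannot be inferred from a single frame")
        fps = 1.0 / float(np.median(np.diff(t_by_frame)))
    if hand_label is None:
        hand_label = meta.get("hand_label", "most_affected")

    frames = np.sort(df["frame"].unique())
    if np.any(np.diff(frames) <= 0):
        raise FormatError("frame indices must be strictly increasing")
    n = frames.size
    index_xy = np.full((n, 2), np.nan)
    thumb_xy = np.full((n, 2), np.nan)
    conf = np.full(n, np.nan)
    time_s = np.full(n, np.nan)
    pos = {int(f): k for k, f in enumerate(frames)}
    has_conf = "confidence" in df.columns
    for row in df.itertuples(index=False):
        k = pos[int(row.frame)]
        time_s[k] = row.time_s
        target = index_xy if row.landmark == INDEX_TIP else thumb_xy
        if np.all(np.isfinite(target[k])):
            raise FormatError(f"duplicate {row.landmark} row for frame {row.frame}")
        target[k] = (row.x, row.y)
        if has_conf and np.isfinite(row.confidence):
            conf[k] = row.confidence if np.isnan(conf[k]) else min(conf[k], row.confidence)
    dropped = ~(np.all(np.isfinite(index_xy), axis=1) & np.all(np.isfinite(thumb_xy), axis=1))
    return LandmarkSeries(
        frame_index=frames.astype(int),
        time_s=time_s,
        index_xy=index_xy,
        thumb_xy=thumb_xy,
        confidence=conf,
        dropped=dropped,
        fps=float(fps),
        hand_label=hand_label,
    )


def compute_distance_waveform(series: LandmarkSeries) -> DistanceWaveform:
    """Euclidean index–thumb aperture per frame.

    Dropped frames are excluded from the trace; the resulting time gaps are
    visible to QC through the series itself.  Time is taken from
    ``frame_index / fps`` so that the trace is anchored to the video clock.
    """
    if len(series) == 0:
        raise InvalidArgumentError("empty landmark series")
    keep = ~series.dropped
    if not np.any(keep):
        raise InvalidArgumentError("all frames dropped; no aperture trace")
    delta = series.index_xy[keep] - series.thumb_xy[keep]
    d = np.hypot(delta[:, 0], delta[:, 1])
    t = series.frame_index[keep] / series.fps
    return DistanceWaveform(
        t=t, d=d, sample_rate_hz=series.fps,
        provenance=("distance:index-thumb euclidean",),
    )


def write_waveform_csv(w: DistanceWaveform, path: str | Path) -> None:
    """Write the ``time_s,d`` waveform dialect plus a JSON metadata sidecar."""
    pd.DataFrame({"time_s": w.t, "d": w.d}).to_csv(path, index=False)
    meta = {"sample_rate_hz": w.sample_rate_hz, "provenance": list(w.provenance)}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta))


def read_waveform_csv(path: str | Path) -> DistanceWaveform:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such waveform file: {path}")
    df = pd.read_csv(path)
    if not {"time_s", "d"}.issubset(df.columns):
        raise FormatError("waveform CSV must have columns time_s,d")
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        rate = float(meta["sample_rate_hz"])
        prov = tuple(meta.get("provenance", ()))
    else:
        t = df["time_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 0.0
        prov = ()
    return DistanceWaveform(
        t=df["time_s"].to_numpy(float), d=df["d"].to_numpy(float),
        sample_rate_hz=rate, provenance=prov,
    )
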
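"""Recordings, electrode layouts, analysis windows and seizure-interval labels.

Voltage data are held as a plain ``(n_samples, n_channels)`` float array in
microvolts together with a sampling rate and seizure onset/offset annotations.
Electrode geometry lives in :class:`ElectrodeLayout`: 2D positions in
millimetres plus an optional precomputed distance matrix (for example geodesic
distances along a cortical surface) that, when present, overrides Euclidean
distances.

Conventions used throughout the package: space in mm, time in s; seizure time
is normalised so onset maps to 0 and termination to 1; a sliding-window
estimate is timestamped at its window *centre*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "Recording",
    "AnalysisWindow",
    "INTERVALS",
    "SchemaError",
    "ValidationError",
    "CoverageError",
    "micro_layout",
    "macro_layout",
    "pair_distance",
    "make_windows",
    "assign_interval",
    "load_recording",
    "save_recording",
    "load_layout",
    "save_layout",
]

#: Seizure intervals on the normalised time axis (onset=0, termination=1).
#: ``Middle`` deliberately overlaps both ``Early`` and ``Late``.  Ranges are
#: half-open except ``Late`` which is closed at 1.
INTERVALS: dict[str, tuple[float, float]] = {
    "Pre": (-0.5, 0.0),
    "Early": (0.0, 0.5),
    "Middle": (0.25, 0.75),
    "Late": (0.5, 1.0),
}


class SchemaError(ValueError):
    """Recording and layout files disagree (channel count, unknown ids...)."""


class ValidationError(ValueError):
    """Data fail an invariant (non-finite samples, bad distance matrix...)."""


class CoverageError(ValueError):
    """Recording does not span the time range an operation needs."""


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode ids, spatial scale, 2D positions and optional distances.

    Parameters
    ----------
    ids : sequence of str
        One label per electrode.
    scale : {"micro", "macro"}
        Spatial scale of the array (0.4 mm pitch microelectrode grid vs
        ~1 cm pitch clinical macroelectrodes).
    positions : (n, 2) array
        Electrode coordinates in mm.
    distance_matrix : (n, n) array, optional
        Precomputed pairwise distances in mm (e.g. geodesic).  Overrides
        Euclidean distances when present.
    """

    ids: tuple[str, ...]
    scale: str
    positions: np.ndarray
    distance_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate electrode ids in layout")
        if self.scale not in ("micro", "macro", "mixed"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(ids), 2):
            raise ValidationError(
                f"positions shape {pos.shape} does not match {len(ids)} ids"
            )
        if not np.all(np.isfinite(pos)):
            raise ValidationError("electrode positions must be finite")
        object.__setattr__(self, "positions", pos)
        if self.distance_matrix is not None:
            dm = np.asarray(self.distance_matrix, dtype=float)
            n = len(ids)
            if dm.shape != (n, n):
                raise ValidationError("distance matrix shape mismatch")
            if not np.allclose(dm, dm.T):
                raise ValidationError("distance matrix must be symmetric")
            if np.any(np.diag(dm) != 0):
                raise ValidationError("distance matrix diagonal must be zero")
            if np.any(dm < 0):
                raise ValidationError("distances must be non-negative")
            object.__setattr__(self, "distance_matrix", dm)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, electrode_id: str) -> int:
        try:
            return self.ids.index(electrode_id)
        except ValueError:
            raise KeyError(f"unknown electrode id {electrode_id!r}") from None

    def distance(self, a: str, b: str) -> float:
        """Pairwise distance in mm (distance matrix if present, else Euclidean)."""
        ia, ib = self.index(a), self.index(b)
        if self.distance_matrix is not None:
            return float(self.distance_matrix[ia, ib])
        return float(np.linalg.norm(self.positions[ia] - self.positions[ib]))


def micro_layout(n_side: int = 10, pitch_mm: float = 0.4) -> ElectrodeLayout:
    """Regular microelectrode-array grid; defaults give the 10x10, 0.4 mm array."""
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="xy")
    pos = np.column_stack([xs.ravel() * pitch_mm, ys.ravel() * pitch_mm])
    ids = tuple(f"m{k:02d}" for k in range(n_side * n_side))
    return ElectrodeLayout(ids=ids, scale="micro", positions=pos)


def macro_layout(n_side: int = 8, pitch_mm: float = 10.0) -> ElectrodeLayout:
    """Regular clinical macroelectrode grid; defaults give an 8x8, 1 cm grid."""
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side), indexing="xy")
    pos = np.column_stack([xs.ravel() * pitch_mm, ys.ravel() * pitch_mm])
    ids = tuple(f"M{k:02d}" for k in range(n_side * n_side))
    return ElectrodeLayout(ids=ids, scale="macro", positions=pos)


def pair_distance(layout: ElectrodeLayout, a: str, b: str) -> float:
    """Distance in mm between electrodes ``a`` and ``b`` of ``layout``."""
    return layout.distance(a, b)


@dataclass
class Recording:
    """Multichannel voltage time series with seizure annotations.

    ``samples`` is ``(n_samples, n_channels)`` in µV, channel order matching
    ``layout.ids``; ``onset``/``offset`` are seizure start/end in seconds
    relative to the first sample; ``t0`` is the time of the first sample.
    """

    samples: np.ndarray
    rate: float
    onset: float
    offset: float
    layout: ElectrodeLayout
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a (time, channel) matrix")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.samples.shape[1] != len(self.layout):
            raise SchemaError(
                f"recording has {self.samples.shape[1]} channels but layout "
                f"has {len(self.layout)} electrodes"
            )
        bad = ~np.isfinite(self.samples)
        if bad.any():
            ch = int(np.argmax(bad.any(axis=0)))
            raise ValidationError(
                f"non-finite samples in channel {self.layout.ids[ch]!r}"
            )
        if not (self.t0 <= self.onset < self.offset <= self.t_end):
            raise ValidationError(
                f"need t0 <= onset < offset <= duration, got t0={self.t0}, "
                f"onset={self.onset}, offset={self.offset}, end={self.t_end}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def channel(self, electrode_id: str) -> np.ndarray:
        return self.samples[:, self.layout.index(electrode_id)]

    def segment(self, start: float, length: float) -> np.ndarray:
        """Samples in ``[start, start+length)`` (seconds, absolute time)."""
        i0 = int(round((start - self.t0) * self.rate))
        i1 = i0 + int(round(length * self.rate))
        if i0 < 0 or i1 > self.n_samples:
            raise CoverageError(
                f"segment [{start}, {start + length}) s outside recording "
                f"[{self.t0}, {self.t_end}) s"
            )
        return self.samples[i0:i1]

    def normalized_time(self, t: float) -> float:
        return (t - self.onset) / (self.offset - self.onset)


@dataclass(frozen=True)
class AnalysisWindow:
    """One sliding analysis window; timestamped at its centre."""

    start: float
    length: float = 10.0
    normalized_time: float = 0.0

    @property
    def center(self) -> float:
        return self.start + self.length / 2.0

    @property
    def end(self) -> float:
        return self.start + self.length


def make_windows(
    rec: Recording,
    length: float = 10.0,
    step: float = 1.0,
    pre_duration: float = 60.0,
) -> list[AnalysisWindow]:
    """Sliding analysis windows covering the pre-seizure and seizure span.

    Windows of ``length`` seconds step by ``step`` seconds (defaults: 10 s
    windows, 9 s overlap), beginning ``pre_duration`` seconds before seizure
    onset and ending at seizure termination (the last window ends at or before
    ``rec.offset``).  Each window carries the normalised seizure time of its
    centre.

    Raises
    ------
    CoverageError
        If the recording does not span ``[onset - pre_duration, offset]``.
    """
    first = rec.onset - pre_duration
    if first < rec.t0 - 1e-9 or rec.offset > rec.t_end + 1e-9:
        raise CoverageError(
            f"recording [{rec.t0}, {rec.t_end}) s does not cover required "
            f"span [{first}, {rec.offset}] s"
        )
    starts = []
    s = first
    while s + length <= rec.offset + 1e-9:
        starts.append(s)
        s += step
    if not starts:
        raise CoverageError("seizure span shorter than one analysis window")
    return [
        AnalysisWindow(
            start=s,
            length=length,
            normalized_time=rec.normalized_time(s + length / 2.0),
        )
        for s in starts
    ]


def assign_interval(normalized_time: float) -> set[str]:
    """Interval labels containing a normalised time (may be empty or plural)."""
    out = set()
    for name, (lo, hi) in INTERVALS.items():
        closed_right = name == "Late"
        if lo <= normalized_time < hi or (closed_right and normalized_time == hi):
            out.add(name)
    return out


# ---------------------------------------------------------------------------
# File I/O.  A recording on disk is a delimited text matrix (one row per
# sample) or an .npz container, plus a JSON sidecar with rate/onset/offset
# and channel ids; a layout is a JSON document.
# ---------------------------------------------------------------------------


def save_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    doc = {
        "ids": list(layout.ids),
        "scale": layout.scale,
        "x_mm": layout.positions[:, 0].tolist(),
        "y_mm": layout.positions[:, 1].tolist(),
    }
    if layout.distance_matrix is not None:
        doc["distance_matrix"] = layout.distance_matrix.tolist()
    Path(path).write_text(json.dumps(doc))


def load_layout(path: str | Path) -> ElectrodeLayout:
    doc = json.loads(Path(path).read_text())
    dm = doc.get("distance_matrix")
    return ElectrodeLayout(
        ids=tuple(doc["ids"]),
        scale=doc["scale"],
        positions=np.column_stack([doc["x_mm"], doc["y_mm"]]),
        distance_matrix=None if dm is None else np.asarray(dm, float),
    )


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write samples (+ sidecar metadata) next to ``path``.

    ``.npz`` keeps float64 samples bit-exactly; any other suffix writes a
    delimited text matrix with full float precision.
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, samples=rec.samples)
    else:
        np.savetxt(path, rec.samples, delimiter="\t", fmt="%.17g")
    sidecar = {
        "rate": rec.rate,
        "onset": rec.onset,
        "offset": rec.offset,
        "t0": rec.t0,
        "channels": list(rec.layout.ids),
        "units": "uV",
        "meta": rec.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_recording(path: str | Path, layout_path: str | Path) -> Recording:
    """Load a recording matrix + JSON sidecar and match channels to a layout.

    Channels are matched to layout electrodes by id; order in the file may
    differ from layout order.
    """
    path = Path(path)
    layout = load_layout(layout_path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if path.suffix == ".npz":
        with np.load(path) as z:
            samples = np.asarray(z["samples"], dtype=float)
    else:
        samples = np.loadtxt(path, delimiter="\t", ndmin=2)
    channels = [str(c) for c in sidecar["channels"]]
    if samples.shape[1] != len(channels):
        raise SchemaError(
            f"file has {samples.shape[1]} columns but sidecar lists "
            f"{len(channels)} channels"
        )
    if set(channels) != set(layout.ids):
        raise SchemaError("sidecar channel ids do not match layout ids")
    order = [channels.index(i) for i in layout.ids]
    samples = samples[:, order]
    return Recording(
        samples=samples,
        rate=float(sidecar["rate"]),
        onset=float(sidecar["onset"]),
        offset=float(sidecar["offset"]),
        t0=float(sidecar.get("t0", 0.0)),
        layout=layout,
        meta=dict(sidecar.get("meta", {})),
    )
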
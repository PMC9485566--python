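"""Shared data containers and their plain-text (CSV + JSON sidecar) round trips.

The package's in-memory currency is deliberately simple: numpy arrays wrapped
in small dataclasses.  Fluorescence traces and event rasters are cells x frames
matrices; current-clamp sweeps are (time, voltage, current) triples.  Every
container can be written to and read back from CSV with a JSON sidecar holding
acquisition metadata, so that external recordings in the same layout can enter
the pipeline at any stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CELL_LABELS = ("chat_pos", "chat_neg", "unknown")


def _as_2d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError(f"expected a cells x frames matrix, got ndim={a.ndim}")
    return a


def _default_ids(n: int, prefix: str = "cell") -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


@dataclass
class FluorescenceTraceSet:
    """Raw per-ROI fluorescence over frames (arbitrary fluorescence units).

    Parameters
    ----------
    F : array, cells x frames
        Mean ROI fluorescence per frame; must be non-negative.
    fps : float
        Acquisition rate, frames per second.
    cell_ids : sequence of str
    cell_labels : sequence of str
        One of ``chat_pos``, ``chat_neg``, ``unknown`` per cell.
    background : None, scalar, 1-D (per cell) or 2-D (per cell per frame)
        Annulus background fluorescence; used as F0 when available.
    """

    F: np.ndarray
    fps: float
    cell_ids: list[str] = field(default_factory=list)
    cell_labels: list[str] = field(default_factory=list)
    background: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.F = _as_2d(self.F)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if np.any(self.F < 0):
            raise ValueError("fluorescence must be non-negative")
        n = self.F.shape[0]
        if not self.cell_ids:
            self.cell_ids = _default_ids(n)
        if not self.cell_labels:
            self.cell_labels = ["unknown"] * n
        if len(self.cell_ids) != n or len(self.cell_labels) != n:
            raise ValueError("cell_ids/cell_labels length must match F rows")
        for lab in self.cell_labels:
            if lab not in CELL_LABELS:
                raise ValueError(f"unknown cell label {lab!r}")
        if self.background is not None and not np.isscalar(self.background):
            self.background = np.asarray(self.background, dtype=float)

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class DffTraceSet:
    """ΔF/F0 traces and their time derivative d(ΔF/F0)/dt (units 1/s)."""

    dff: np.ndarray
    derivative: np.ndarray
    fps: float
    cell_ids: list[str] = field(default_factory=list)
    cell_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dff = _as_2d(self.dff)
        self.derivative = _as_2d(self.derivative)
        if self.dff.shape != self.derivative.shape:
            raise ValueError("dff and derivative shapes differ")
        if not self.cell_ids:
            self.cell_ids = _default_ids(self.dff.shape[0])
        if not self.cell_labels:
            self.cell_labels = ["unknown"] * self.dff.shape[0]

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]


@dataclass
class EventRaster:
    """Binary cells x frames activity matrix (a raster plot).

    Rows are cells/ROIs, columns movie frames; ``A[i, t] == 1`` marks inferred
    firing of cell *i* in frame *t*.
    """

    A: np.ndarray
    fps: float
    cell_ids: list[str] = field(default_factory=list)
    cell_labels: list[str] = field(default_factory=list)
    condition_tag: str = ""

    def __post_init__(self) -> None:
        A = _as_2d(self.A)
        if not np.isin(A, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.A = A.astype(np.uint8)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        n = self.A.shape[0]
        if not self.cell_ids:
            self.cell_ids = _default_ids(n)
        if not self.cell_labels:
            self.cell_labels = ["unknown"] * n

    @property
    def n_cells(self) -> int:
        return self.A.shape[0]

    @property
    def n_frames(self) -> int:
        return self.A.shape[1]

    def event_frames(self, i: int) -> np.ndarray:
        """Frame indices with activity for cell ``i``."""
        return np.flatnonzero(self.A[i])

    def total_events(self) -> int:
        return int(self.A.sum())

    def subset(self, cells: Sequence[int] | None = None,
               frames: slice | None = None,
               condition_tag: str | None = None) -> "EventRaster":
        idx = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        fr = frames if frames is not None else slice(None)
        return EventRaster(
            self.A[idx][:, fr], self.fps,
            [self.cell_ids[i] for i in idx],
            [self.cell_labels[i] for i in idx],
            self.condition_tag if condition_tag is None else condition_tag,
        )


@dataclass
class StepProtocol:
    """A square current step: ``amplitude_pA`` between ``t_on`` and ``t_off`` (s)."""

    amplitude_pA: float
    t_on: float
    t_off: float

    def current(self, t: np.ndarray) -> np.ndarray:
        I = np.zeros_like(t)
        I[(t >= self.t_on) & (t < self.t_off)] = self.amplitude_pA
        return I


@dataclass
class SweepRecording:
    """One current-clamp sweep: time (s), voltage (mV), injected current (pA)."""

    t: np.ndarray
    V: np.ndarray
    I: np.ndarray
    fs: float
    step: StepProtocol | None = None
    holding_mV: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if not (len(self.t) == len(self.V) == len(self.I)):
            raise ValueError("t, V, I must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs


# ---------------------------------------------------------------------------
# CSV / JSON round trips
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_traces(ts: FluorescenceTraceSet, path: str | Path,
                 metadata: dict | None = None) -> None:
    """Traces CSV: rows = cells, columns = frames, header = frame times (s)."""
    path = Path(path)
    df = pd.DataFrame(ts.F, index=pd.Index(ts.cell_ids, name="cell_id"),
                      columns=[f"{t:.6f}" for t in ts.frame_times])
    df.insert(0, "label", ts.cell_labels)
    df.to_csv(path)
    meta = {"fps": ts.fps}
    if ts.background is not None:
        bg = ts.background
        meta["background"] = bg if np.isscalar(bg) else np.asarray(bg).tolist()
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_traces(path: str | Path) -> FluorescenceTraceSet:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    labels = df.pop("label").tolist()
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    fps = meta.get("fps")
    if fps is None:
        ft = df.columns.astype(float).to_numpy()
        fps = 1.0 / np.mean(np.diff(ft)) if len(ft) > 1 else 1.0
    bg = meta.get("background")
    if isinstance(bg, list):
        bg = np.asarray(bg, dtype=float)
    return FluorescenceTraceSet(df.to_numpy(float), float(fps),
                                df.index.astype(str).tolist(), labels, bg)


def write_raster(raster: EventRaster, path: str | Path,
                 metadata: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(raster.A, index=pd.Index(raster.cell_ids, name="cell_id"),
                      columns=[str(j) for j in range(raster.n_frames)])
    df.insert(0, "label", raster.cell_labels)
    df.to_csv(path)
    meta = {"fps": raster.fps, "condition_tag": raster.condition_tag}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_raster(path: str | Path) -> EventRaster:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    labels = df.pop("label").tolist()
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    return EventRaster(df.to_numpy(float), float(meta.get("fps", 1.0)),
                       df.index.astype(str).tolist(), labels,
                       meta.get("condition_tag", ""))


def write_sweep(sweep: SweepRecording, path: str | Path,
                metadata: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": sweep.t, "voltage_mV": sweep.V,
                  "current_pA": sweep.I}).to_csv(path, index=False)
    meta: dict = {"fs": sweep.fs}
    if sweep.step is not None:
        meta["step"] = {"amplitude_pA": sweep.step.amplitude_pA,
                        "t_on": sweep.step.t_on, "t_off": sweep.step.t_off}
    if sweep.holding_mV is not None:
        meta["holding_mV"] = sweep.holding_mV
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_sweep(path: str | Path) -> SweepRecording:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    t = df["time_s"].to_numpy()
    fs = meta.get("fs")
    if fs is None:
        fs = 1.0 / np.mean(np.diff(t)) if len(t) > 1 else 1.0
    step = None
    if "step" in meta:
        s = meta["step"]
        step = StepProtocol(s["amplitude_pA"], s["t_on"], s["t_off"])
    return SweepRecording(t, df["voltage_mV"].to_numpy(),
                          df["current_pA"].to_numpy(), float(fs), step,
                          meta.get("holding_mV"))
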
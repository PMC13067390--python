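"""Static and sliding-window functional connectivity from ROI time series.

Functional connectivity (FC) is the Fisher z-transformed Pearson correlation
between regional BOLD time courses.  Static FC uses the full scan; dynamic FC
recomputes the correlation inside overlapping windows stepped one repetition
time (TR) at a time, producing one connectivity matrix per window.  A
participant-level head-motion rule based on framewise displacement (FD)
decides which subjects enter the analysis at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: correlations are clipped to +/-(1 - CLIP_EPS) before atanh so z stays finite
CLIP_EPS = 1e-7

#: FD quality control: a frame is "high motion" at or above this displacement (mm)
FD_THRESHOLD_MM = 0.5
#: subjects fail QC when the high-motion fraction strictly exceeds this
FD_MAX_FRACTION = 0.075


@dataclass
class RoiTimeSeries:
    """One subject's parcellated signal: frames x ROIs with TR metadata."""

    subject_id: str
    tr_seconds: float
    data: np.ndarray  # (n_frames, n_rois)
    roi_names: Sequence[str] = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D frames x ROIs array")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError(f"subject {self.subject_id}: non-finite values in time series")
        if self.roi_names is None:
            self.roi_names = [f"roi{i:03d}" for i in range(self.data.shape[1])]
        elif len(self.roi_names) != self.data.shape[1]:
            raise ValueError("roi_names length must match the number of columns")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    values: np.ndarray
    roi_names: Sequence[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("FC matrix contains non-finite values")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        v = (v + v.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class WindowedFC:
    """Sliding-window connectivity: one FCMatrix per window, step 1 TR."""

    window_trs: int
    matrices: list  # list[FCMatrix]
    window_start_frames: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.matrices)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -(1.0 - CLIP_EPS), 1.0 - CLIP_EPS))


def static_fc(ts: RoiTimeSeries) -> FCMatrix:
    """Whole-scan Pearson correlation, Fisher z-transformed.

    Correlations are clipped to +/-(1 - 1e-7) before atanh so that perfectly
    (anti-)correlated column pairs map to a finite ceiling/floor rather than
    +/-inf.  The diagonal is set to 0 (self-connections are excluded
    everywhere downstream).
    """
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(str(ts.roi_names[i]) for i in dead)
        raise ValueError(f"subject {ts.subject_id}: constant ROI column(s): {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    z = _fisher_z(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FCMatrix(z, roi_names=ts.roi_names)


def _window_correlations(data: np.ndarray, window: int) -> np.ndarray:
    """Pearson r inside every length-`window` contiguous block, step 1 frame.

    Returns (n_windows, n_rois, n_rois).  Batched over windows with a strided
    view; each window is demeaned independently (implicit in Pearson r).
    """
    n_frames, n_rois = data.shape
    n_win = n_frames - window + 1
    windows = np.lib.stride_tricks.sliding_window_view(data, window, axis=0)
    # sliding_window_view yields (n_win, n_rois, window); demean along time
    windows = windows - windows.mean(axis=2, keepdims=True)
    cov = np.einsum("wit,wjt->wij", windows, windows, optimize=True)
    sd = np.sqrt(np.einsum("wii->wi", cov))
    denom = sd[:, :, None] * sd[:, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    assert r.shape == (n_win, n_rois, n_rois)
    return r


def sliding_window_fc(ts: RoiTimeSeries, window_trs: int) -> WindowedFC:
    """Rectangular sliding-window FC with step size 1 TR.

    Window count is ``n_frames - window_trs + 1``.  No taper is applied; each
    window's correlation matrix is Fisher z-transformed exactly like the
    static one.
    """
    if window_trs < 2:
        raise ValueError("window_trs must be at least 2")
    if window_trs >= ts.n_frames + 1:
        raise ValueError(
            f"window of {window_trs} TRs exceeds the series length ({ts.n_frames} frames)"
        )
    r = _window_correlations(ts.data, window_trs)
    if not np.isfinite(r).all():
        raise ValueError(
            f"subject {ts.subject_id}: a window contains a constant ROI signal"
        )
    z = _fisher_z(r)
    mats = []
    for w in range(z.shape[0]):
        m = (z[w] + z[w].T) / 2.0
        np.fill_diagonal(m, 0.0)
        mats.append(FCMatrix(m, roi_names=ts.roi_names))
    starts = np.arange(len(mats))
    return WindowedFC(
        window_trs=window_trs,
        matrices=mats,
        window_start_frames=starts,
        tr_seconds=ts.tr_seconds,
        subject_id=ts.subject_id,
    )


def window_seconds(window_trs: int, tr_seconds: float) -> float:
    """Window duration in seconds (reported to 2 decimals): window_trs * TR."""
    if window_trs <= 0 or tr_seconds <= 0:
        raise ValueError("window_trs and tr_seconds must be positive")
    return round(window_trs * tr_seconds, 2)


@dataclass
class QCResult:
    subject_id: str
    passed: bool
    high_motion_fraction: float
    median_fd: float


def qc_fd(
    fd_series: np.ndarray,
    fd_threshold_mm: float = FD_THRESHOLD_MM,
    max_fraction: float = FD_MAX_FRACTION,
    subject_id: str = "",
) -> QCResult:
    """Participant-level motion QC.

    A subject fails when *more than* ``max_fraction`` of frames have FD at or
    above ``fd_threshold_mm`` (default: > 7.5% of frames with FD >= 0.5 mm).
    The boundary fraction itself passes.  The median FD is returned for
    group-level motion comparisons.
    """
    fd = np.asarray(fd_series, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD series")
    if (fd < 0).any():
        raise ValueError("FD values must be nonnegative")
    frac = float(np.mean(fd >= fd_threshold_mm))
    return QCResult(
        subject_id=subject_id,
        passed=frac <= max_fraction,
        high_motion_fraction=frac,
        median_fd=float(np.median(fd)),
    )


# ---------------------------------------------------------------------------
# delimited-text I/O (same dialect the synthetic generator writes)
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, subject_id: str, tr_seconds: float) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(
        subject_id=subject_id,
        tr_seconds=tr_seconds,
        data=df.to_numpy(dtype=float),
        roi_names=list(df.columns),
    )


def write_fc_matrix(fc: FCMatrix, path: str | Path) -> None:
    names = fc.roi_names or [f"roi{i:03d}" for i in range(fc.n_rois)]
    pd.DataFrame(fc.values, columns=names).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_fc_matrix(path: str | Path) -> FCMatrix:
    df = pd.read_csv(path, sep="\t")
    return FCMatrix(df.to_numpy(dtype=float), roi_names=list(df.columns))


def write_windowed_fc(wfc: WindowedFC, path: str | Path) -> None:
    """Stacked long format: one row per (window, ROI-row) with a window column."""
    names = wfc.matrices[0].roi_names or [f"roi{i:03d}" for i in range(wfc.matrices[0].n_rois)]
    blocks = []
    for w, m in enumerate(wfc.matrices):
        df = pd.DataFrame(m.values, columns=names)
        df.insert(0, "window", w)
        blocks.append(df)
    pd.concat(blocks, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_windowed_fc(path: str | Path, window_trs: int, tr_seconds: float, subject_id: str = "") -> WindowedFC:
    df = pd.read_csv(path, sep="\t")
    names = [c for c in df.columns if c != "window"]
    mats = []
    for w, block in df.groupby("window", sort=True):
        mats.append(FCMatrix(block[names].to_numpy(dtype=float), roi_names=names))
    return WindowedFC(
        window_trs=window_trs,
        matrices=mats,
        window_start_frames=np.arange(len(mats)),
        tr_seconds=tr_seconds,
        subject_id=subject_id,
    )
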
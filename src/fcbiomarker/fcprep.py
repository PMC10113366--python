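"""ROI time series → canonical FC feature vector.

The feature-extraction chain for one subject:

1. band-pass filter the region time courses (default 0.008–0.1 Hz,
   zero-phase second-order Butterworth);
2. linearly regress out nuisance signals (tissue confounds plus the six
   rigid-body motion parameters);
3. scrub: censor every frame whose framewise displacement (FD) exceeds
   0.5 mm, computed Power-style as the sum of absolute frame-to-frame
   translation changes plus rotation changes scaled by a 50 mm head radius;
4. pairwise Pearson correlation over the retained frames (137 regions give
   9316 edges);
5. Fisher r-to-z transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .dataset import edge_pairs, n_edges

__all__ = [
    "ROITimeSeries",
    "MotionTrace",
    "FCVector",
    "FCPrepParams",
    "PreprocError",
    "bandpass",
    "regress_nuisance",
    "framewise_displacement",
    "scrub",
    "compute_fc",
    "fisher_z",
    "fc_pipeline",
]

MIN_FRAMES_FOR_FC = 8


class PreprocError(ValueError):
    pass


@dataclass
class ROITimeSeries:
    """frames × regions signal matrix with its sampling interval (s)."""

    data: np.ndarray
    tr: float
    region_names: list | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreprocError(f"time series must be 2-D, got shape {self.data.shape}")
        if self.data.shape[1] < 2:
            raise PreprocError("need at least 2 regions")
        if not np.all(np.isfinite(self.data)):
            raise PreprocError("time series contains missing/non-finite values")
        if self.tr <= 0:
            raise PreprocError(f"tr must be positive, got {self.tr}")
        if self.region_names is None:
            self.region_names = [f"R{k:03d}" for k in range(self.data.shape[1])]
        elif len(self.region_names) != self.data.shape[1]:
            raise PreprocError("region_names length mismatch")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """frames × 6 realignment parameters: x, y, z (mm), pitch, roll, yaw (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise PreprocError(
                f"motion trace must have 6 columns, got shape {self.params.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class FCVector:
    """Canonical-ordered vector of pairwise edge values.

    ``values[e]`` is the value of edge e in row-major strict-upper-triangle
    order; ``scale`` is ``"pearson_r"`` or ``"fisher_z"``.
    """

    values: np.ndarray
    scale: str
    n_regions: int
    retained_frames: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("pearson_r", "fisher_z"):
            raise PreprocError(f"unknown scale {self.scale!r}")
        if self.values.shape != (n_edges(self.n_regions),):
            raise PreprocError(
                f"expected {n_edges(self.n_regions)} edge values for "
                f"{self.n_regions} regions, got {self.values.shape}"
            )
        if self.scale == "pearson_r" and np.any(np.abs(self.values) > 1 + 1e-12):
            raise PreprocError("pearson_r values must lie in [-1, 1]")

    @property
    def n_edges(self) -> int:
        return self.values.shape[0]

    def edge_pairs(self) -> np.ndarray:
        return edge_pairs(self.n_regions)


@dataclass
class FCPrepParams:
    low_hz: float = 0.008
    high_hz: float = 0.1
    fd_threshold_mm: float = 0.5
    fd_radius_mm: float = 50.0
    filter_order: int = 2
    scrub_neighbors: int = 0   # frames to censor on each side of a flagged frame


def bandpass(ts: ROITimeSeries, low_hz: float = 0.008, high_hz: float = 0.1,
             order: int = 2) -> ROITimeSeries:
    """Zero-phase Butterworth band-pass of every region's time course.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude response is the squared Butterworth response and the
    phase is exactly zero.  The series is demeaned first; DC lies outside any
    valid band in any case.
    """
    nyq = 0.5 / ts.tr
    if not (0.0 < low_hz < high_hz < nyq):
        raise PreprocError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq:.4g} Hz at tr={ts.tr} s)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="band", fs=1.0 / ts.tr,
                        output="sos")
    x = ts.data - ts.data.mean(axis=0)
    out = signal.sosfiltfilt(sos, x, axis=0)
    return ROITimeSeries(out, ts.tr, list(ts.region_names))


def regress_nuisance(ts: ROITimeSeries, confounds: np.ndarray | None) -> ROITimeSeries:
    """Residualise every region on [intercept | confounds] by least squares.

    Rank-deficient confound sets are tolerated (minimum-norm solution); the
    residuals are orthogonal to every confound column by construction.  With
    no confounds this reduces to removing each region's mean.
    """
    if confounds is None or (hasattr(confounds, "shape") and np.size(confounds) == 0):
        X = np.ones((ts.n_frames, 1))
    else:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != ts.n_frames:
            raise PreprocError(
                f"confounds have {confounds.shape[0]} rows but series has "
                f"{ts.n_frames} frames"
            )
        X = np.column_stack([np.ones(ts.n_frames), confounds])
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return ROITimeSeries(resid, ts.tr, list(ts.region_names))


def framewise_displacement(motion: MotionTrace | np.ndarray,
                           radius_mm: float = 50.0) -> np.ndarray:
    """Per-frame head-motion summary, in mm.

    FD(0) = 0 (no predecessor); FD(t) = sum of |Δ translation| over x, y, z
    plus ``radius_mm`` times the sum of |Δ rotation| over pitch, roll, yaw —
    rotations converted to arc length at the given head radius.
    """
    if not isinstance(motion, MotionTrace):
        motion = MotionTrace(motion)
    d = np.abs(np.diff(motion.params, axis=0))
    fd = np.zeros(motion.n_frames)
    if motion.n_frames > 1:
        fd[1:] = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return fd


def scrub(ts: ROITimeSeries, fd: np.ndarray, threshold_mm: float = 0.5,
          neighbors: int = 0):
    """Censor frames with FD strictly above threshold.

    Returns ``(scrubbed series, retained-frame boolean mask)``.  The mask has
    the original length; ``neighbors`` > 0 additionally censors that many
    frames on each side of every flagged frame (off by default).
    """
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (ts.n_frames,):
        raise PreprocError(f"fd length {fd.shape} does not match {ts.n_frames} frames")
    bad = fd > threshold_mm
    if neighbors > 0:
        flagged = np.flatnonzero(bad)
        for t in flagged:
            bad[max(0, t - neighbors):t + neighbors + 1] = True
    mask = ~bad
    if not mask.any():
        raise PreprocError("insufficient frames for correlation: all frames scrubbed")
    return ROITimeSeries(ts.data[mask], ts.tr, list(ts.region_names)), mask


def compute_fc(ts: ROITimeSeries) -> FCVector:
    """Pairwise Pearson correlations over all region pairs, canonical order."""
    if ts.n_frames < MIN_FRAMES_FOR_FC:
        raise PreprocError(
            f"insufficient frames for correlation: {ts.n_frames} < {MIN_FRAMES_FOR_FC}"
        )
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(ts.region_names[k] for k in dead[:5])
        raise PreprocError(f"zero-variance region(s): {names}")
    C = np.corrcoef(ts.data, rowvar=False)
    iu = np.triu_indices(ts.n_regions, k=1)
    values = np.clip(C[iu], -1.0, 1.0)
    return FCVector(values, scale="pearson_r", n_regions=ts.n_regions,
                    retained_frames=ts.n_frames)


def fisher_z(fc: FCVector) -> FCVector:
    """Variance-stabilising transform z = atanh(r), edge-wise."""
    if fc.scale != "pearson_r":
        raise PreprocError(f"fisher_z expects pearson_r input, got {fc.scale}")
    if np.any(np.abs(fc.values) >= 1.0):
        raise PreprocError(
            "fisher_z undefined at |r| = 1; check for duplicated or degenerate "
            "region time courses"
        )
    return FCVector(np.arctanh(fc.values), scale="fisher_z",
                    n_regions=fc.n_regions, retained_frames=fc.retained_frames)


def fc_pipeline(ts: ROITimeSeries, motion: MotionTrace | np.ndarray | None,
                confounds: np.ndarray | None,
                params: FCPrepParams | None = None) -> FCVector:
    """Full per-subject chain: band-pass → nuisance regression → scrub → r → z.

    ``confounds`` carries the tissue signals (white matter, CSF, global); the
    six motion parameters are appended as additional regressors when a motion
    trace is supplied, and the same trace drives FD-based scrubbing.
    """
    params = params or FCPrepParams()
    out = bandpass(ts, params.low_hz, params.high_hz, order=params.filter_order)
    cols = []
    if confounds is not None and np.size(confounds) > 0:
        cols.append(np.asarray(confounds, dtype=float).reshape(ts.n_frames, -1))
    if motion is not None:
        mt = motion if isinstance(motion, MotionTrace) else MotionTrace(motion)
        if mt.n_frames != ts.n_frames:
            raise PreprocError("motion trace frame count does not match time series")
        cols.append(mt.params)
    all_conf = np.column_stack(cols) if cols else None
    out = regress_nuisance(out, all_conf)
    if motion is not None:
        fd = framewise_displacement(motion, params.fd_radius_mm)
        out, _ = scrub(out, fd, params.fd_threshold_mm, params.scrub_neighbors)
    fc = compute_fc(out)
    return fisher_z(fc)
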
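"""Temporal cleaning of BOLD series.

The pipeline order is fixed and mirrors standard resting-state practice:
(1) discard lead-in volumes, (2) regress nuisance confounds (head motion,
white-matter and CSF signals, plus an intercept), (3) zero-phase band-pass
filter, by default 0.01-0.1 Hz.  Subjects with excessive head motion are
excluded, not individual frames.

Framewise displacement follows the Power convention: the sum of absolute
backward differences of the six realignment parameters, with rotations
converted to arc length on a 50 mm sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import Bold4D, SubjectRecord

HEAD_RADIUS_MM = 50.0
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class MotionSummary:
    mean_motion_mm: float
    max_fd_mm: float
    mean_fd_mm: float

    def __post_init__(self) -> None:
        if min(self.mean_motion_mm, self.max_fd_mm, self.mean_fd_mm) < 0:
            raise ValueError("motion summaries must be nonnegative")


def discard_initial_volumes(bold: Bold4D, n: int) -> Bold4D:
    """Drop the first ``n`` volumes (lead-in scans before equilibrium)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= bold.n_timepoints:
        raise ValueError(
            f"cannot discard {n} of {bold.n_timepoints} volumes; result would be empty"
        )
    if n == 0:
        return bold
    return Bold4D(values=bold.values[..., n:], tr_s=bold.tr_s, geometry=bold.geometry)


def framewise_displacement(motion, radius_mm: float = HEAD_RADIUS_MM) -> np.ndarray:
    """Power-style FD: sum |Delta translations| + r * sum |Delta rotations|.

    ``motion`` is a (T, 6) array or a DataFrame holding the columns
    ``trans_x..rot_z`` (translations mm, rotations rad).  FD of the first
    frame is 0 by convention; the output has one value per frame.
    """
    if isinstance(motion, pd.DataFrame):
        motion = motion[list(MOTION_COLUMNS)].to_numpy(dtype=float)
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (T, 6), got {motion.shape}")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters must be finite")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def motion_summary(motion, mean_motion_mm: float | None = None) -> MotionSummary:
    """Summarize a realignment-parameter table into QC scalars."""
    if isinstance(motion, pd.DataFrame):
        trans = motion[list(MOTION_COLUMNS[:3])].to_numpy(dtype=float)
    else:
        trans = np.asarray(motion, dtype=float)[:, :3]
    fd = framewise_displacement(motion)
    if mean_motion_mm is None:
        mean_motion_mm = float(np.mean(np.linalg.norm(trans, axis=1)))
    return MotionSummary(mean_motion_mm=mean_motion_mm,
                         max_fd_mm=float(fd.max()), mean_fd_mm=float(fd.mean()))


def expand_motion_24(confounds: pd.DataFrame) -> pd.DataFrame:
    """Friston-style 24-parameter expansion of the six motion columns
    (values, backward differences, and squares of both).  WM/CSF columns are
    passed through unchanged."""
    out = confounds.copy()
    for col in MOTION_COLUMNS:
        d = np.concatenate([[0.0], np.diff(confounds[col].to_numpy(dtype=float))])
        out[f"{col}_derivative"] = d
        out[f"{col}_sq"] = confounds[col].to_numpy(dtype=float) ** 2
        out[f"{col}_derivative_sq"] = d**2
    return out


def _design_matrix(confounds: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = list(confounds.columns)
    X = np.column_stack([np.ones(len(confounds)), confounds.to_numpy(dtype=float)])
    return X, ["intercept"] + cols


def _collinear_pairs(X: np.ndarray, names: list[str]) -> list[tuple[str, str]]:
    # name the offending columns for the error message
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    corr = (Xc / sd).T @ (Xc / sd) / len(X)
    pairs = []
    for i in range(1, corr.shape[0]):
        for j in range(i + 1, corr.shape[1]):
            if abs(corr[i, j]) > 1 - 1e-10:
                pairs.append((names[i], names[j]))
    return pairs


def regress_confounds(bold: Bold4D, confounds: pd.DataFrame) -> Bold4D:
    """Replace every voxel series by its least-squares residual against the
    confound columns plus an intercept.  Residuals are orthogonal to every
    regressor by construction."""
    if len(confounds) != bold.n_timepoints:
        raise ValueError(
            f"confound rows ({len(confounds)}) must equal volumes ({bold.n_timepoints})"
        )
    X, names = _design_matrix(confounds)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        pairs = _collinear_pairs(X, names)
        detail = ", ".join(f"{a}~{b}" for a, b in pairs) or "unidentified columns"
        raise ValueError(f"confound design is rank deficient (collinear: {detail})")
    flat = bold.values.reshape(-1, bold.n_timepoints)  # (V, T)
    beta, *_ = np.linalg.lstsq(X, flat.T, rcond=None)
    resid = flat.T - X @ beta  # (T, V)
    out = resid.T.reshape(bold.values.shape)
    return Bold4D(values=out, tr_s=bold.tr_s, geometry=bold.geometry)


def bandpass_sos(low_hz: float, high_hz: float, tr_s: float, order: int = 2):
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low ({low_hz}) < high ({high_hz})")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz must be below Nyquist {nyq:.4f} Hz")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(bold: Bold4D, low_hz: float = 0.01, high_hz: float = 0.1,
                    order: int = 2) -> Bold4D:
    """Zero-phase Butterworth band-pass along time (forward-backward, so the
    effective attenuation is the squared magnitude response).  Odd-reflection
    padding suppresses edge transients on short series."""
    sos = bandpass_sos(low_hz, high_hz, bold.tr_s, order=order)
    out = signal.sosfiltfilt(sos, bold.values, axis=-1, padtype="odd")
    return Bold4D(values=np.ascontiguousarray(out), tr_s=bold.tr_s, geometry=bold.geometry)


def bandpass_gain(freq_hz: float, low_hz: float, high_hz: float, tr_s: float,
                  order: int = 2) -> float:
    """Amplitude gain of the zero-phase filter at one frequency (squared
    single-pass magnitude); handy as an analytic oracle."""
    sos = bandpass_sos(low_hz, high_hz, tr_s, order=order)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=1.0 / tr_s)
    return float(np.abs(h[0]) ** 2)


def qc_filter_subjects(
    subjects: list[SubjectRecord], threshold_mm: float = 3.0, use_max_fd: bool = False,
    max_fd: dict[str, float] | None = None,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Partition subjects into (kept, excluded) by the head-motion rule.

    By default a subject is excluded when ``mean_motion_mm`` exceeds the
    threshold; with ``use_max_fd`` the decision uses a supplied per-subject
    maximum framewise displacement instead.
    """
    if not (threshold_mm > 0):
        raise ValueError("threshold_mm must be positive")
    kept, excluded = [], []
    for s in subjects:
        metric = (max_fd or {}).get(s.id, s.mean_motion_mm) if use_max_fd else s.mean_motion_mm
        (excluded if metric > threshold_mm else kept).append(s)
    return kept, excluded


def preprocess_bold(
    bold: Bold4D,
    confounds: pd.DataFrame,
    n_discard: int = 5,
    band: tuple[float, float] = (0.01, 0.1),
    motion_model: str = "6",
) -> Bold4D:
    """Full temporal cleaning: discard -> confound regression -> band-pass.

    ``confounds`` must cover the retained volumes only.  ``motion_model``
    "24" applies the Friston expansion of the motion columns before
    regression.
    """
    out = discard_initial_volumes(bold, n_discard)
    conf = confounds
    if motion_model == "24":
        conf = expand_motion_24(confounds)
    elif motion_model != "6":
        raise ValueError(f"motion_model must be '6' or '24', got {motion_model!r}")
    out = regress_confounds(out, conf)
    return bandpass_filter(out, band[0], band[1])
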
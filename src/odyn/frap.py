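"""Fluorescence recovery after photobleaching (FRAP) quantification.

A FRAP experiment bleaches a region (here, the whole Golgi area loaded with
fluorescent cholera toxin B) and monitors the return of fluorescence.  The
normalized recovery

    R(t) = (F(t) - F0) / (F_pre - F0)

with ``F_pre`` the prebleach mean and ``F0`` the first post-bleach sample,
rises toward the *mobile fraction* — the proportion of the fluorophore able
to exchange with the bleached region.  Recovery is modelled as a single
exponential ``F(t) = F0 + (F_inf - F0)(1 - exp(-t/tau))`` fitted over the
post-bleach samples; no diffusion-model interpretation is attempted.

No acquisition-bleaching or reference-ROI correction is applied by default
(monitoring used low-intensity illumination); :func:`fit_recovery` accepts an
optional pre-normalized curve should a caller apply one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import imaging_io

__all__ = [
    "FrapCurve", "FrapFit", "extract_roi_series", "detect_bleach",
    "recovery_percent", "fit_recovery", "plateau_reached",
    "read_curve_csv", "write_curve_csv",
]


@dataclass
class FrapCurve:
    """ROI mean intensity versus time, optionally with the bleach located.

    ``bleach_index`` is the index of the first post-bleach sample; samples
    before it are prebleach.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    bleach_index: int | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_s.shape != self.intensities.shape or self.times_s.ndim != 1:
            raise ValueError("times_s and intensities must be equal-length 1-D")
        if len(self.times_s) > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.bleach_index is not None:
            if not 1 <= self.bleach_index < len(self.times_s):
                raise ValueError("bleach_index must be >= 1 and inside the curve")

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def prebleach_mean(self) -> float:
        self._require_bleach()
        return float(self.intensities[: self.bleach_index].mean())

    @property
    def f0(self) -> float:
        """Post-bleach floor: the single sample at the bleach index."""
        self._require_bleach()
        return float(self.intensities[self.bleach_index])

    def _require_bleach(self) -> None:
        if self.bleach_index is None:
            raise ValueError("bleach_index not set; run detect_bleach first")


@dataclass
class FrapFit:
    """Exponential recovery fit.  ``mobile_fraction`` is clipped to [0, 1];
    the unclipped estimate is kept in ``mobile_fraction_raw``."""

    f_pre: float
    f0: float
    f_inf: float
    tau_s: float
    mobile_fraction: float
    mobile_fraction_raw: float
    residual_rms: float

    def as_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


def extract_roi_series(movie: imaging_io.Movie, roi: imaging_io.Roi) -> FrapCurve:
    """Per-frame mean intensity over the ROI; times from the movie calibration."""
    if not roi.contained_in(movie.frame_shape):
        raise ValueError(f"{roi} exceeds frame shape {movie.frame_shape}")
    ys, xs = roi.as_slices()
    series = movie.frames[:, ys, xs].reshape(movie.n_frames, -1).mean(axis=1)
    return FrapCurve(times_s=movie.times_s, intensities=series.astype(float))


def detect_bleach(curve: FrapCurve, min_drop_frac: float = 0.5) -> int:
    """Locate the bleach as the largest single-step intensity drop.

    The drop must exceed ``min_drop_frac`` of the running prebleach mean
    (the mean of all samples before the drop); otherwise the curve is deemed
    to contain no bleach and an error is raised.
    """
    x = curve.intensities
    if len(x) < 3:
        raise ValueError("need at least 3 samples to locate a bleach")
    drops = x[:-1] - x[1:]
    k = int(np.argmax(drops))
    pre_mean = float(x[: k + 1].mean())
    if drops[k] <= min_drop_frac * pre_mean or drops[k] <= 0:
        raise ValueError("no qualifying bleach step found")
    return k + 1


def recovery_percent(curve: FrapCurve, t_s: float) -> float:
    """Percent recovery ``100 (F(t) - F0)/(F_pre - F0)`` at time ``t_s``
    after the bleach, linearly interpolating between samples."""
    curve._require_bleach()
    tb = curve.times_s[curve.bleach_index]
    if t_s < 0 or tb + t_s > curve.times_s[-1] + 1e-9:
        raise ValueError(f"t_s={t_s} outside the post-bleach span of the curve")
    f_pre = curve.prebleach_mean
    f0 = curve.f0
    if f_pre <= f0:
        raise ValueError("degenerate curve: prebleach mean <= post-bleach floor")
    f_t = float(np.interp(tb + t_s, curve.times_s, curve.intensities))
    return 100.0 * (f_t - f0) / (f_pre - f0)


def fit_recovery(curve: FrapCurve) -> FrapFit:
    """Least-squares single-exponential fit over the post-bleach samples.

    ``F0`` is fixed at the bleach-index sample (the region is emptied by the
    bleach, so the floor is measured, not fitted).  Initialization is
    deterministic: ``F_inf`` starts at the last sample and ``tau`` at half
    the post-bleach span.
    """
    curve._require_bleach()
    f_pre = curve.prebleach_mean
    f0 = curve.f0
    if f_pre - f0 <= 1e-12 * max(abs(f_pre), 1.0):
        raise ValueError("degenerate curve: no bleach contrast (F_pre ~ F0)")
    t = curve.times_s[curve.bleach_index:] - curve.times_s[curve.bleach_index]
    y = curve.intensities[curve.bleach_index:]
    if len(t) < 4:
        raise ValueError("need >= 4 post-bleach samples to fit")

    def model(tt, f_inf, tau):
        return f0 + (f_inf - f0) * (1 - np.exp(-tt / tau))

    p0 = [float(y[-1]), max(float(t[-1]) / 2, 1e-6)]
    popt, _ = curve_fit(model, t, y, p0=p0,
                        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                        maxfev=10000)
    f_inf, tau = float(popt[0]), float(popt[1])
    raw = (f_inf - f0) / (f_pre - f0)
    resid = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    return FrapFit(f_pre=f_pre, f0=f0, f_inf=f_inf, tau_s=tau,
                   mobile_fraction=float(np.clip(raw, 0.0, 1.0)),
                   mobile_fraction_raw=float(raw), residual_rms=resid)


def plateau_reached(curve: FrapCurve, epsilon_frac: float = 0.02) -> bool:
    """True iff the last two samples differ by less than
    ``epsilon_frac * F_pre`` — the acquisition stopping rule ("until the
    level of fluorescence remained constant between consecutive scans")."""
    if len(curve) < 2:
        raise ValueError("need at least 2 samples")
    f_pre = curve.prebleach_mean
    step = abs(curve.intensities[-1] - curve.intensities[-2])
    return bool(step < epsilon_frac * f_pre)


def write_curve_csv(path: str | Path, curve: FrapCurve) -> None:
    pd.DataFrame({"time_s": curve.times_s,
                  "intensity": curve.intensities}).to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> FrapCurve:
    df = pd.read_csv(path)
    return FrapCurve(times_s=df["time_s"].to_numpy(),
                     intensities=df["intensity"].to_numpy())
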
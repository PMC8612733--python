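"""FRAP trace correction, normalization, and recovery fitting.

A FRAP acquisition yields three region-mean intensity traces: the bleach
region (BL), an unbleached reference region (REF) that reports acquisition
photobleaching, and a background region (BG). The double-normalization

    BL_corr2(t) = [BL(t) - BG(t)] / [REF(t) - BG(t)]
    BL_corr3(t) = BL_corr2(t) / mean(BL_corr2 over pre-bleach frames)

removes background and multiplicative acquisition bleaching and scales the
pre-bleach signal to 1 (= 100 % fluorescence). The post-bleach recovery is
fitted with a single exponential

    f(t') = plateau - (plateau - f0) * exp(-t'/tau)

with t' measured from the first post-bleach frame and f0 pinned to the
first post-bleach observation (a free-f0 variant is available). The mobile
fraction is (plateau - f0) / (1 - f0) on the normalized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import CondquantError, CorrectionError, FitError, NormalizationError

__all__ = [
    "FRAPTrace",
    "CorrectedTrace",
    "FRAPFit",
    "correct_trace",
    "fit_recovery",
    "recovery_at",
    "batch_fit",
]


@dataclass
class FRAPTrace:
    """Raw region-mean traces for one bleach experiment.

    ``bleach_index`` is the index of the first post-bleach frame; frames in
    ``prebleach_indices`` (default: everything before ``bleach_index``)
    define the 100 % intensity level.
    """

    t: np.ndarray
    bl: np.ndarray
    ref: np.ndarray
    bg: np.ndarray
    bleach_index: int
    prebleach_indices: np.ndarray | None = None
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.bl = np.asarray(self.bl, dtype=np.float64)
        self.ref = np.asarray(self.ref, dtype=np.float64)
        self.bg = np.asarray(self.bg, dtype=np.float64)
        n = len(self.t)
        if not (len(self.bl) == len(self.ref) == len(self.bg) == n):
            raise CondquantError("t, BL, REF, BG must have equal lengths")
        if np.any(np.diff(self.t) <= 0):
            raise CondquantError("t must be strictly increasing")
        if not (1 <= self.bleach_index < n):
            raise CondquantError(f"bleach_index {self.bleach_index} out of range")
        if self.prebleach_indices is None:
            self.prebleach_indices = np.arange(self.bleach_index)
        else:
            self.prebleach_indices = np.asarray(self.prebleach_indices, dtype=int)
        if np.any(self.prebleach_indices >= self.bleach_index) or np.any(
            self.prebleach_indices < 0
        ):
            raise CondquantError("prebleach_indices must all be < bleach_index")


@dataclass
class CorrectedTrace:
    """Background/reference-corrected and pre-bleach-normalized trace."""

    t: np.ndarray
    bl_corr2: np.ndarray
    bl_corr3: np.ndarray
    bleach_index: int
    prebleach_indices: np.ndarray
    trace_id: str = ""


@dataclass
class FRAPFit:
    """Fitted single-exponential recovery parameters."""

    f0: float
    plateau: float
    tau_s: float
    half_time_s: float
    mobile_fraction: float
    residual_rms: float
    trace_id: str = ""
    flags: list[str] = field(default_factory=list)


def correct_trace(trace: FRAPTrace) -> CorrectedTrace:
    """Apply the double normalization to a raw trace.

    Raises :class:`CorrectionError` if REF <= BG at any frame (the
    reference correction is then undefined) and :class:`NormalizationError`
    if the pre-bleach mean of the corrected signal is not positive.
    """
    denom = trace.ref - trace.bg
    bad = np.nonzero(denom <= 0)[0]
    if bad.size:
        raise CorrectionError(f"REF <= BG at frame(s) {bad.tolist()[:5]}")
    bl_corr2 = (trace.bl - trace.bg) / denom
    pre = float(np.mean(bl_corr2[trace.prebleach_indices]))
    if pre <= 0:
        raise NormalizationError("pre-bleach mean of corrected signal is <= 0")
    return CorrectedTrace(
        t=trace.t,
        bl_corr2=bl_corr2,
        bl_corr3=bl_corr2 / pre,
        bleach_index=trace.bleach_index,
        prebleach_indices=trace.prebleach_indices,
        trace_id=trace.trace_id,
    )


def _recovery(tp: np.ndarray, plateau: float, tau: float, f0: float) -> np.ndarray:
    return plateau - (plateau - f0) * np.exp(-tp / tau)


def fit_recovery(
    corrected: CorrectedTrace, fix_f0: bool = True, min_post_frames: int = 5
) -> FRAPFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Only frames from ``bleach_index`` onward enter the fit; the time axis
    is rebased so the first post-bleach frame is t' = 0. With
    ``fix_f0=True`` (default) the bleach depth f0 is pinned to the first
    post-bleach observation; otherwise it is a third free parameter.
    A non-recovering trace (fitted plateau < f0) is reported with
    ``mobile_fraction = 0`` and a ``"no_recovery"`` flag rather than an
    error.
    """
    post = slice(corrected.bleach_index, None)
    tp = corrected.t[post] - corrected.t[corrected.bleach_index]
    y = corrected.bl_corr3[post]
    if len(y) < min_post_frames:
        raise FitError(f"need >= {min_post_frames} post-bleach frames, got {len(y)}")
    f0 = float(y[0])
    flags: list[str] = []

    if float(np.std(y)) < 1e-12:
        # flat trace: no recovery, time constant unidentifiable
        return FRAPFit(
            f0=f0,
            plateau=f0,
            tau_s=float("inf"),
            half_time_s=float("inf"),
            mobile_fraction=0.0,
            residual_rms=0.0,
            trace_id=corrected.trace_id,
            flags=["no_recovery", "flat_trace"],
        )

    tau0 = max(float(tp[-1]) / 3.0, float(np.min(np.diff(tp))))
    plateau0 = float(np.mean(y[max(len(y) - 5, 0):]))
    try:
        if fix_f0:
            popt, _ = curve_fit(
                lambda tt, plateau, tau: _recovery(tt, plateau, tau, f0),
                tp,
                y,
                p0=(plateau0, tau0),
                bounds=((-np.inf, 1e-12), (np.inf, np.inf)),
                maxfev=20000,
            )
            plateau, tau = float(popt[0]), float(popt[1])
        else:
            popt, _ = curve_fit(
                _recovery,
                tp,
                y,
                p0=(plateau0, tau0, f0),
                bounds=((-np.inf, 1e-12, -np.inf), (np.inf, np.inf, np.inf)),
                maxfev=20000,
            )
            plateau, tau, f0 = (float(v) for v in popt)
    except RuntimeError as exc:
        raise FitError(f"recovery fit did not converge: {exc}") from exc

    resid = y - _recovery(tp, plateau, tau, f0)
    if plateau < f0:
        mobile = 0.0
        flags.append("no_recovery")
    elif f0 >= 1.0:
        mobile = float("nan")
        flags.append("f0_above_prebleach")
    else:
        mobile = (plateau - f0) / (1.0 - f0)
    return FRAPFit(
        f0=f0,
        plateau=plateau,
        tau_s=tau,
        half_time_s=tau * float(np.log(2.0)),
        mobile_fraction=mobile,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        trace_id=corrected.trace_id,
        flags=flags,
    )


def recovery_at(fit: FRAPFit, t_s: float) -> float:
    """Evaluate the fitted recovery curve at time ``t_s`` after bleach."""
    if t_s < 0:
        raise CondquantError("t_s must be >= 0")
    if not np.isfinite(fit.tau_s):
        return fit.f0
    return float(_recovery(np.asarray(t_s, dtype=float), fit.plateau, fit.tau_s, fit.f0))


def batch_fit(
    traces: list[FRAPTrace], fix_f0: bool = True, resample: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every trace and build the mean +/- SE normalized curve.

    All traces must share a common time base (to within float tolerance)
    unless ``resample=True``, in which case each trace is linearly
    interpolated onto the first trace's time base. Returns ``(fits,
    mean_curve)``: one row per trace with the fitted parameters, and the
    per-timepoint mean of BL_corr3 with its standard error (SE is NaN and
    flagged for n = 1).
    """
    if not traces:
        raise CondquantError("batch_fit needs at least one trace")
    corrected = [correct_trace(tr) for tr in traces]
    t0 = corrected[0].t
    curves = []
    for c in corrected:
        if len(c.t) == len(t0) and np.allclose(c.t, t0):
            curves.append(c.bl_corr3)
        elif resample:
            curves.append(np.interp(t0, c.t, c.bl_corr3))
        else:
            raise CondquantError(
                "traces have incompatible time bases; pass resample=True"
            )
    fits = [fit_recovery(c, fix_f0=fix_f0) for c in corrected]
    fits_df = pd.DataFrame(
        {
            "trace_id": [f.trace_id for f in fits],
            "f0": [f.f0 for f in fits],
            "plateau": [f.plateau for f in fits],
            "tau_s": [f.tau_s for f in fits],
            "half_time_s": [f.half_time_s for f in fits],
            "mobile_fraction": [f.mobile_fraction for f in fits],
            "residual_rms": [f.residual_rms for f in fits],
            "flags": [";".join(f.flags) for f in fits],
        }
    )
    arr = np.vstack(curves)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    if n > 1:
        se = arr.std(axis=0, ddof=1) / np.sqrt(n)
        se[np.ptp(arr, axis=0) == 0] = 0.0  # identical values: SE exactly 0
    else:
        se = np.full(arr.shape[1], np.nan)
    mean_curve = pd.DataFrame({"t": t0, "mean_bl_corr3": mean, "se": se})
    mean_curve.attrs["n"] = n
    if n == 1:
        mean_curve.attrs["se_undefined"] = True
    return fits_df, mean_curve
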
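"""Puncta counting and dissolution (survival) kinetics.

Hexanediol-type experiments record a time-lapse of a cell field while a
condensate-dissolving treatment is added; the readout is the number of
fluorescent puncta per frame, normalized to the count at the moment of
treatment (t = 0). Counting reuses the droplet mask machinery, so
"surviving puncta" means per-frame counts with no identity tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .droplets import MaskParams, make_droplet_mask
from .exceptions import CondquantError, FitError, NormalizationError
from .io import Image2D, ImageStack

__all__ = [
    "DissolutionSeries",
    "count_puncta",
    "survival_curve",
    "fit_dissolution",
]


@dataclass
class DissolutionSeries:
    """Per-frame puncta counts with survival normalized to t = 0.

    ``t`` is time from treatment in seconds (negative for pre-treatment
    frames); ``survival`` is ``counts / counts[t = 0]`` and is NaN for
    pre-treatment frames, which are excluded from normalization.
    """

    t: np.ndarray
    counts: np.ndarray
    survival: np.ndarray
    t0_index: int


def count_puncta(frame: Image2D, params: MaskParams = MaskParams()) -> int:
    """Number of puncta in a dark-corrected frame (mask component count)."""
    return make_droplet_mask(frame, params).n_droplets


def survival_curve(
    stack: ImageStack, t0_index: int, params: MaskParams = MaskParams()
) -> DissolutionSeries:
    """Count puncta per frame and normalize to the treatment frame.

    The treatment frame ``t0_index`` maps to t = 0; earlier frames get
    negative times and NaN survival. Zero puncta at t0 is a
    :class:`NormalizationError` (nothing to normalize to).
    """
    n = len(stack)
    if not (0 <= t0_index < n):
        raise CondquantError(f"t0_index {t0_index} out of range for {n} frames")
    counts = np.array(
        [count_puncta(fr, params) for fr in stack.frames], dtype=np.int64
    )
    if counts[t0_index] == 0:
        raise NormalizationError("zero puncta at the treatment frame")
    t = (np.arange(n) - t0_index) * stack.frame_interval_s
    survival = np.full(n, np.nan)
    survival[t0_index:] = counts[t0_index:] / counts[t0_index]
    return DissolutionSeries(t=t, counts=counts, survival=survival, t0_index=t0_index)


def fit_dissolution(series: DissolutionSeries) -> tuple[float, float]:
    """Fit exponential decay to the survival curve.

    Returns ``(lambda_per_s, half_life_s)`` from a least-squares fit of
    ``survival = exp(-lambda * t)`` over t >= 0. A non-dissolving series
    (flat at 1) returns ``(0, inf)``.
    """
    post = series.t >= 0
    t = series.t[post]
    s = series.survival[post]
    if len(t) < 3:
        raise FitError("need >= 3 post-treatment frames to fit dissolution")
    if np.allclose(s, 1.0):
        return 0.0, float("inf")
    try:
        popt, _ = curve_fit(
            lambda tt, lam: np.exp(-lam * tt),
            t,
            s,
            p0=(1.0 / max(t[-1], 1e-9),),
            bounds=((0.0,), (np.inf,)),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"dissolution fit did not converge: {exc}") from exc
    lam = float(popt[0])
    half = float(np.log(2.0) / lam) if lam > 0 else float("inf")
    return lam, half
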
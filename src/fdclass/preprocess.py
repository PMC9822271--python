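"""Baseline/tilt correction, contact-point detection and optional smoothing.

Rupture detection is only well-posed on a retract trace whose force baseline
is flat around zero and whose z origin sits at the tip-sample contact point.
The baseline is a least-squares line fitted over the far field of the retract
(the farthest-from-surface fraction of the z range, 30% by default) where no
tether event can occur: events happen within ~2x the tether contour length
(~100 nm) of contact while the default retract range is 300 nm.

Smoothing is available but OFF by default in the pipeline — a quadratic
moving fit biases rupture-force magnitudes downward, so detection operates on
the raw corrected trace with a noise-aware threshold instead.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import savgol_filter

from .curve_io import SEGMENT_RETRACT, FDCurve

#: Gaussian-consistency factor for the median absolute deviation
MAD_SCALE = 1.4826

FLAG_NO_CONTACT = "no-contact"


class EstimationError(ValueError):
    """Raised when a window is too short for a stable estimate."""


class ParameterError(ValueError):
    """Raised for invalid smoothing / windowing parameters."""


def mad_sigma(x) -> float:
    """Robust spread estimate: median absolute deviation scaled to Gaussian sigma."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    return float(MAD_SCALE * np.median(np.abs(x - med)))


def diff_sigma(x) -> float:
    """Noise sigma from first differences; insensitive to slow structure and steps."""
    x = np.asarray(x, dtype=float)
    return mad_sigma(np.diff(x)) / math.sqrt(2.0)


def baseline_window_mask(z: np.ndarray, fraction: float = 0.30) -> np.ndarray:
    """Boolean mask of the farthest ``fraction`` of the z range (the far field)."""
    if not 0 < fraction < 1:
        raise ParameterError(f"baseline fraction must be in (0, 1), got {fraction}")
    span = float(z.max() - z.min())
    return z >= z.max() - fraction * span


def estimate_baseline(curve: FDCurve, fraction: float = 0.30):
    """Least-squares (slope pN/nm, intercept pN) of the far-field retract force."""
    z, f = curve.segment_arrays(SEGMENT_RETRACT)
    if z.size < 16:
        raise EstimationError("retract segment too short for baseline estimation")
    mask = baseline_window_mask(z, fraction)
    if mask.sum() < 8:
        raise EstimationError(
            f"baseline window has {int(mask.sum())} samples, need at least 8"
        )
    slope, intercept = np.polyfit(z[mask], f[mask], deg=1)
    return float(slope), float(intercept)


def correct_curve(curve: FDCurve, baseline) -> FDCurve:
    """Subtract the baseline line slope*z + intercept from the whole force trace."""
    slope, intercept = baseline
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("baseline coefficients must be finite")
    return curve.replace(force=curve.force - (slope * curve.z + intercept))


def find_contact_point(
    curve: FDCurve,
    threshold_sigma: float = 3.0,
    baseline_fraction: float = 0.30,
) -> float:
    """Locate the contact point on a baseline-corrected retract trace.

    The repulsive contact region is the leading run of samples whose force
    exceeds +threshold_sigma x noise floor; the contact point z0 is the last
    sample of that run (the curve should subsequently be re-origined so that
    z0 -> 0, see :func:`recenter`).  When no sample exceeds the threshold the
    curve is flagged "no-contact" and the first retract sample is returned.
    """
    z, f = curve.segment_arrays(SEGMENT_RETRACT)
    noise = mad_sigma(f[baseline_window_mask(z, baseline_fraction)])
    thresh = max(threshold_sigma * noise, 1e-9)
    above = f > thresh
    if not above.any():
        curve.flags.add(FLAG_NO_CONTACT)
        return float(z[0])
    i = int(np.argmax(above))  # first sample in contact
    while i + 1 < above.size and above[i + 1]:
        i += 1
    return float(z[i])


def recenter(curve: FDCurve, z0: float) -> FDCurve:
    """Shift the z origin so the contact point maps to z = 0."""
    return curve.replace(z=curve.z - z0)


def smooth_force(curve: FDCurve, window: int) -> FDCurve:
    """Quadratic moving least-squares (Savitzky-Golay) smoothing of the force.

    ``window`` must be odd; ``window=1`` returns the input unchanged.  The z
    grid is never modified and white noise is never amplified.
    """
    if window == 1:
        return curve
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"smoothing window must be odd and >= 3, got {window}")
    force = curve.force.copy()
    for name in curve.segment_names():
        mask = curve.segment == name
        n = int(mask.sum())
        if window >= n:
            raise ParameterError(
                f"smoothing window {window} >= segment '{name}' length {n}"
            )
        force[mask] = savgol_filter(curve.force[mask], window_length=window, polyorder=2)
    return curve.replace(force=force)


def preprocess_curve(
    curve: FDCurve,
    baseline_fraction: float = 0.30,
    contact_threshold_sigma: float = 3.0,
    smooth_window: int = 1,
) -> FDCurve:
    """Baseline-correct, contact-align and (optionally) smooth one curve."""
    corrected = correct_curve(curve, estimate_baseline(curve, baseline_fraction))
    z0 = find_contact_point(corrected, contact_threshold_sigma, baseline_fraction)
    out = recenter(corrected, z0)
    if smooth_window > 1:
        out = smooth_force(out, smooth_window)
    return out
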
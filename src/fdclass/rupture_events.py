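"""Rupture-event detection on the retract trace.

A rupture (adhesion) event is a local force minimum that (i) is deeper than
max(min_force, sigma_multiplier x noise floor) and (ii) is followed by an
abrupt release — the force recovers at least 50% of the event magnitude
within a short z span (5 nm by default).  The sharp-release requirement is
what distinguishes molecular tether ruptures from gradual non-specific
adhesion ramps: at retract velocities of order 1000-2600 nm/s, bond rupture
is effectively instantaneous on the z grid.

The two classification features are extracted here: the maximum adhesion
force f_max (magnitude of the global post-contact force minimum) and the
number of detected peaks.  "Simultaneous detachment" of several tethers is
deliberately NOT resolved into multiple events — it manifests as one very
deep minimum, and classification of such curves is force-magnitude-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .curve_io import SEGMENT_RETRACT, FDCurve
from .preprocess import (
    FLAG_NO_CONTACT,
    EstimationError,
    baseline_window_mask,
    diff_sigma,
    mad_sigma,
)

FLAG_SATURATED = "saturated"
FLAG_BASELINE_JUMP = "baseline-jump"
FLAG_OVERRANGE = "overrange"

ARTIFACT_FLAGS = frozenset(
    {FLAG_NO_CONTACT, FLAG_SATURATED, FLAG_BASELINE_JUMP, FLAG_OVERRANGE}
)


class PreconditionError(ValueError):
    """Raised when detection is attempted on an uncorrected curve."""


@dataclass(frozen=True)
class AdhesionEvent:
    """One detected rupture: position of the force minimum (nm from contact),
    positive force magnitude (pN) and the z span of the release (nm)."""

    z_rupture: float
    force: float
    release_width: float


@dataclass(frozen=True)
class CurveFeatures:
    """Classifier input for one curve: event count, maximum adhesion force
    (0 when no event), robust baseline noise floor, and quality flags."""

    n_events: int
    f_max: float
    noise_floor: float
    quality_flags: frozenset = frozenset()

    def __post_init__(self):
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        if self.f_max < 0:
            raise ValueError("f_max must be non-negative")
        if self.n_events == 0 and self.f_max != 0:
            raise ValueError("f_max must be 0 when no events were detected")


def estimate_noise(curve: FDCurve, baseline_fraction: float = 0.30) -> float:
    """Robust noise floor (pN): scaled MAD of the baseline-window retract force."""
    z, f = curve.segment_arrays(SEGMENT_RETRACT)
    mask = baseline_window_mask(z, baseline_fraction)
    if mask.sum() < 8:
        raise EstimationError("baseline window too short for noise estimation")
    return mad_sigma(f[mask])


def flag_saturation(curve: FDCurve, min_force: float = 75.0) -> bool:
    """Detect detector saturation on the *raw* retract trace.

    Saturation leaves a run of bit-identical samples clamped at the trace
    extreme; a run of >=5 identical values at the global minimum, at a depth
    that cannot be noise, flags the curve.  Must be called before baseline
    correction (the subtraction breaks exact equality).
    """
    _, f = curve.segment_arrays(SEGMENT_RETRACT)
    fmin = f.min()
    idx = np.flatnonzero(f == fmin)
    if idx.size < 5:
        return False
    runs = np.split(idx, np.where(np.diff(idx) != 1)[0] + 1)
    longest = max(len(r) for r in runs)
    depth = float(np.median(f) - fmin)
    return longest >= 5 and depth > max(10.0 * mad_sigma(f), min_force)


def flag_baseline_jump(curve: FDCurve, baseline_fraction: float = 0.30) -> bool:
    """Detect a step discontinuity in the corrected far-field baseline.

    Compares the standard deviation of the baseline window (sensitive to any
    residual structure a line fit cannot absorb) against a first-difference
    noise estimate (insensitive to steps).  A ratio above 5 cannot be produced
    by white noise.
    """
    z, f = curve.segment_arrays(SEGMENT_RETRACT)
    w = f[baseline_window_mask(z, baseline_fraction)]
    return float(np.std(w)) > 5.0 * max(diff_sigma(w), 1e-9)


def detect_ruptures(
    curve: FDCurve,
    min_force: float = 75.0,
    min_separation: float = 8.0,
    sigma_multiplier: float = 5.0,
    release_width: float = 5.0,
    noise_floor: Optional[float] = None,
    baseline_fraction: float = 0.30,
) -> list[AdhesionEvent]:
    """Detect rupture events on a baseline-corrected, contact-aligned retract.

    Events closer than ``min_separation`` (nm) are merged keeping the deeper
    one; the returned list is ordered by increasing z.
    """
    z, f = curve.segment_arrays(SEGMENT_RETRACT)
    if noise_floor is None:
        noise_floor = estimate_noise(curve, baseline_fraction)
    bw_mean = float(np.mean(f[baseline_window_mask(z, baseline_fraction)]))
    if abs(bw_mean) > max(5.0 * noise_floor, 1e-6):
        raise PreconditionError(
            f"baseline mean {bw_mean:.3g} pN >> noise floor {noise_floor:.3g} pN; "
            "correct the curve first"
        )

    post = z > 0  # post-contact region only
    zr, fr = z[post], f[post]
    if zr.size < 3:
        return []
    threshold = max(min_force, sigma_multiplier * noise_floor)
    # a genuine rupture rises from near-baseline to the peak and releases back,
    # so its prominence matches its depth; noise spikes riding on a stretched
    # tether have large absolute depth but prominence of only a few sigma
    peaks, _ = find_peaks(-fr, height=threshold, prominence=threshold)

    candidates: list[AdhesionEvent] = []
    for p in peaks:
        depth = -fr[p]
        ahead = (zr > zr[p]) & (zr <= zr[p] + release_width)
        recovered = fr[ahead] >= 0.5 * fr[p]  # fr[p] < 0: recovery of >=50%
        if not recovered.any():
            continue
        z_rel = zr[ahead][int(np.argmax(recovered))]
        candidates.append(
            AdhesionEvent(
                z_rupture=float(zr[p]),
                force=float(depth),
                release_width=float(z_rel - zr[p]),
            )
        )

    kept: list[AdhesionEvent] = []
    for ev in sorted(candidates, key=lambda e: -e.force):
        if all(abs(ev.z_rupture - k.z_rupture) >= min_separation for k in kept):
            kept.append(ev)
    return sorted(kept, key=lambda e: e.z_rupture)


def extract_features(
    curve: FDCurve,
    events: Iterable[AdhesionEvent],
    noise_floor: Optional[float] = None,
    overrange_force: float = 2000.0,
    baseline_fraction: float = 0.30,
) -> CurveFeatures:
    """Build the classifier's feature vector from a curve and its events.

    f_max is the magnitude of the global post-contact force minimum when
    events exist (hence >= every individual event force) and 0 otherwise.
    """
    events = list(events)
    if noise_floor is None:
        noise_floor = estimate_noise(curve, baseline_fraction)
    z, f = curve.segment_arrays(SEGMENT_RETRACT)
    post = z > 0
    f_max = float(-f[post].min()) if events and post.any() else 0.0
    flags = set(curve.flags)
    if f_max > overrange_force:
        flags.add(FLAG_OVERRANGE)
    return CurveFeatures(
        n_events=len(events),
        f_max=f_max,
        noise_floor=float(noise_floor),
        quality_flags=frozenset(flags),
    )


def events_table(events: Iterable[AdhesionEvent], curve_index: int = 0) -> pd.DataFrame:
    """Tabulate events for CSV export."""
    return pd.DataFrame(
        [
            {
                "curve_index": curve_index,
                "event_index": i,
                "z_rupture_nm": ev.z_rupture,
                "force_pN": ev.force,
                "release_width_nm": ev.release_width,
            }
            for i, ev in enumerate(events)
        ],
        columns=["curve_index", "event_index", "z_rupture_nm", "force_pN", "release_width_nm"],
    )
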
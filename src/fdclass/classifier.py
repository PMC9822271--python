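"""Seven-way classification of F-d curves from (event count, maximum adhesion force).

Curves are assigned to one of six interaction groups plus an artifact group,
using two experimental magnitudes only: the maximum adhesion force f_max and
the number of rupture peaks.  The force bands reflect the biotin-streptavidin
literature: non-specific adhesion stays below 200 pN, a single specific
unbinding event falls in (200, 650] pN (mean ~400 pN), and simultaneous
detachment of closely spaced pairs reaches up to 2000 pN.  Band upper limits
are inclusive; anything beyond 2000 pN, and any curve with a quality flag
(saturation, baseline discontinuity, no contact), is discarded as an artifact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import rupture_events as re_
from .curve_io import FDCurve, read_fd_table, read_manifest
from .preprocess import (
    correct_curve,
    estimate_baseline,
    find_contact_point,
    recenter,
    smooth_force,
)


class CurveClass(str, Enum):
    """Categorical curve type: six interaction groups plus artifacts."""

    TYPE1 = "Type1"
    TYPE2 = "Type2"
    TYPE3 = "Type3"
    TYPE4 = "Type4"
    TYPE5 = "Type5"
    TYPE6 = "Type6"
    TYPE7 = "Type7"

    @property
    def label(self) -> str:
        return CLASS_LABELS[self]


CLASS_LABELS = {
    CurveClass.TYPE1: "no interaction",
    CurveClass.TYPE2: "non-specific",
    CurveClass.TYPE3: "single interaction",
    CurveClass.TYPE4: "multiple-independent",
    CurveClass.TYPE5: "multiple-simultaneous",
    CurveClass.TYPE6: "multiple-combined",
    CurveClass.TYPE7: "artifact",
}

#: the four classes counted as successful specific interactions
SUCCESS_CLASSES = (CurveClass.TYPE3, CurveClass.TYPE4, CurveClass.TYPE5, CurveClass.TYPE6)


@dataclass(frozen=True)
class ClassifierConfig:
    """Force band boundaries in pN; upper limits are inclusive."""

    f_nonspecific: float = 200.0
    f_high: float = 650.0
    f_veryhigh: float = 2000.0

    def __post_init__(self):
        if not 0 < self.f_nonspecific < self.f_high < self.f_veryhigh:
            raise ValueError(
                "thresholds must satisfy 0 < f_nonspecific < f_high < f_veryhigh"
            )


@dataclass(frozen=True)
class DetectionConfig:
    """Preprocessing and event-detection parameters (nm / pN units)."""

    baseline_fraction: float = 0.30
    contact_threshold_sigma: float = 3.0
    smooth_window: int = 1
    min_force_pN: float = 75.0
    min_separation_nm: float = 8.0
    sigma_multiplier: float = 5.0
    release_width_nm: float = 5.0


def _le(value: float, bound: float) -> bool:
    # inclusive upper bound, robust to last-ulp noise from baseline correction
    return value <= bound or math.isclose(value, bound, rel_tol=1e-9, abs_tol=1e-9)


def is_artifact(features: re_.CurveFeatures, config: ClassifierConfig = ClassifierConfig()) -> bool:
    """A curve is an artifact if its force exceeds the very-high ceiling or any
    quality flag (saturated, overrange, baseline-jump, no-contact) is set."""
    if not _le(features.f_max, config.f_veryhigh):
        return True
    return bool(features.quality_flags & re_.ARTIFACT_FLAGS)


def classify_curve(
    features: re_.CurveFeatures, config: ClassifierConfig = ClassifierConfig()
) -> CurveClass:
    """Total, deterministic decision rule over (n_events, f_max)."""
    if is_artifact(features, config):
        return CurveClass.TYPE7
    if features.n_events == 0:
        return CurveClass.TYPE1
    if _le(features.f_max, config.f_nonspecific):
        return CurveClass.TYPE2
    if _le(features.f_max, config.f_high):
        return CurveClass.TYPE3 if features.n_events == 1 else CurveClass.TYPE4
    return CurveClass.TYPE5 if features.n_events == 1 else CurveClass.TYPE6


def analyze_curve(
    curve: FDCurve,
    detection: DetectionConfig = DetectionConfig(),
    config: ClassifierConfig = ClassifierConfig(),
):
    """Run the full per-curve pipeline: quality flags, baseline correction,
    contact alignment, rupture detection, feature extraction, classification.

    Returns (features, curve class, processed curve).
    """
    curve.validate()
    work = curve.replace()  # do not mutate the caller's flags
    if re_.flag_saturation(work, detection.min_force_pN):
        work.flags.add(re_.FLAG_SATURATED)
    work = correct_curve(work, estimate_baseline(work, detection.baseline_fraction))
    if re_.flag_baseline_jump(work, detection.baseline_fraction):
        work.flags.add(re_.FLAG_BASELINE_JUMP)
    z0 = find_contact_point(work, detection.contact_threshold_sigma, detection.baseline_fraction)
    work = recenter(work, z0)
    if detection.smooth_window > 1:
        work = smooth_force(work, detection.smooth_window)
    noise = re_.estimate_noise(work, detection.baseline_fraction)
    events = re_.detect_ruptures(
        work,
        min_force=detection.min_force_pN,
        min_separation=detection.min_separation_nm,
        sigma_multiplier=detection.sigma_multiplier,
        release_width=detection.release_width_nm,
        noise_floor=noise,
        baseline_fraction=detection.baseline_fraction,
    )
    features = re_.extract_features(
        work, events, noise, config.f_veryhigh, detection.baseline_fraction
    )
    return features, classify_curve(features, config), work


RESULT_COLUMNS = [
    "curve_index",
    "condition_label",
    "n_events",
    "f_max_pN",
    "noise_floor_pN",
    "flags",
    "class_code",
    "true_class",
    "error",
]


def classify_curves(
    curves: Iterable[FDCurve],
    detection: DetectionConfig = DetectionConfig(),
    config: ClassifierConfig = ClassifierConfig(),
) -> pd.DataFrame:
    """Classify an in-memory sequence of curves; one result row per curve,
    temporal (input) order preserved."""
    rows = []
    for curve in curves:
        meta = curve.metadata
        try:
            features, cls, _ = analyze_curve(curve, detection, config)
            rows.append(
                {
                    "curve_index": meta.curve_index,
                    "condition_label": meta.condition_label,
                    "n_events": features.n_events,
                    "f_max_pN": features.f_max,
                    "noise_floor_pN": features.noise_floor,
                    "flags": ";".join(sorted(features.quality_flags)),
                    "class_code": cls.value,
                    "true_class": meta.true_class,
                    "error": None,
                }
            )
        except Exception as exc:  # keep the batch going, flag the row
            rows.append(
                {
                    "curve_index": meta.curve_index,
                    "condition_label": meta.condition_label,
                    "n_events": None,
                    "f_max_pN": None,
                    "noise_floor_pN": None,
                    "flags": "",
                    "class_code": None,
                    "true_class": meta.true_class,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def classify_batch(
    batch_dir,
    detection: DetectionConfig = DetectionConfig(),
    config: ClassifierConfig = ClassifierConfig(),
    manifest_name: str = "manifest.csv",
) -> pd.DataFrame:
    """Classify every curve of an on-disk batch (directory + manifest CSV).

    Unreadable curve files produce a flagged row (``error`` column) and the
    pipeline continues.  Without a manifest, ``*.tsv`` files are taken in
    sorted order.
    """
    batch_dir = Path(batch_dir)
    manifest_path = batch_dir / manifest_name
    if manifest_path.exists():
        manifest = read_manifest(manifest_path)
    else:
        files = sorted(p.name for p in batch_dir.glob("*.tsv"))
        manifest = pd.DataFrame(
            {
                "filename": files,
                "curve_index": range(len(files)),
                "condition_label": "",
                "true_class": None,
            }
        )
    if manifest.empty:
        warnings.warn(f"batch directory {batch_dir} contains no curves")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    rows = []
    for rec in manifest.itertuples(index=False):
        try:
            curve = read_fd_table(batch_dir / rec.filename)
            features, cls, _ = analyze_curve(curve, detection, config)
            rows.append(
                {
                    "curve_index": rec.curve_index,
                    "condition_label": rec.condition_label,
                    "n_events": features.n_events,
                    "f_max_pN": features.f_max,
                    "noise_floor_pN": features.noise_floor,
                    "flags": ";".join(sorted(features.quality_flags)),
                    "class_code": cls.value,
                    "true_class": rec.true_class,
                    "error": None,
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "curve_index": rec.curve_index,
                    "condition_label": rec.condition_label,
                    "n_events": None,
                    "f_max_pN": None,
                    "noise_floor_pN": None,
                    "flags": "",
                    "class_code": None,
                    "true_class": rec.true_class,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
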
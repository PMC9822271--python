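"""Data model and plain-text I/O for force-distance (F-d) curves.

One AFM approach/retract cycle is stored as a single text file: ``#``-prefixed
``key=value`` header lines carry calibration metadata, followed by a TSV body
with columns ``segment``, ``z_nm`` and either ``force_pN`` or ``deflection_V``.
A batch of curves is a directory of such files plus a ``manifest.csv``.

All quantities are kept in canonical units internally — nm, pN, s, V.
Photodetector deflection (V) is converted to force at read time when both the
cantilever spring constant (pN/nm) and the deflection sensitivity (nm/V) are
known.  Attractive (adhesive) force is negative in stored traces; reported
adhesion forces elsewhere in the package are positive magnitudes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

SEGMENT_APPROACH = "approach"
SEGMENT_RETRACT = "retract"

#: minimum number of samples per segment for a curve to be analysable
MIN_SEGMENT_SAMPLES = 16

MANIFEST_COLUMNS = ["filename", "curve_index", "condition_label", "true_class"]


class FormatError(ValueError):
    """Raised when a curve file does not conform to the columnar dialect."""


class CurveValidationError(ValueError):
    """Raised when a parsed or constructed curve violates an invariant."""


def deflection_to_force(deflection, spring_constant: float, sensitivity: float):
    """Convert photodetector deflection (V) to force (pN).

    force = spring_constant [pN/nm] x sensitivity [nm/V] x deflection [V]

    The conversion is linear in each argument.  Accepts scalars or arrays.
    """
    if not spring_constant > 0:
        raise ValueError(f"spring_constant must be positive, got {spring_constant}")
    if not sensitivity > 0:
        raise ValueError(f"sensitivity must be positive, got {sensitivity}")
    return spring_constant * sensitivity * np.asarray(deflection, dtype=float)


@dataclass
class CurveMetadata:
    """Calibration and provenance metadata for one F-d curve.

    spring_constant is in pN/nm (0.18 N/m == 180 pN/nm), deflection
    sensitivity in nm/V, velocities in nm/s, contact time in s.
    ``true_class`` carries the simulator's ground-truth label and is absent
    (None) for real instrument data.
    """

    spring_constant: float = 180.0
    deflection_sensitivity: Optional[float] = None
    forward_velocity: float = 1000.0
    backward_velocity: float = 2600.0
    contact_time: float = 1.0
    condition_label: str = "pristine"
    curve_index: int = 0
    true_class: Optional[str] = None

    def validate(self) -> None:
        if not self.spring_constant > 0:
            raise CurveValidationError("spring_constant must be positive")
        if self.deflection_sensitivity is not None and not self.deflection_sensitivity > 0:
            raise CurveValidationError("deflection_sensitivity must be positive")
        for name in ("forward_velocity", "backward_velocity", "contact_time"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise CurveValidationError(f"{name} must be positive")
        if self.curve_index < 0:
            raise CurveValidationError("curve_index must be non-negative")


_HEADER_KEYS = {
    "spring_constant_pN_nm": ("spring_constant", float),
    "deflection_sensitivity_nm_V": ("deflection_sensitivity", float),
    "forward_velocity_nm_s": ("forward_velocity", float),
    "backward_velocity_nm_s": ("backward_velocity", float),
    "contact_time_s": ("contact_time", float),
    "condition_label": ("condition_label", str),
    "curve_index": ("curve_index", int),
    "true_class": ("true_class", str),
}


@dataclass
class FDCurve:
    """One force-distance record: per-sample segment label, piezo displacement
    z (nm, strictly monotone within a segment) and force (pN).

    ``flags`` accumulates quality annotations (e.g. "no-contact", "saturated")
    during analysis; it is transient state, not serialized.
    """

    segment: np.ndarray
    z: np.ndarray
    force: np.ndarray
    metadata: CurveMetadata = field(default_factory=CurveMetadata)
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.segment = np.asarray(self.segment, dtype=object)
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)

    # -- structure ---------------------------------------------------------
    def segment_names(self):
        return list(dict.fromkeys(self.segment.tolist()))

    def has_segment(self, name: str) -> bool:
        return bool(np.any(self.segment == name))

    def segment_arrays(self, name: str):
        """Return (z, force) views for one segment."""
        mask = self.segment == name
        return self.z[mask], self.force[mask]

    @property
    def retract(self):
        return self.segment_arrays(SEGMENT_RETRACT)

    def replace(self, z: np.ndarray | None = None, force: np.ndarray | None = None) -> "FDCurve":
        """Copy of this curve with z and/or force substituted; flags are copied."""
        return FDCurve(
            segment=self.segment,
            z=self.z if z is None else np.asarray(z, dtype=float),
            force=self.force if force is None else np.asarray(force, dtype=float),
            metadata=self.metadata,
            flags=set(self.flags),
        )

    # -- invariants --------------------------------------------------------
    def validate(self) -> "FDCurve":
        if not (len(self.segment) == len(self.z) == len(self.force)):
            raise CurveValidationError("segment, z and force must have equal length")
        if not self.has_segment(SEGMENT_RETRACT):
            raise CurveValidationError("retract segment is mandatory")
        for name in self.segment_names():
            z, f = self.segment_arrays(name)
            if z.size < MIN_SEGMENT_SAMPLES:
                raise CurveValidationError(
                    f"segment '{name}' has {z.size} samples, minimum is {MIN_SEGMENT_SAMPLES}"
                )
            dz = np.diff(z)
            if not (np.all(dz > 0) or np.all(dz < 0)):
                raise CurveValidationError(f"z is not strictly monotone within segment '{name}'")
            if not np.all(np.isfinite(f)):
                raise CurveValidationError(f"non-finite force values in segment '{name}'")
        self.metadata.validate()
        return self


def read_fd_table(path) -> FDCurve:
    """Read one F-d curve from the columnar text dialect and validate it.

    A ``deflection_V`` column is auto-converted to force when both the spring
    constant and the deflection sensitivity are present in the header.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
    meta = CurveMetadata()
    for key, raw in header.items():
        if key in _HEADER_KEYS:
            attr, cast = _HEADER_KEYS[key]
            setattr(meta, attr, cast(raw))

    table = pd.read_csv(path, sep="\t", comment="#")
    for col in ("segment", "z_nm"):
        if col not in table.columns:
            raise FormatError(f"mandatory column '{col}' missing in {path}")
    if "force_pN" in table.columns:
        force = table["force_pN"].to_numpy(dtype=float)
    elif "deflection_V" in table.columns:
        if meta.deflection_sensitivity is None:
            raise FormatError(
                "deflection_V column requires deflection_sensitivity_nm_V in the header"
            )
        force = deflection_to_force(
            table["deflection_V"].to_numpy(dtype=float),
            meta.spring_constant,
            meta.deflection_sensitivity,
        )
    else:
        raise FormatError(f"need a force_pN or deflection_V column in {path}")

    curve = FDCurve(
        segment=table["segment"].to_numpy(dtype=object),
        z=table["z_nm"].to_numpy(dtype=float),
        force=force,
        metadata=meta,
    )
    return curve.validate()


def write_fd_table(curve: FDCurve, path) -> str:
    """Write a validated curve to ``path``; round-trips arrays to <=1e-6."""
    curve.validate()
    m = curve.metadata
    lines = [
        f"# spring_constant_pN_nm={m.spring_constant:.6g}",
        f"# forward_velocity_nm_s={m.forward_velocity:.6g}",
        f"# backward_velocity_nm_s={m.backward_velocity:.6g}",
        f"# contact_time_s={m.contact_time:.6g}",
        f"# condition_label={m.condition_label}",
        f"# curve_index={m.curve_index}",
    ]
    if m.deflection_sensitivity is not None:
        lines.insert(1, f"# deflection_sensitivity_nm_V={m.deflection_sensitivity:.6g}")
    if m.true_class is not None:
        lines.append(f"# true_class={m.true_class}")
    body = pd.DataFrame(
        {"segment": curve.segment, "z_nm": curve.z, "force_pN": curve.force}
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        body.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    return str(path)


def write_manifest(manifest: pd.DataFrame, path) -> str:
    """Write a batch manifest CSV (filename, curve_index, condition_label, true_class)."""
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    manifest.loc[:, MANIFEST_COLUMNS].to_csv(path, index=False)
    return str(path)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"filename": str, "condition_label": str, "true_class": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise FormatError(f"manifest missing columns {missing}")
    manifest["true_class"] = manifest["true_class"].where(manifest["true_class"].notna(), None)
    return manifest
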
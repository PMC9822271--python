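"""Physics-based generator of labeled F-d retract curves.

Each simulated retract trace is a sum of worm-like-chain (WLC, Marko-Siggia
interpolation) tether pulls through a ~50 nm PEG spacer, a linear repulsive
contact ramp before the contact point, a random baseline tilt/offset, and
Gaussian force noise.  Tether rupture forces are drawn from type-conditioned
truncated normal distributions matching the force scales of the
biotin-streptavidin system: non-specific adhesion below 200 pN, single
specific unbinding in (200, 650] pN with a ~400 pN mean, and simultaneous
detachment of closely spaced pairs in (650, 2000] pN.

Two condition presets reproduce the composition of a functionalized-probe
experiment: "pristine" (streptavidin freely accessible, ~90% of curves show
a specific interaction) and "blocked" (binding sites saturated with
biotinylated albumin, no-interaction curves dominate).  A small fraction of
artifact curves (saturation clipping, baseline jumps, over-range forces) is
injected under both presets.

Sampling is peak-preserving: the last rendered sample of each tether is
pinned to its sampled rupture force, so the 1024-point grid does not clip
force peaks the way naive decimation of the steep WLC wall would (real
acquisitions sample far more densely than the grid used here).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classifier import CurveClass
from .curve_io import (
    SEGMENT_RETRACT,
    CurveMetadata,
    FDCurve,
    write_fd_table,
    write_manifest,
)

#: repulsive contact stiffness rendered before the contact point, pN/nm
CONTACT_STIFFNESS = 50.0
#: in-contact travel rendered before the contact point, nm
CONTACT_DEPTH = 10.0


@dataclass(frozen=True)
class TetherModel:
    """Worm-like-chain parameters of the PEG spacer.

    contour_length: fully extended tether length, nm (~50 nm for 10 kDa PEG).
    persistence_length: bending stiffness length scale, nm (0.38 nm for PEG).
    kT: thermal energy, pN nm (4.114 at 298 K).
    """

    contour_length: float = 50.0
    persistence_length: float = 0.38
    kT: float = 4.114

    def __post_init__(self):
        if not (self.contour_length > 0 and self.persistence_length > 0 and self.kT > 0):
            raise ValueError("all tether parameters must be positive")
        if not self.persistence_length < self.contour_length:
            raise ValueError("persistence length must be below the contour length")


DEFAULT_MODEL = TetherModel()


def wlc_force(x, model: TetherModel = DEFAULT_MODEL):
    """Marko-Siggia interpolation force (pN) at extension x (nm).

    F = (kT/p) [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

    Strictly increasing in x, diverging as x -> Lc.  Accepts scalars or arrays
    with 0 <= x < Lc.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr >= model.contour_length):
        raise ValueError("extension must satisfy 0 <= x < contour_length")
    t = x_arr / model.contour_length
    force = (model.kT / model.persistence_length) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    return float(force) if np.isscalar(x) else force


def wlc_extension_at_force(force: float, model: TetherModel = DEFAULT_MODEL) -> float:
    """Inverse of :func:`wlc_force`: the unique extension x in [0, Lc) with
    wlc_force(x) = force, solved by bracketed root finding to |dF| <= 1e-6 pN."""
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0:
        return 0.0
    upper = model.contour_length * (1.0 - 1e-9)
    return float(brentq(lambda x: wlc_force(x, model) - force, 0.0, upper, xtol=1e-12))


@dataclass(frozen=True)
class ForceBand:
    """Truncated-normal rupture-force distribution (pN); samples in (lo, hi]."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        for _ in range(10000):
            v = rng.normal(self.mean, self.sd)
            if self.lo < v <= self.hi:
                return float(v)
        raise RuntimeError("rupture-force rejection sampling failed to converge")


@dataclass(frozen=True)
class RuptureSpec:
    """Per-type tether counts, rupture-force bands and geometry parameters."""

    nonspecific: ForceBand = ForceBand(150.0, 30.0, 80.0, 200.0)
    single: ForceBand = ForceBand(400.0, 80.0, 200.0, 650.0)
    simultaneous: ForceBand = ForceBand(1000.0, 250.0, 650.0, 2000.0)
    #: sd of the per-tether contour-length jitter (nm), clipped to +-2 sd
    contour_jitter_sd: float = 5.0
    #: first tether anchor offset from contact, nm (uniform bounds)
    anchor_offset: tuple = (0.0, 10.0)
    #: anchor gap between consecutive tethers, nm (uniform bounds)
    anchor_gap: tuple = (15.0, 40.0)
    #: minimum separation between rupture positions, nm (rejection resampling)
    min_rupture_separation: float = 12.0
    #: bounds on the tether count of a multiple-independent curve
    n_independent: tuple = (2, 4)


DEFAULT_SPEC = RuptureSpec()


@dataclass(frozen=True)
class SimCondition:
    """One experimental condition preset: mixture over curve types plus
    tether/noise/acquisition parameters."""

    name: str
    mixture: dict
    noise_sigma: float = 15.0
    tilt_sd: float = 0.02
    z_range: float = 300.0
    samples: int = 1024
    seed: Optional[int] = None

    def __post_init__(self):
        weights = np.array([self.mixture.get(c, 0.0) for c in CurveClass], dtype=float)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")


def preset_pristine() -> SimCondition:
    """Freely accessible streptavidin: specific interactions dominate (~90%
    of curves), multiple-independent detachment the most frequent type."""
    return SimCondition(
        name="pristine",
        mixture={
            CurveClass.TYPE1: 0.06,
            CurveClass.TYPE2: 0.04,
            CurveClass.TYPE3: 0.28,
            CurveClass.TYPE4: 0.37,
            CurveClass.TYPE5: 0.14,
            CurveClass.TYPE6: 0.10,
            CurveClass.TYPE7: 0.01,
        },
    )


def preset_blocked() -> SimCondition:
    """Binding sites blocked with biotinylated albumin: no-interaction curves
    dominate, single interactions outnumber multiple ones."""
    return SimCondition(
        name="blocked",
        mixture={
            CurveClass.TYPE1: 0.37,
            CurveClass.TYPE2: 0.16,
            CurveClass.TYPE3: 0.22,
            CurveClass.TYPE4: 0.13,
            CurveClass.TYPE5: 0.07,
            CurveClass.TYPE6: 0.04,
            CurveClass.TYPE7: 0.01,
        },
    )


class _Tether(NamedTuple):
    anchor: float  # nm from the contact point
    model: TetherModel
    multiplicity: int  # parallel strands sharing the anchor (2 = simultaneous pair)
    f_rupture: float  # total rupture force of the strand group, pN


def _jittered_model(rng, spec: RuptureSpec, base: TetherModel) -> TetherModel:
    jit = float(
        np.clip(rng.normal(0.0, spec.contour_jitter_sd), -2 * spec.contour_jitter_sd, 2 * spec.contour_jitter_sd)
    )
    return dataclasses.replace(base, contour_length=base.contour_length + jit)


def _rupture_z(t: _Tether) -> float:
    return t.anchor + wlc_extension_at_force(t.f_rupture / t.multiplicity, t.model)


def _propose_tethers(
    curve_class: CurveClass, spec: RuptureSpec, rng, base: TetherModel
) -> list[_Tether]:
    a_lo, a_hi = spec.anchor_offset
    g_lo, g_hi = spec.anchor_gap
    if curve_class == CurveClass.TYPE1:
        return []
    if curve_class == CurveClass.TYPE2:
        return [
            _Tether(rng.uniform(a_lo, a_hi), _jittered_model(rng, spec, base), 1, spec.nonspecific.sample(rng))
        ]
    if curve_class == CurveClass.TYPE3:
        return [
            _Tether(rng.uniform(a_lo, a_hi), _jittered_model(rng, spec, base), 1, spec.single.sample(rng))
        ]
    if curve_class == CurveClass.TYPE5:
        return [
            _Tether(rng.uniform(a_lo, a_hi), _jittered_model(rng, spec, base), 2, spec.simultaneous.sample(rng))
        ]
    if curve_class == CurveClass.TYPE4:
        n = int(rng.integers(spec.n_independent[0], spec.n_independent[1] + 1))
        anchor = rng.uniform(a_lo, a_hi)
        tethers = []
        for i in range(n):
            if i:
                anchor += rng.uniform(g_lo, g_hi)
            tethers.append(
                _Tether(anchor, _jittered_model(rng, spec, base), 1, spec.single.sample(rng))
            )
        return tethers
    if curve_class == CurveClass.TYPE6:
        anchor = rng.uniform(a_lo, a_hi)
        tethers = [
            _Tether(anchor, _jittered_model(rng, spec, base), 2, spec.simultaneous.sample(rng))
        ]
        for _ in range(int(rng.integers(1, 3))):
            anchor += rng.uniform(g_lo, g_hi)
            tethers.append(
                _Tether(anchor, _jittered_model(rng, spec, base), 1, spec.single.sample(rng))
            )
        return tethers
    raise ValueError(f"unknown curve class {curve_class!r}")


def _draw_tethers(
    curve_class: CurveClass,
    spec: RuptureSpec,
    condition: SimCondition,
    rng,
    base: TetherModel,
) -> list[_Tether]:
    """Rejection-sample tether sets whose rupture positions are pairwise
    separated (resolvable as independent events) and stay clear of the
    far-field baseline window."""
    # keep rupture positions clear of the far-field baseline window, which
    # starts at 0.7 x z_range on the grid (i.e. 0.7*range - CONTACT_DEPTH from contact)
    z_cap = 0.67 * condition.z_range - CONTACT_DEPTH
    for _ in range(200):
        tethers = _propose_tethers(curve_class, spec, rng, base)
        if not tethers:
            return tethers
        z_r = sorted(_rupture_z(t) for t in tethers)
        if z_r[-1] > z_cap:
            continue
        if all(b - a >= spec.min_rupture_separation for a, b in zip(z_r, z_r[1:])):
            return tethers
    raise RuntimeError(f"could not draw a valid tether set for {curve_class}")


def _render(
    tethers: list[_Tether],
    condition: SimCondition,
    rng,
    dip: Optional[tuple] = None,
    clip_level: Optional[float] = None,
    jump: Optional[tuple] = None,
):
    """Render one retract trace: contact ramp + tether pulls + tilt + noise,
    then optional artifact post-processing (rectangular dip, detector clip,
    baseline step)."""
    z = np.linspace(-CONTACT_DEPTH, condition.z_range - CONTACT_DEPTH, condition.samples)
    f = np.zeros_like(z)
    in_contact = z < 0
    f[in_contact] = CONTACT_STIFFNESS * (-z[in_contact])
    for t in tethers:
        x_star = wlc_extension_at_force(t.f_rupture / t.multiplicity, t.model)
        active = (z > t.anchor) & (z <= t.anchor + x_star)
        if not active.any():
            continue
        f[active] -= t.multiplicity * wlc_force(z[active] - t.anchor, t.model)
        last = int(np.flatnonzero(active)[-1])
        # peak-preserving sampling: pin the final active sample to the rupture force
        f[last] = f[last] + t.multiplicity * wlc_force(z[last] - t.anchor, t.model) - t.f_rupture
    if dip is not None:
        z_start, width, depth = dip
        f[(z >= z_start) & (z <= z_start + width)] -= depth
    slope = rng.normal(0.0, condition.tilt_sd)
    offset = rng.normal(0.0, 5.0) if condition.noise_sigma > 0 else 0.0
    f = f + slope * z + offset
    if condition.noise_sigma > 0:
        f = f + rng.normal(0.0, condition.noise_sigma, size=f.shape)
    if clip_level is not None:
        f = np.clip(f, -clip_level, None)
    if jump is not None:
        z_jump, step = jump
        f[z >= z_jump] += step
    return z, f


def _artifact_pieces(spec: RuptureSpec, condition: SimCondition, rng, base: TetherModel):
    """Randomly choose one artifact mechanism: over-range force, detector
    saturation clip, or a baseline step in the far field."""
    kind = int(rng.integers(3))
    tethers: list[_Tether] = []
    dip = clip_level = jump = None
    if kind == 0:  # over-range simultaneous detachment, beyond the 2000 pN ceiling
        tethers = [
            _Tether(rng.uniform(*spec.anchor_offset), _jittered_model(rng, spec, base), 2, rng.uniform(2050.0, 3000.0))
        ]
    elif kind == 1:  # detector saturation: deep wide dip clipped to a flat plateau
        clip_level = rng.uniform(900.0, 1800.0)
        dip = (rng.uniform(20.0, 60.0), rng.uniform(5.0, 15.0), clip_level + rng.uniform(100.0, 400.0))
    else:  # baseline step inside the far-field window
        window_start = 0.7 * condition.z_range - CONTACT_DEPTH
        z_jump = window_start + rng.uniform(0.2, 0.8) * 0.3 * condition.z_range
        step = float(rng.choice([-1.0, 1.0])) * rng.uniform(800.0, 2000.0)
        jump = (z_jump, step)
    return tethers, dip, clip_level, jump


def simulate_curve(
    curve_class: CurveClass,
    spec: RuptureSpec = DEFAULT_SPEC,
    condition: SimCondition = None,
    rng: np.random.Generator | int | None = None,
    model: TetherModel = DEFAULT_MODEL,
    curve_index: int = 0,
) -> FDCurve:
    """Simulate one retract curve of the requested type; ground truth is
    recorded in ``metadata.true_class``."""
    curve_class = CurveClass(curve_class)
    if condition is None:
        condition = preset_pristine()
    rng = np.random.default_rng(rng)
    dip = clip_level = jump = None
    if curve_class == CurveClass.TYPE7:
        tethers, dip, clip_level, jump = _artifact_pieces(spec, condition, rng, model)
    else:
        tethers = _draw_tethers(curve_class, spec, condition, rng, model)
    z, f = _render(tethers, condition, rng, dip=dip, clip_level=clip_level, jump=jump)
    meta = CurveMetadata(
        condition_label=condition.name,
        curve_index=curve_index,
        true_class=curve_class.value,
    )
    return FDCurve(
        segment=np.full(z.shape, SEGMENT_RETRACT, dtype=object), z=z, force=f, metadata=meta
    )


def single_rupture_curve(
    force: float,
    model: TetherModel = DEFAULT_MODEL,
    noise_sigma: float = 0.0,
    tilt_sd: float = 0.0,
    anchor: float = 5.0,
    z_range: float = 300.0,
    samples: int = 1024,
    rng: np.random.Generator | int | None = None,
) -> FDCurve:
    """One tether with a prescribed rupture force — noise-free by default.

    Used for threshold sweeps and controlled detector tests.
    """
    if not force > 0:
        raise ValueError("rupture force must be positive")
    condition = SimCondition(
        name="sweep",
        mixture={CurveClass.TYPE3: 1.0},
        noise_sigma=noise_sigma,
        tilt_sd=tilt_sd,
        z_range=z_range,
        samples=samples,
    )
    rng = np.random.default_rng(rng)
    tether = _Tether(anchor, model, 1, float(force))
    z, f = _render([tether], condition, rng)
    meta = CurveMetadata(condition_label="sweep", true_class=None)
    return FDCurve(
        segment=np.full(z.shape, SEGMENT_RETRACT, dtype=object), z=z, force=f, metadata=meta
    )


def simulate_curves(
    condition: SimCondition,
    n: int,
    seed: int | np.random.Generator | None = None,
    spec: RuptureSpec = DEFAULT_SPEC,
    model: TetherModel = DEFAULT_MODEL,
) -> list[FDCurve]:
    """Simulate ``n`` curves with true classes drawn i.i.d. from the condition
    mixture; fully reproducible given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    classes = list(CurveClass)
    weights = np.array([condition.mixture.get(c, 0.0) for c in classes], dtype=float)
    draws = rng.choice(len(classes), size=n, p=weights)
    return [
        simulate_curve(classes[k], spec, condition, rng, model, curve_index=i)
        for i, k in enumerate(draws)
    ]


def simulate_batch(
    condition: SimCondition,
    n: int,
    out_dir,
    seed: int | None = None,
    spec: RuptureSpec = DEFAULT_SPEC,
    model: TetherModel = DEFAULT_MODEL,
) -> pd.DataFrame:
    """Simulate a batch, write one file per curve plus a manifest CSV, and
    return the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curves = simulate_curves(condition, n, seed, spec, model)
    records = []
    for curve in curves:
        filename = f"curve_{curve.metadata.curve_index:05d}.tsv"
        write_fd_table(curve, out_dir / filename)
        records.append(
            {
                "filename": filename,
                "curve_index": curve.metadata.curve_index,
                "condition_label": curve.metadata.condition_label,
                "true_class": curve.metadata.true_class,
            }
        )
    manifest = pd.DataFrame(records)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
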
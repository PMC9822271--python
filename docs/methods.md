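# Methods

## Scope and model

`fdclass` analyses AFM force-distance (F-d) retract traces from
single-molecule adhesion experiments in which a biotin-functionalized probe
is cycled against a streptavidin-coated substrate. Each retract trace is
reduced to two experimental magnitudes — the **maximum adhesion force**
`f_max` (positive magnitude of the deepest post-contact force minimum) and
the **number of rupture peaks** — and classified into one of seven groups:

| Code  | Meaning                                | Rule (after artifact screening)     |
|-------|----------------------------------------|-------------------------------------|
| Type1 | no interaction                         | no detected events                  |
| Type2 | non-specific adhesion                  | `f_max <= 200 pN`                   |
| Type3 | single specific interaction            | 1 event, `f_max <= 650 pN`          |
| Type4 | multiple, independent detachment       | >=2 events, `f_max <= 650 pN`       |
| Type5 | multiple, simultaneous detachment      | 1 event, `650 < f_max <= 2000 pN`   |
| Type6 | combined independent + simultaneous    | >=2 events, `650 < f_max <= 2000 pN`|
| Type7 | experimental artifact                  | any quality flag, or `f_max > 2000` |

Band upper limits are inclusive ("upper limit" read as `<=`), with a 1e-9
relative tolerance so that a rupture engineered at exactly a boundary is not
flipped by last-ulp floating-point residue from baseline correction. A curve
with `f_max <= 200 pN` is non-specific regardless of its peak count: the
low-adhesion band is defined purely by force. The success rate is the
fraction of Types 3-6 among **all** recorded curves, artifacts included.

The force bands come from the biotin-streptavidin literature: single
specific unbinding averages ~400 pN (range ~200-1000 pN depending on pulling
geometry and loading rate), non-covalent/non-specific adhesion stays below
~200 pN, and simultaneous detachment of closely spaced pairs has been
reported up to ~2000 pN. Loading-rate (Bell-Evans) dependence of rupture
forces is out of scope; forces are treated as draws from static
distributions at the fixed retract velocity (2600 nm/s) of the emulated
acquisition protocol.

## Preprocessing

- **Baseline**: least-squares line over the farthest 30% of the retract z
  range. Tether events cannot reach this window: the PEG spacer's contour
  length is ~50 nm and the generator keeps all rupture positions <=190 nm
  from contact on a 300 nm ramp, so the far field is event-free by
  construction (and for real data the fraction is configurable).
- **Contact point**: last sample of the leading run whose corrected force
  exceeds +3x the robust noise floor; the curve is re-origined so that the
  contact point is z = 0 and events are measured as distances from contact.
  Curves with no such run are flagged `no-contact` and routed to Type7.
  Simulation at the default noise (sigma = 15 pN) recovers the true contact
  point within 2 nm in >=95% of curves; the residual bias (~threshold /
  contact stiffness, <1 nm) cancels out of all force-based statistics.
- **Smoothing** (Savitzky-Golay, degree 2) is available but **off by
  default**: polynomial smoothing attenuates sharp rupture peaks and so
  biases `f_max` downward. A caveat: a minimal 5-sample quadratic window can
  *overshoot* at the discontinuous release (standard polynomial-fit behavior
  at a kink), so peak attenuation is only monotone from ~9-sample windows
  upward. Detection instead operates on the raw corrected trace with a
  noise-aware threshold.

## Event detection

The noise floor is the scaled median absolute deviation (x1.4826) of the
baseline-window force — robust to isolated spikes and, by construction,
independent of any events. A rupture event is a local force minimum that

1. is deeper than `max(75 pN, 5 x noise floor)` (75 pN keeps weak
   non-specific events, which start at ~80 pN, detectable while holding the
   false-peak rate on pure-noise curves below 1%);
2. has **prominence** at least that same threshold — a genuine rupture rises
   from near baseline and releases back, so its prominence equals its depth,
   whereas a noise spike riding on a stretched tether has large absolute
   depth but prominence of only a few sigma;
3. releases sharply: the force recovers >=50% of the event magnitude within
   5 nm of z. At retract velocities of 1000-2600 nm/s molecular bond rupture
   is abrupt on the z grid, while non-specific adhesion ramps relax
   gradually and are rejected.

Events closer than 8 nm are merged keeping the deeper one — below the
>=12 nm rupture-position spacing the generator guarantees for independent
events, and wide enough to absorb noise-induced satellite minima on the
steep force wall next to a real peak. Simultaneous detachment of several
tethers is deliberately **not** resolved into multiple events; it appears as
one very deep minimum and is separated from single interactions by force
magnitude, which is exactly how the classification is defined.

Artifact screens, in addition to `f_max > 2000 pN`:

- `saturated`: >=5 consecutive bit-identical samples at the raw trace
  minimum at a depth inconsistent with noise (detector clipping leaves exact
  plateaus; the check runs before baseline subtraction, which would destroy
  exact equality).
- `baseline-jump`: standard deviation of the corrected baseline window
  exceeding 5x a first-difference (high-pass) noise estimate. A line fit
  cannot absorb a step discontinuity, so its residual spread explodes, while
  the difference-based noise estimate ignores the single large step. White
  noise has a ratio ~1, so false alarms are negligible.
- `no-contact`: see above.

## Synthetic data generator

The generator emulates retract curves of the two-condition blocking
experiment (250-curve batches per condition in the emulated protocol). Each
curve is rendered on 1024 samples over 300 nm (~0.3 nm resolution, enough to
resolve 5 nm releases), with 10 nm of in-contact travel at 50 pN/nm
repulsive stiffness before the contact point:

- **Tether pulls**: worm-like-chain (Marko-Siggia interpolation) force
  `F = (kT/p)[1/(4(1-x/Lc)^2) - 1/4 + x/Lc]` with contour length
  `Lc = 50 nm` (10 kDa PEG spacer) jittered N(0, 5 nm) per tether (clipped
  at +-2 sd), persistence length `p = 0.38 nm` (standard PEG value; not a
  measured quantity of this system) and `kT = 4.114 pN nm` (298 K). A tether
  contributes until its sampled rupture force is reached, then vanishes.
- **Rupture forces**: Type2 ~ N(150, 30) truncated to (80, 200]; Type3 and
  each independent Type4 tether ~ N(400, 80) truncated to (200, 650]; the
  simultaneous pair of Type5/Type6 ~ N(1000, 250) truncated to (650, 2000]
  combined. The simultaneous pair is modeled as two parallel strands sharing
  an anchor that fail as a cascade (one deep minimum) — multiplicity 2 in
  the force sum.
- **Geometry**: first anchor uniform in [0, 10] nm from contact; subsequent
  anchors at gaps uniform in [15, 40] nm, with rejection resampling until
  all rupture *positions* (anchor + extension at rupture) are pairwise
  >=12 nm apart and <=190 nm from contact. Anchor spacing alone does not
  control rupture-position spacing (extension varies with the sampled force
  and contour length), and positions are what the detector's merge distance
  acts on.
- **Peak-preserving sampling**: the last active sample of each tether is
  pinned to the sampled rupture force. Real acquisitions sample the steep
  WLC wall orders of magnitude more densely than 1024 points; naive
  decimation would clip peaks by up to ~25 pN (the per-sample force step
  near rupture) and bias every force statistic low by a discretization
  artifact rather than anything physical.
- **Noise and drift**: Gaussian force noise sigma = 15 pN, baseline tilt
  slope N(0, 0.02 pN/nm), offset N(0, 5 pN).
- **Artifacts (Type7)**, one mechanism per curve, equiprobable: over-range
  simultaneous detachment (rupture force uniform in [2050, 3000] pN);
  detector saturation (a 5-15 nm deep dip clipped to an exact plateau at
  900-1800 pN); baseline step of +-800-2000 pN placed inside the far-field
  window.

**Condition presets** (mixture weights over types): the printed composition
constraints of the emulated experiment — success ~90%, Type1+Type2 = 10%,
Type7 ~ 1%, the pristine frequency ordering T4 > T3 > T5 > T6, blocked
T1 = 37% with T1+T2 > 50% and T3 > T4 — cannot all hold simultaneously
(10% + 1% + 90% > 100%). The presets honor T1+T2 = 10% and T7 = 1% exactly,
leaving success = 89%:

- pristine: T1 .06, T2 .04, T3 .28, T4 .37, T5 .14, T6 .10, T7 .01
- blocked:  T1 .37, T2 .16, T3 .22, T4 .13, T5 .07, T6 .04, T7 .01

What the generator does **not** emulate: loading-rate dependence, thermal
cantilever dynamics, hydrodynamic drag, approach-segment physics beyond the
linear contact ramp, instrument drift between curves (the temporal series is
i.i.d., so the drift profile is stationary by construction), and freely
jointed chain behavior of short tethers. Passing tests therefore demonstrate
that the analysis recovers the truth of this model class, not that it is
correct for any particular instrument's artifacts.

## Batch statistics

- Type percentages are over all classified curves (including Type7).
- Adhesion histograms use half-open 50 pN bins over [0, 2100) plus an
  overflow bin; 50 pN places the 200 and 650 pN boundaries on bin edges.
- The drift profile uses consecutive non-overlapping windows of 50 curves;
  `delta_pct = window % - overall %` per class. With equal partitioning
  windows the per-class deltas average to zero exactly (algebraic identity);
  the overall mean is computed over all curves of the condition, which
  coincides with the mean of window percentages when windows partition
  evenly. A trailing partial window is reported but flagged and excluded
  from the identity.
- RMS roughness of a height map is the root-mean-square deviation about the
  mean or about the best-fit plane (`plane_correct=True`).

## Numerical choices and problem sizes

- WLC inversion by bracketed root finding (`brentq`) on [0, Lc(1-1e-9)],
  accurate to |dF| <= 1e-6 pN.
- Truncated normals by rejection sampling; all randomness flows from a
  single `numpy` Generator per batch, so batches are byte-reproducible given
  a seed (files are written with fixed %.6f formatting). Experiment configs
  require explicit seeds; nothing is clock-seeded.
- Composition checks simulate 2000 curves per condition (binomial standard
  error ~0.7 percentage points on the success rate); force recovery uses 500
  single-interaction curves (standard error ~3.6 pN); boundary sweeps use
  noise-free curves in 1 pN steps. These sizes make the stochastic checks
  decisive at the stated tolerances while keeping a full run in tens of
  seconds on one core.

## Known limitations

- Artifact criteria for real data are inherently instrument-specific; the
  three implemented screens cover the mechanisms the generator injects and
  common hard failures, nothing more. Curves with `f_max` between 2000 pN
  and detector saturation are discarded as artifacts by rule, a choice the
  emulated protocol leaves open.
- Event *counting* at forces within a few sigma of the detection threshold
  is probabilistic; a small fraction of weak non-specific events is missed
  (classified Type1 instead of Type2 — the combined low-adhesion fraction is
  unaffected).
- No WLC fitting of individual pulls in the analyzer: the detector is
  deliberately model-agnostic so that the generator and the analysis do not
  share assumptions beyond what a real instrument would provide.
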
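# fdclass

Classification and batch statistics of AFM force-distance (F-d) curves from
single-molecule adhesion experiments — the kind performed with a
biotin-functionalized probe against a streptavidin-coated substrate, with a
biotin-albumin-blocked substrate as the negative control.

Single-molecule force spectroscopy produces hundreds of retract traces per
tip-substrate pair; the question is always the same: *which curves show a
specific ligand-receptor interaction, how strong is it, and does the probe
degrade over the series?* `fdclass` answers this by reducing each
baseline-corrected retract trace to two magnitudes — the maximum adhesion
force `F` (pN) and the number of rupture peaks `n` — and classifying it:

| Type | Interpretation                         | Rule                       |
|------|----------------------------------------|----------------------------|
| 1    | no interaction                         | `n = 0`                    |
| 2    | non-specific adhesion                  | `F <= 200 pN`              |
| 3    | single specific interaction            | `n = 1`, `F <= 650 pN`     |
| 4    | multiple, independent detachment       | `n >= 2`, `F <= 650 pN`    |
| 5    | multiple, simultaneous detachment      | `n = 1`, `650 < F <= 2000` |
| 6    | combined independent + simultaneous    | `n >= 2`, `650 < F <= 2000`|
| 7    | experimental artifact                  | quality flag or `F > 2000` |

Types 3-6 count as successful specific events; the success rate is their
fraction of *all* recorded curves. On top of the per-curve pipeline the
package computes type distributions, adhesion-force histograms, a 50-curve
windowed drift profile of the temporal series, and RMS surface roughness of
probe height maps.

Because instrument data of this kind are rarely public, the package includes
a first-class physics-based generator: worm-like-chain (Marko-Siggia) tether
pulls through a ~50 nm PEG spacer with type-conditioned rupture-force
distributions (single interactions ~N(400, 80) pN truncated to (200, 650]),
Gaussian force noise, baseline tilt, and injected artifacts, under two
condition presets (`pristine`, `blocked`). See `docs/methods.md` for the
full model and every default.

## Worked example

```python
import fdclass as fd

curves = fd.simulate_curves(fd.preset_pristine(), 250, seed=11)
results = fd.classify_curves(curves)          # one row per curve
dist = fd.type_distribution(results)

print("n =", dist.n_total)
for code, pct in dist.percentages.items():
    print(f"  {code}: {pct:5.1f} %")
print(f"success rate: {fd.success_rate(dist):.3f}")

feats, cls, _ = fd.analyze_curve(curves[1])
print("curve 1:", curves[1].metadata.true_class, "->", cls.value,
      f"n_events={feats.n_events} f_max={feats.f_max:.1f} pN")
```

prints

```
n = 250
  Type1:   7.2 %
  Type2:   6.0 %
  Type3:  28.4 %
  Type4:  36.0 %
  Type5:  12.8 %
  Type6:   8.4 %
  Type7:   1.2 %
success rate: 0.856
curve 1: Type4 -> Type4 n_events=3 f_max=431.2 pN
```

The 250-curve batch lands near the pristine preset's composition (success
rate 0.89 in expectation; a single batch fluctuates by a couple of
percentage points), Type 4 — several tethers detaching independently — is
the most frequent class, and the example curve's three rupture peaks with a
431 pN maximum adhesion force put it in Type 4, matching its generator
ground truth.

The same pipeline runs from the shell:

```sh
fdclass simulate --condition pristine -n 250 --seed 11 --out batch/
fdclass classify batch/ --out results.csv
fdclass stats results.csv --window 50 --bin 50 --out report.json
fdclass run --config experiment.yaml --out bundle/   # two-condition experiment
```

where `experiment.yaml` names the conditions, batch sizes and (mandatory)
seeds:

```yaml
conditions:
  - {name: pristine, preset: pristine, n: 250, seed: 11}
  - {name: blocked,  preset: blocked,  n: 250, seed: 12}
```

Real instrument data enter through the same door: one TSV per curve
(`segment`, `z_nm`, `force_pN` or `deflection_V` columns, `#` key=value
header with the spring constant and deflection sensitivity) plus a manifest
CSV — see `fdclass.curve_io`.

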
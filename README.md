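# popgeom

A toolkit for **neural population geometry**: given a stimulus–response
tensor (neurons × stimulus sequences × time, e.g. trial-averaged PSTHs of a
recorded population or of units inside an artificial network), it builds the
three complementary views used to compare such systems at the population
level:

1. **Decoding manifolds & trajectories** — stimulus conditions embedded in
   PCA-reduced neural coordinates. Each condition's time-averaged population
   vector becomes one point of the manifold; treating each time step as a
   separate point turns every condition into a time-indexed *decoding
   trajectory*. Classification accuracy and per-neuron orientation/direction
   selectivity (circular-variance OSI/DSI) quantify stimulus separability,
   and neuron-group ablation (e.g. removing a non-selective "intensity arm")
   probes what drives the temporal development of activity.
2. **Encoding manifolds** — neurons embedded in stimulus-response space via
   non-negative CP tensor factorization (HALS), an adaptive-bandwidth
   similarity graph on the neuron loadings, and a diffusion-map embedding.
   Topology statistics summarise whether the population is organised into
   discrete functional types (clustered, retina-like) or a continuum
   (cortex-like).
3. **Tubularity metrics** — same-stimulus trajectories form "tubes" in
   healthy representations. `S_tight ∈ [0, 1]` is the time-averaged ratio
   `b/(b + 2w)` of between-bundle centroid spacing `b` to tube spread `w`;
   `S_cross ∈ [0, 1]` is the rate at which cross-class trajectory pairs
   exchange order along their centroid axis (per pair, per time step). A
   seeded within-class bootstrap compares two systems' scores with
   Bonferroni correction.

A fourth module scores **representational alignment** between two systems on
a shared stimulus set: RSA (Spearman correlation of representational
dissimilarity matrices), CCA (mean canonical correlation after PCA
reduction), linear predictivity (cross-validated ridge, both directions),
and DSA (similarity of fitted one-step linear dynamics operators up to an
orthogonal change of basis), plus their arithmetic mean.

Because real recordings and large pretrained models are heavy, the
`synthetic` module generates everything needed to exercise and validate the
pipeline: a parametric stimulus ensemble (by default 88 unique sequences —
6 base classes of drifting gratings and optical-flow patterns, 11 variants
in total, each drifting in 8 directions), von-Mises-tuned populations with
planted ground truth, geometric trajectory bundles with a known number of
planted crossings, and linear dynamical systems for DSA validation.

## Worked example

```python
import popgeom as pg

ensemble = pg.make_stimulus_ensemble()            # 88 sequences, 6 classes, 8 directions
tensor, truth = pg.simulate_population(ensemble, seed=0)

res = pg.DecodingModel(tensor).fit(n_dims=3)
print(res.summary())

tub = pg.TubularityModel(res.trajectories).fit()
print(tub.summary())
```

prints

```
Decoding analysis
========================================
grouping:            class-direction
analysis units:      48
neurons:             120
time bins:           20
embedding dims:      3
explained variance:  0.096, 0.093, 0.079
accuracy (NC-LOO):   1.000

Tubularity analysis
========================================
trajectories:        48 in 6 classes
time steps / dims:   20 / 3
S_tight:             0.3855
S_cross:             0.0274
per-class tightness: grating=0.343, flow-1dot=0.362, ...
```

The 88 sequences collapse to 48 analysis units (6 classes × 8 directions,
variants averaged), each a point on the decoding manifold. Accuracy 1.000
means leave-one-out nearest-centroid decoding reads the base class perfectly
from the time-averaged population state at this noise level. `S_tight ≈ 0.39`
says the class tubes are spaced at roughly two thirds of their combined
spread; `S_cross ≈ 0.03` means about 3% of cross-class pair-steps exchange
order — loose but structured bundles, as expected for mildly noisy tuned
populations.

The CLI mirrors the library:

```bash
popgeom simulate --seed 1 --out tensor.h5
popgeom decode summary --input tensor.h5
popgeom encode --input tensor.h5 --rank auto --out embedding.csv
popgeom run --config examples/demo_config.yaml --out runs/demo
```

`popgeom run` executes the whole synthetic study (two populations →
decoding → encoding → tubularity → alignment) and writes tensors (HDF5),
coordinate exports (CSV), score reports (JSON), a log of every seed and
parameter, and a manifest of produced artifacts. Re-running the same config
reproduces every number.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full synthetic-study pipeline from scratch under the given
seed (all stage seeds derive from it deterministically) and writes the
acceptance JSON to `--out`.
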
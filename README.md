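# smlmkit

Acquisition-speed planning and fit-quality control for single-molecule
localization microscopy (PALM/STORM).

## The problem

In localization microscopy the reconstruction is assembled from fluorophore
positions fitted one camera frame at a time.  Two activations closer
together than the minimum separation *r* that the fitting algorithm can
handle spoil each other: the fit is rejected, or worse, silently biased
toward their mean position (*artificial sharpening*).  Modelling each
activation as excluding further activations from the area
**E = c·r^D** — the intersection of a disc of radius *r* with the labelled
structure, where *D* is the structure's local dimensionality (0 for a
point, 1 for a filament with *E ≈ 2wr*, 2 for an extended patch with
*E ≈ πr²*) — gives a closed-form estimate of the frames needed to reach a
target localization density *Q*:

```
T(a) = Q / (a · exp(−a·E)),     a* = 1/E,     T_min = e·Q·E
```

with *a* the activation density (activations per unit area per frame).
Because *E* grows like *r^D*, every added dimension costs roughly an order
of magnitude in acquisition time — a filament can be imaged ~40–90× faster
than a focal adhesion at equal target density.

Above the optimum, fitting failures are *silent*: counting all returned
localizations, the data appear to improve with density while the
reconstruction fills with overlap artefacts.  The package therefore also
implements a per-dataset quality classifier: 21×21-pixel patches around
each localization (current, previous and next frame) are aligned, windowed
and log-transformed, compressed to 20 dimensions with a PCA fitted on that
acquisition, and a 300-tree random forest trained on ~300 labelled
localizations sorts the rest into **good / background / too dense**.

Everything is testable without external data: a Markov-chain
blinking simulator with a pixel-integrated Gaussian PSF and an EMCCD noise
model generates ground-truth acquisitions, and a reference single-emitter
localizer closes the loop.

## Worked example

```bash
python examples/plan_acquisition.py
```

prints (target *Q* = 1 localization per 5×5 nm, *r* = 440 nm):

```
1D strand (8 nm wide)
  exclusion area E = 7,040 nm^2 = 0.0070 um^2
  optimal activation a* = 142.05 /um^2/frame
  minimum frames T_min = 765

2D plane
  exclusion area E = 608,212 nm^2 = 0.6082 um^2
  optimal activation a* = 1.64 /um^2/frame
  minimum frames T_min = 66,132

  2D / 1D frame ratio: 86
```

i.e. the same reconstruction density that takes ~765 frames on a filament
takes ~66,000 frames on an extended structure, and the best activation
density differs by two orders of magnitude.  The other examples cover the
simulator (`simulate_and_localize.py`), the two-emitter sweep that measures
*r* for the bundled fitter (`estimate_exclusion_radius.py`), quality
classification on the four-vesicle overlap benchmark
(`classify_quality.py`) and FRC-based evaluation
(`evaluate_resolution.py`).

A thin CLI wraps the same calls:

```bash
smlmkit plan --structure strand --width-nm 7 --radius-nm 400 --target-q 0.04
smlmkit simulate strand_1d --frames 200 --seed 1 --out-dir out/
smlmkit localize out/strand_1d.tif --out out/locs.csv
smlmkit evaluate --locs out/locs.csv --n-frames 200
```

Localization tables use the ThunderSTORM-compatible CSV dialect
(`x [nm]`, `intensity [photon]`, …); stacks are plain multi-page TIFF.

## Layout

| module | contents |
| --- | --- |
| `smlmkit.geometry` | exclusion areas, T(a), optima, speed ratios |
| `smlmkit.simulate` | structures, emitter seeding, Markov blinking, EMCCD rendering |
| `smlmkit.localize` | reference detector/fitter, rejection, separation sweep |
| `smlmkit.features` | patch triples, alignment, log transform, per-acquisition PCA |
| `smlmkit.classify` | oracle labeller, stratified sampling, random forest |
| `smlmkit.evaluate` | reconstructions, FRC, density estimators, extrapolation |
| `smlmkit.experiments` | scripted density-ladder experiments |
| `smlmkit.io` | CSV/TIFF/YAML round trips, fixtures, seed substreams |

See `docs/methods.md` for the modelling assumptions, defaults and known
limitations.
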
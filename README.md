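# mtquant

Quantification pipeline for four fluorescence-microscopy measurements used
in studies of microtubule (MT) regulation by depolymerizing kinesins
(kinesin-13 family), together with a synthetic-scene simulator that renders
each kind of data with known ground truth:

1. **MT bundling** — fields of rhodamine-labeled MTs are segmented into
   regions of interest (ROIs); bundles of k laterally cross-linked MTs are
   ≈k× brighter per pixel than single filaments, so the *bundling fraction*
   — the fraction of total ROI area whose mean normalized intensity exceeds
   a threshold (0.4 by default) — quantifies bundling activity per image,
   and conditions are compared by Welch t-tests across slide images.
2. **MT depolymerization** — filament lengths are measured at two time
   points (0 s and 400 s by convention) and the shrinkage rate is
   (L(t₀) − L(t₁))/(t₁ − t₀) per filament, in µm/min, summarized as
   mean ± SEM.
3. **Mitotic-spindle geometry** — from XY kinetochore centroids per cell:
   the spindle-equator line by total least squares (the principal axis of
   the kinetochore cloud), signed perpendicular distances dᵢ to it, and the
   metrics SD = std(dᵢ), AvgDist = mean|dᵢ|, KW (2–98 percentile width
   along the equator), SL (pole-to-pole length), SW (tubulin-mask width
   perpendicular to the pole axis); plus metaphase-plate selection,
   cross-cell rigid alignment for pooled distributions, and
   lagging-kinetochore scoring in anaphase.
4. **Tubulin poleward flux** — a kymograph is resliced along the spindle
   axis of a GFP-tubulin movie; photobleached stripes translate poleward,
   and their slope in the kymograph (tracked per row, fitted by least
   absolute deviations) gives the flux rate:
   rate = |slope| · pixel_size / frame_interval · 60 (µm/min).

The simulator (`mtquant.synthetic`) renders straight filaments of uniform
linear photon density through an isotropic Gaussian PSF with Poisson shot
noise, two-row kinetochore distributions with controllable scatter, and
spindle bands with moving bleach stripes — always returning the generative
ground truth so every estimator can be validated by parameter recovery.

## Worked example

```python
from mtquant.synthetic import FluxMovieParams, render_flux_movie
from mtquant.kymograph import estimate_flux

params = FluxMovieParams(flux_rate_um_per_min=0.9, seed=3)  # 5 s frames
movie, truth = render_flux_movie(params)
h, w, px = movie.shape[-2], movie.shape[-1], movie.pixel_size_um
line = ((0.5 * px, h / 2 * px), ((w - 0.5) * px, h / 2 * px))
est = estimate_flux(movie, line)
print(f"true {truth.flux_rate_um_per_min:.2f}  "
      f"recovered {est.mean_rate_um_per_min:.3f} um/min  "
      f"per mark {[round(r, 3) for r in est.rates_um_per_min]}")
```

prints

```
true 0.90  recovered 0.916 um/min  per mark [0.9, 0.933]
```

— the two bleach marks (one per half-spindle) move in opposite directions
at the same speed; their |rates| are averaged. The ~2% deviation at this
seed is shot-noise scatter; across seeds and rates the mean absolute
relative error stays below 2% (see the acceptance script).

The same end-to-end loop is available for every stage from the command
line: `mtquant demo --seed 1 --out out/` simulates wild-type-like and
mutant-like condition groups and writes a JSON report with all five metric
families (bundling fraction, shrinkage rate, SD/AvgDist, SL/SW/KW, flux
rate). `mtquant simulate/bundling/depoly/spindle/flux` expose the
individual stages on TIFF/CSV inputs.

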
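# condensate-tools

Quantitative analysis of liquid-like nuclear protein condensates — the
micron-scale droplets that chromatin factors such as SS18 (a BAF-complex
subunit) form by liquid–liquid phase separation — together with the tabular
statistics that accompany such studies: pooled CRISPR-screen count
normalization and chromatin-site relocation.

The package is built around a synthetic-data module that generates every
observable with known ground truth, so each analysis stage is testable
end-to-end without microscope or sequencing data.

## What it computes

* **FRAP** — normalized recovery traces from bleach experiments, fit to
  `I(t) = i0 + (P − i0)(1 − e^(−t/τ))` for the recovery time `τ` and mobile
  fraction (plateau) `P`; order-of-magnitude diffusion `D ~ L²/τ`;
  position-vs-time kymographs along a line.
* **Detection / tracking / events** — LoG + half-max segmentation of
  condensates, greedy nearest-neighbour tracking, fusion and fission calls
  with an area-conservation check.
* **Fusion kinetics** — aspect-ratio relaxation
  `AR(t) = 1 + (ar0 − 1)e^(−t/τ_f)` per event, and the linear size scaling
  `τ_f ≈ K·d` across events (OLS slope `K` in s/µm with standard error).
* **Colocalization** — two-channel line profiles across condensates,
  Pearson r plus baseline enrichment, and dispersal/washout (hexanediol-
  style) response: per-condensate dispersal times and the recovered
  fraction.
* **Screen statistics** — `counts/sum × 10⁶ + 1` normalization, log₂
  five-number summaries, two-sided Wilcoxon rank-sum comparisons (exact for
  small groups), per-sgRNA log₂ fold changes, and a permutation gene score.
* **Relocation** — fold-change classification of genomic sites
  (up / permanent / down) and the relocation rate
  `mean(factor @ up) / mean(factor @ down)`.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

Simulate a bleach series for one condensate (recovery time 1.841 s, mobile
fraction 66.18%) and refit it from the rendered images:

```sh
$ condensate simulate frap --out-prefix scratch/frap --seed 1
wrote scratch/frap.tif and scratch/frap_rois.json

$ condensate frap --stack scratch/frap.tif --roi scratch/frap_rois.json \
      --bleach-frame 5 --out scratch/fits.tsv
inside: tau = 1.841 s, plateau = 66.18%, D ~ 1.13 um^2/s
outside: tau = 1.905 s, plateau = 79.91%, D ~ 1.09 um^2/s
```

The fitted `tau`/`plateau` reproduce the generator's parameters because the
trace extraction and normalization are exact on noiseless input; `D` is the
order-of-magnitude estimate `L²/τ` for this bleach-spot diameter (1.44 µm).

The same round trip from the library:

```python
from condensate import frap, synth_data
from condensate.io_formats import CircleRoi, ImagingMeta

meta = ImagingMeta(pixel_size_um=0.1, frame_interval_s=0.2, height_px=64, width_px=64)
droplet = synth_data.DropletSpec((31.5, 31.5), diameter_um=3.0, peak_intensity=100.0)
bleach = CircleRoi((31.5, 31.5), diameter_um=1.5)
truth = synth_data.FrapTruth(1.841, 66.18, 20.0, bleach_frame=5, bleach_roi=bleach)
stack, _ = synth_data.simulate_frap_series(meta, droplet, truth, n_frames=60)

trace = frap.extract_recovery_trace(stack, bleach, 5, CircleRoi((8.0, 8.0), 0.6))
fit = frap.fit_recovery(trace)
print(f"tau = {fit.tau_s:.3f} s, plateau = {fit.plateau_pct:.2f}%")
# tau = 1.841 s, plateau = 66.18%
```

A fusion movie, tracked and fitted:

```sh
$ condensate simulate fusion --out-prefix scratch/fu --seed 2 --noise-sigma 1
wrote scratch/fu.tif (tau_f = 1.838 s)
$ condensate fusion --stack scratch/fu.tif --out scratch/fu_fits.tsv
1 fusion fits -> scratch/fu_fits.tsv
```

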
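# ribbonquant

Quantification pipeline for zebrafish lateral-line hair-cell ribbon synapses
and their Ca²⁺/fluorescence dynamics. The package re-implements, as a tested
and reusable library, the image- and trace-analysis computations used to
quantify:

* **synapse morphology** — 3D segmentation of presynaptic ribbon (Ribeye b)
  and postsynaptic-density (MAGUK) immunolabel puncta from confocal
  Airyscan-style Z-stacks, with per-punctum projected 2D area and integrated
  intensity;
* **synapse pairing** — matching each ribbon to its postsynaptic partner by
  3D centroid distance against a radius-sum threshold, counting complete
  synapses, orphan puncta and extrasynaptic Ribeye aggregates, and measuring
  Ca_V_1.3-channel immunolabel intensity inside ribbon ROIs;
* **fluorescence traces** — evoked ΔF/F₀ with per-indicator activity
  thresholds, spontaneous-activity magnitude and frequency from
  percentile-baselined, noise-thresholded traces, divisive photobleaching
  correction, two-channel Pearson correlation, mock-control normalization,
  and four-parameter logistic (4PL) dose–response fitting for IC₅₀;
* **synthetic phantoms** — a first-class generator of image stacks and trace
  sets with exact ground truth, so every stage can be validated without any
  microscope data.

It is written for researchers quantifying punctate synaptic immunolabel and
calcium-indicator recordings who want the full chain — phantom → segmentation
→ pairing → statistics — scripted, seeded and testable.

## The core computations

**Pairing threshold.** Each punctum's max-projection footprint of area *A*
(µm²) is treated as a disc of radius √(*A*/π). A ribbon and a PSD form a
synapse when their 3D centroid distance *d* satisfies

    d ≤ √(A_ribbon/π) + √(A_PSD/π)

with one-to-one greedy matching in ascending distance. Minimum projected
areas of 0.08 µm² (ribbon) and 0.04 µm² (PSD) reject sub-resolution specks;
extrasynaptic Ribeye aggregates are counted from an unfiltered pass.

**Evoked traces.** F₀ is the mean pre-stimulus fluorescence;
ΔF/F₀ = (F − F₀)/F₀. A cell is active when max ΔF/F₀ strictly exceeds 0.25
(membrane-localized GCaMP6sCAAX) or 0.05 (mitochondria-targeted indicators).

**Spontaneous traces.** After divisive mono-exponential bleach correction,
F₀ is the bottom 15th percentile of the trace; ΔF/F₀ samples below 10% are
treated as noise and zeroed. Magnitude = suprathreshold ΔF/F₀ sum / number
of frames (300 frames for a 900 s recording at 0.33 Hz); frequency = local
maxima of the thresholded trace per second.

**Dose–response.** response(d) = bottom + (top − bottom)/(1 + (d/IC₅₀)^h),
fitted by least squares with a variable Hill slope *h*.

## Worked example

```python
from ribbonquant import synthdata as S, experiments as E, pairing as PR, traces as T

# phantom: 4 cells x 3 ribbons, 10 of 12 paired, 2 extrasynaptic aggregates
spec = S.ImagePhantomSpec(n_cells=4, ribbons_per_cell=3, paired_fraction=10/12,
                          n_extrasynaptic=2, seed=42)
stacks, truth = S.simulate_stack(spec)
ribbons = E.segment_channel(stacks, "ribbon")
psds = E.segment_channel(stacks, "psd")
pairs, summary = PR.pair_synapses(ribbons, psds)
print(f"complete synapses: {summary.n_pairs}  orphan ribbons: {summary.n_unpaired_ribbons}")

df = S.simulate_dose_response(1.37, 1.0, 0.0, 1.0, [0, 0.5, 2, 5, 10],
                              noise_sd=0.01, seed=3)
fit = T.fit_4pl(df.dose_uM.to_numpy(), df.response.to_numpy())
print(f"IC50 = {fit.ic50:.2f} uM, Hill slope {fit.hill:.2f}")
```

prints

```
complete synapses: 10  orphan ribbons: 2
IC50 = 1.45 uM, Hill slope 0.85
```

The 10 recovered synapses match the phantom's ground-truth pair table
exactly; the two orphan ribbons are the unpaired ones the generator planted.
The fitted IC₅₀ recovers the planted 1.37 µM from five doses with 1%
measurement noise.

The same pipeline is scriptable from the shell:

```sh
ribbonquant simulate-image --seed 42 --out phantom/
ribbonquant segment --input phantom/ribbon.tif --channel ribbon --out run/
ribbonquant segment --input phantom/psd.tif --channel psd --out run/
ribbonquant pair --ribbons run/puncta_ribbon.csv --psds run/puncta_psd.csv --out run/
```

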
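# phasetag

Cationic peptide tag design and per-cell condensate detection in bacterial
fluorescence micrographs.

Appending a short cationic tag to a protein of interest can drive its
liquid–liquid phase separation with endogenous RNA in *E. coli*, sequestering
it into intracellular condensates without re-engineering the protein surface.
`phasetag` packages the two computational halves of that workflow for
synthetic-biology and biophysics groups:

* **sequence tools** — an integer net-charge model at neutral pH
  (K/R = +1, D/E = −1, H neutral, termini ignored), proteome-wide charge
  distributions, and a designer for C-terminal `[GGSKKRKKR]n` tags.  Each
  nine-residue repeat (4 K + 2 R) adds **+6**; a lysine linker fine-tunes by
  +1.  The design rules: a fusion net charge of exactly **+6** sits at the
  intracellular phase-separation threshold and yields *transient* condensates
  (they assemble mid-growth and disassemble again), while **≥ +12** yields
  *persistent* condensates.
* **image analysis** — the MicrobeJ-style detection chain for rod-shaped
  bacteria: rolling-ball background subtraction (radius 100 px), Li
  minimum-cross-entropy thresholding, shape-constrained segmentation with
  medial axes, then per-cell condensate calling: pixels at least
  τ = 1.20 times brighter than the cytoplasm reference at the cell midpoint
  form foci.  Strain-level statistics: the fraction of condensate-containing
  cells (cutoff 0.11 separates condensate-forming strains from the detector's
  false-positive floor), a τ ∈ [1.05, 2.00] sweep probing the condensed/dilute
  partition ratio ρ, and none/transient/persistent classification over a
  growth time course.

A deterministic synthetic-scene generator (spherocylindrical cells with known
per-cell partition ratio, PSF blur, Poisson + Gaussian camera noise, full
ground truth) makes every stage testable without any experimental data.

## Worked example

```python
import numpy as np
import phasetag as pt

params = pt.SceneParams(image_shape=(512, 512), n_cells=40,
                        condensate_fraction=0.6, partition_ratio=1.7, seed=42)
img, truth = pt.generate_scene(params)

sub = pt.rolling_ball_subtract(img, radius_px=100)
regions = pt.segment_cells(sub)
calls = pt.call_cells(regions, sub, threshold=1.20)
result = pt.fraction_with_condensates(calls)

print(f"fraction with condensates: {result.fraction:.3f}")
enr = [c.enrichment_ratio for c in calls if c.has_condensate]
print(f"mean enrichment ratio: {np.mean(enr):.2f}")
print(f"condensate-forming strain: {pt.classify_strain(result)}")
```

prints

```
fraction with condensates: 0.475
mean enrichment ratio: 1.62
condensate-forming strain: True
```

All 40 cells are segmented; the measured fraction equals the ground-truth
carrying fraction of this scene (0.475), the per-cell enrichment ratio
recovers the true condensed/dilute ratio ρ = 1.7 to within a few percent, and
the fraction clears the 0.11 cutoff, so the strain is scored
condensate-forming.  The `examples/` directory has one short script per
capability (tag design, proteome charge distribution, simulate-and-call,
threshold sweep, time-course classification); each prints the numbers it
computes and what they mean.

The same chain is available from a shell:

```bash
phasetag simulate --rho 1.7 --n-cells 40 --out scene.tiff
phasetag call scene.tiff --threshold 1.2 --out calls.csv
phasetag design-tag --domain-charge -7 --mode transient
phasetag run --demo --out results/
```

## Layout

```
src/phasetag/
  charge.py      net charge, proteome CDF, tag designer
  synthdata.py   synthetic scenes and growth tables with ground truth
  micrograph.py  image container + TIFF I/O
  segment.py     rolling ball, Li threshold, shape-filtered cell regions
  call.py        condensate calls, fraction statistic, threshold sweep
  timecourse.py  replicate aggregation, persistence classes, expression proxy
  config.py      declarative pipeline configuration (YAML, content hash)
  pipeline.py    simulate -> segment -> call -> classify, seeded end to end
  cli.py         thin click front end
docs/methods.md  model, estimators, parameter choices, limitations
```
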
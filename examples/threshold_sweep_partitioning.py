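"""Probe condensate partitioning with a ratio-threshold sweep.

Two populations with different true partition ratios (rho = 1.3 and 1.8) are
swept over detection thresholds 1.05..2.00.  The fraction of positive cells
drops near each population's true rho, so the sweep curve reads out how
strongly the protein partitions into the condensed phase.
"""

import phasetag as pt

for rho in (1.3, 1.8):
    params = pt.SceneParams(
        image_shape=(448, 448), n_cells=30, condensate_fraction=1.0,
        partition_ratio=rho, psf_sigma=0.0, poisson_gain=None,
        read_noise_sigma=0.0, background_intensity=0.0, seed=7,
    )
    img, _ = pt.generate_scene(params)
    regions = pt.segment_cells(img)
    sweep = pt.threshold_sweep(regions, img, [1.05, 1.25, 1.45, 1.65, 1.85])
    fractions = " ".join(f"{f:.2f}" for f in sweep.fraction)
    print(f"true rho {rho}: fractions over tau 1.05..1.85 -> {fractions}")

print(
    "\nFractions are non-increasing in the threshold by construction; the "
    "step locates the true condensed/dilute ratio of each population."
)
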
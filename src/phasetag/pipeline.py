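"""End-to-end chain: simulate -> subtract -> segment -> call -> classify.

One global seed fans out deterministically to per-stage seeds: the seed for a
stage keyed by tags ``(variant, replicate, timepoint)`` is drawn from
``numpy.random.SeedSequence([global_seed, crc32("variant/rep/time")])``, so
any single stage can be re-run in isolation and reproduce its output exactly.

Outputs are plain CSVs (each stamped with the config hash on a leading
comment line) plus a machine-readable JSON manifest.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import call as callmod
from . import segment as segmod
from .config import PipelineConfig
from .synthdata import generate_scene
from .timecourse import aggregate, persistence_class

logger = logging.getLogger(__name__)


def seed_for(global_seed: int, *tags) -> int:
    """Deterministic per-stage seed derived from the global seed and tags."""
    key = zlib.crc32("/".join(str(t) for t in tags).encode())
    ss = np.random.SeedSequence([int(global_seed), key])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_stamped_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read a pipeline CSV, skipping the config-hash comment line."""
    return pd.read_csv(path, comment="#")


def process_image(img, config: PipelineConfig):
    """Subtract background, segment, and call one micrograph.

    Returns ``(subtracted, regions, calls)``.
    """
    sub = segmod.rolling_ball_subtract(
        img, radius_px=config.segmentation.rolling_ball_radius_px
    )
    regions = segmod.segment_cells(sub, config.segmentation.constraints)
    calls = callmod.call_cells(
        regions,
        sub,
        threshold=config.calling.threshold,
        min_focus_px=config.calling.min_focus_px,
        disk_radius_px=config.calling.disk_radius_px,
    )
    return sub, regions, calls


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> dict:
    """Run the full synthetic experiment described by ``config``.

    For every (variant, replicate, timepoint) cell of the design a scene is
    simulated, background-subtracted, segmented and called; fractions are
    aggregated per variant and classified as none/transient/persistent.
    Writes ``fractions.csv``, ``classification.csv``, optionally
    ``sweep.csv``, and ``manifest.json``; returns the manifest.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash
    logger.info("running pipeline, config hash %s", chash)

    fraction_rows = []
    sweep_frames = []
    class_rows = []
    final_time = max(config.variants[0].fractions_by_time)

    for variant in config.variants:
        per_replicate: dict[str, dict[float, float]] = {}
        for rep in range(config.n_replicates):
            rep_id = f"rep{rep + 1}"
            series: dict[float, float] = {}
            for t, true_fraction in sorted(variant.fractions_by_time.items()):
                params = replace(
                    config.scene,
                    condensate_fraction=true_fraction,
                    seed=seed_for(config.seed, variant.name, rep_id, t),
                )
                img, _truth = generate_scene(params)
                sub, regions, calls = process_image(img, config)
                if not calls:
                    logger.warning(
                        "%s %s t=%g h: no cells segmented", variant.name, rep_id, t
                    )
                    continue
                fr = callmod.fraction_with_condensates(calls)
                series[t] = fr.fraction
                fraction_rows.append(
                    dict(
                        variant=variant.name,
                        net_charge=variant.net_charge,
                        replicate=rep_id,
                        time_h=t,
                        n_cells=fr.n_cells,
                        n_with_condensates=fr.n_with_condensates,
                        fraction=fr.fraction,
                    )
                )
                if config.run_sweep and rep == 0 and t == final_time:
                    lo, hi, step = config.calling.sweep
                    grid = np.round(np.arange(lo, hi + step / 2, step), 6)
                    sw = callmod.threshold_sweep(
                        regions, sub, grid,
                        min_focus_px=config.calling.min_focus_px,
                        disk_radius_px=config.calling.disk_radius_px,
                    )
                    sw.insert(0, "variant", variant.name)
                    sw.insert(1, "net_charge", variant.net_charge)
                    sw.insert(2, "time_h", t)
                    sweep_frames.append(sw)
            per_replicate[rep_id] = series

        tc = aggregate(per_replicate, variant=variant.name, net_charge=variant.net_charge)
        cls = persistence_class(tc, cutoff=config.calling.cutoff)
        class_rows.append(
            dict(
                variant=variant.name,
                net_charge=variant.net_charge,
                final_fraction_mean=tc.mean[tc.times[-1]],
                final_fraction_sd=tc.sd[tc.times[-1]],
                condensate_forming=callmod.classify_strain(
                    tc.mean[tc.times[-1]], config.calling.cutoff
                ),
                persistence=cls,
            )
        )

    fractions = pd.DataFrame(fraction_rows)
    classification = pd.DataFrame(class_rows)
    _write_csv(fractions, outdir / "fractions.csv", chash)
    _write_csv(classification, outdir / "classification.csv", chash)
    outputs = ["fractions.csv", "classification.csv"]
    if sweep_frames:
        sweep = pd.concat(sweep_frames, ignore_index=True)
        _write_csv(sweep, outdir / "sweep.csv", chash)
        outputs.append("sweep.csv")

    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "n_variants": len(config.variants),
        "n_replicates": config.n_replicates,
        "outputs": outputs,
        "config": config.to_dict(),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
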
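"""Run orchestration: execute selected workflows over one input bundle.

One call to :func:`run` loads the bundle, builds the matched random
reference, executes each selected workflow on the real (and random) particle
set, writes the per-workflow result CSVs, histograms and overlays, and emits
a machine-readable run manifest recording inputs, seeds, parameters and the
package version — replaying a manifest's configuration reproduces every CSV
byte-identically. A workflow failure is logged and the remaining workflows
continue; the exit status is nonzero only if all fail.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .clustering import ClusterConfig, cluster_particles, summarize_clusters
from .data_model import ParticlePointSet, RoiMask, ScaleSpec
from .distances import landmark_nnd, nnd_distances, particle_nnd
from .errors import ConfigError, GoldioError
from .io_formats import (
    RESULT_SCHEMAS,
    InputBundle,
    read_mask_tiff,
    read_points_csv,
    result_filename,
    write_results_csv,
)
from .random_points import RandomGenConfig, generate_random
from .rippler import RipplerConfig, lcpi_curve
from .separation import SeparationConfig, cluster_separation, separation_rows
from .viz import (
    RANDOM_PALETTE,
    REAL_PALETTE,
    OverlayLayer,
    lcpi_plot,
    nnd_histogram,
    render_overlay,
)

log = logging.getLogger("goldio")

WORKFLOWS = ("nnd", "cluster", "separation", "rippler", "goldstar")


@dataclass
class RunConfig:
    bundle: InputBundle
    workflows: Sequence[str] = ("nnd",)
    scale: ScaleSpec = field(default_factory=ScaleSpec)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    separation: SeparationConfig = field(default_factory=SeparationConfig)
    rippler: RipplerConfig = field(default_factory=RipplerConfig)
    random_reference: bool = True
    random_n: Optional[int] = None  # default: match the real count
    random_seed: int = 0
    min_separation: float = 5.0
    histogram_bin_width: float = 10.0
    output_dir: Path = Path(".")
    real_palette: dict = field(default_factory=lambda: dict(REAL_PALETTE))
    random_palette: dict = field(default_factory=lambda: dict(RANDOM_PALETTE))

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        unknown = set(self.workflows) - set(WORKFLOWS)
        if unknown:
            raise ConfigError(f"unknown workflows: {sorted(unknown)}")
        if not self.workflows:
            raise ConfigError("at least one workflow must be selected")
        needs_landmarks = {"rippler", "goldstar"} & set(self.workflows)
        if needs_landmarks and self.bundle.landmark_csv_path is None:
            raise ConfigError(
                f"workflows {sorted(needs_landmarks)} require a landmark CSV"
            )


@dataclass
class RunResult:
    outputs: List[Path]
    errors: Dict[str, str]
    manifest_path: Path

    @property
    def ok(self) -> bool:
        return len(self.errors) == 0


def _segments(records) -> np.ndarray:
    return np.array(
        [[[r.point.x, r.point.y], [r.neighbor_point.x, r.neighbor_point.y]] for r in records]
    )


def run(config: RunConfig) -> RunResult:
    t0 = time.time()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    bundle = config.bundle
    stem = Path(bundle.gold_csv_path).stem

    log.info("loading inputs from %s", bundle.gold_csv_path)
    mask = read_mask_tiff(bundle.mask_path)
    gold = read_points_csv(bundle.gold_csv_path, label="gold")
    landmarks = None
    if bundle.landmark_csv_path is not None:
        landmarks = read_points_csv(bundle.landmark_csv_path, label="landmark")

    rand = None
    if config.random_reference:
        n = config.random_n if config.random_n is not None else len(gold)
        rand = generate_random(
            mask,
            RandomGenConfig(
                n=n, min_separation=config.min_separation, seed=config.random_seed
            ),
        )
        log.info("generated %d random reference particles (seed %d)", n, config.random_seed)

    outputs: List[Path] = []
    errors: Dict[str, str] = {}
    unit = config.scale.output_unit

    for wf in config.workflows:
        t_wf = time.time()
        try:
            outputs.extend(
                _run_workflow(wf, gold, rand, landmarks, mask, config, stem, unit)
            )
            log.info("workflow %s completed in %.2fs", wf, time.time() - t_wf)
        except GoldioError as exc:
            log.error("workflow %s failed: %s", wf, exc)
            errors[wf] = str(exc)

    manifest = {
        "version": __version__,
        "inputs": {
            "mask": str(bundle.mask_path),
            "gold": str(bundle.gold_csv_path),
            "image": str(bundle.image_path) if bundle.image_path else None,
            "landmark": str(bundle.landmark_csv_path)
            if bundle.landmark_csv_path
            else None,
        },
        "workflows": list(config.workflows),
        "scale": {"nm_per_pixel": config.scale.nm_per_pixel, "output_unit": unit},
        "cluster": asdict(config.cluster),
        "separation": asdict(config.separation),
        "rippler": asdict(config.rippler),
        "random": {
            "enabled": config.random_reference,
            "n": len(rand) if rand is not None else None,
            "seed": config.random_seed,
            "min_separation": config.min_separation,
        },
        "errors": errors,
        "elapsed_s": round(time.time() - t0, 3),
    }
    manifest_path = out / f"manifest_{stem}.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    outputs.append(manifest_path)
    return RunResult(outputs=outputs, errors=errors, manifest_path=manifest_path)


def _run_workflow(wf, gold, rand, landmarks, mask, config, stem, unit) -> List[Path]:
    out = config.output_dir
    scale = config.scale
    produced: List[Path] = []

    def emit(records, name, random=False, schema="nnd"):
        path = out / result_filename(name, stem, random=random)
        write_results_csv(records, path, scale, RESULT_SCHEMAS[schema])
        produced.append(path)

    if wf == "nnd":
        real = particle_nnd(gold)
        emit([r.as_row() for r in real], "nnd")
        rand_rec = None
        if rand is not None and len(rand) >= 2:
            rand_rec = particle_nnd(rand)
            emit([r.as_row() for r in rand_rec], "nnd", random=True)
        nnd_histogram(
            scale.length(nnd_distances(real)),
            scale.length(nnd_distances(rand_rec)) if rand_rec else None,
            out / f"nnd_{stem}_hist.png",
            bin_width=config.histogram_bin_width,
            unit=unit,
        )
        layers = [OverlayLayer(points=gold.xy, segments=_segments(real), palette=config.real_palette)]
        if rand_rec:
            layers.append(
                OverlayLayer(points=rand.xy, segments=_segments(rand_rec), palette=config.random_palette)
            )
        render_overlay(mask, layers, out / f"nnd_{stem}_overlay.png")
        produced += [out / f"nnd_{stem}_hist.png", out / f"nnd_{stem}_overlay.png"]

    elif wf == "cluster":
        for pts, is_rand in ((gold, False), (rand, True)):
            if pts is None or len(pts) == 0:
                continue
            summary = summarize_clusters(cluster_particles(pts, config.cluster))
            path = out / result_filename("cluster", stem, random=is_rand)
            write_results_csv(summary["clusters"], path, scale, RESULT_SCHEMAS["cluster_summary"])
            mpath = out / result_filename("cluster_members", stem, random=is_rand)
            write_results_csv(summary["membership"], mpath, scale, RESULT_SCHEMAS["cluster_membership"])
            produced += [path, mpath]

    elif wf == "separation":
        for pts, is_rand in ((gold, False), (rand, True)):
            if pts is None or len(pts) == 0:
                continue
            assignment = cluster_particles(pts, config.cluster)
            records = cluster_separation(assignment, config.separation)
            path = out / result_filename("separation", stem, random=is_rand)
            write_results_csv(separation_rows(records), path, scale, RESULT_SCHEMAS["separation"])
            produced.append(path)

    elif wf == "rippler":
        curves = {}
        for pts, is_rand in ((gold, False), (rand, True)):
            if pts is None or len(pts) == 0:
                continue
            curve = lcpi_curve(pts, landmarks, mask, config.rippler)
            label = "random" if is_rand else "real"
            curves[label] = curve
            path = out / result_filename("rippler", stem, random=is_rand)
            write_results_csv(curve.rows(), path, scale, RESULT_SCHEMAS["rippler"])
            produced.append(path)
        ppath = out / f"rippler_{stem}_curve.png"
        lcpi_plot(curves, ppath, unit="px")
        produced.append(ppath)

    elif wf == "goldstar":
        real = landmark_nnd(gold, landmarks)
        emit([r.as_row() for r in real], "goldstar")
        rand_rec = None
        if rand is not None and len(rand) >= 1:
            rand_rec = landmark_nnd(rand, landmarks)
            emit([r.as_row() for r in rand_rec], "goldstar", random=True)
        nnd_histogram(
            scale.length(nnd_distances(real)),
            scale.length(nnd_distances(rand_rec)) if rand_rec else None,
            out / f"goldstar_{stem}_hist.png",
            bin_width=config.histogram_bin_width,
            unit=unit,
            title="Particle to landmark distance",
        )
        produced.append(out / f"goldstar_{stem}_hist.png")

    return produced
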
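"""Benchmark experiments on phantoms.

Reproduces, at phantom scale, the qualitative behaviour of the three
segmenters under degraded guide images and jittered seeds (robustness
orderings, not absolute overlap values), and the detector's learning
curve against the number of training stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .detect import DetectorConfig, scan_detect, train_detector
from .evaluate import average_precision, segmentation_ao
from .phantom import PhantomSpec, degrade_guide, generate_phantom, jitter_seeds
from .preprocess import GuideParams, make_guide_worm
from .segment import ContourParams, active_contours, marker_watershed, truncated_voronoi

__all__ = [
    "BenchConfig",
    "benchmark_phantom_spec",
    "run_segmenter_grid",
    "run_detector_learning_curve",
]

# Canonical segmentation-benchmark conditions: a densely packed grid of
# cells tiling the volume (every boundary has a competitor behind it,
# as in tissue), with enough cell-size variation that a fixed-radius
# baseline is honestly imperfect.
BENCH_DEGRADE_KERNEL = (30, 30, 16)
BENCH_DEGRADE_ORIGIN = (1, 1, 4)


def benchmark_phantom_spec(seed: int) -> PhantomSpec:
    """The packed-grid phantom used for segmenter comparisons."""
    return PhantomSpec(
        seed=seed,
        arrangement="grid",
        shape=(32, 32, 24),
        n_cells=48,
        min_separation=2.4,
        mean_radius=1.6,
        radius_jitter=0.15,
    )


@dataclass
class BenchConfig:
    phantom: PhantomSpec = field(default_factory=lambda: benchmark_phantom_spec(0))
    jitter_radii: tuple = (0.0, 0.5, 1.0)
    guide_conditions: tuple = ("clean", "degraded")
    segmenters: tuple = ("ac", "voronoi", "watershed")
    degrade_kernel: tuple = BENCH_DEGRADE_KERNEL
    degrade_origin: tuple = BENCH_DEGRADE_ORIGIN
    guide_params: GuideParams = field(default_factory=GuideParams)
    contour_params: ContourParams = field(default_factory=ContourParams)
    voronoi_radius_um: float | None = None  # default: phantom mean radius
    seed: int = 0


def _segment(name, guide, seeds, cfg: BenchConfig):
    if name == "ac":
        return active_contours(guide, seeds, cfg.contour_params)
    if name == "voronoi":
        r = cfg.voronoi_radius_um or cfg.phantom.mean_radius * cfg.phantom.cell_radius_frac
        return truncated_voronoi(seeds, r, guide.data.shape, guide.spacing)
    if name == "watershed":
        return marker_watershed(guide, seeds)
    raise ValueError(f"unknown segmenter {name!r}")


def run_segmenter_grid(config: BenchConfig | None = None) -> pd.DataFrame:
    """AO per (segmenter x guide condition x jitter radius) on one
    phantom, with relative decreases against the clean/zero-jitter
    baseline of each segmenter."""
    cfg = config or BenchConfig()
    ph = generate_phantom(cfg.phantom)
    guides = {"clean": make_guide_worm(ph.membrane, cfg.guide_params)}
    if "degraded" in cfg.guide_conditions:
        guides["degraded"] = degrade_guide(
            guides["clean"], crop_origin=cfg.degrade_origin, kernel_shape=cfg.degrade_kernel
        )
    rows = []
    for seg in cfg.segmenters:
        for cond in cfg.guide_conditions:
            for rho in cfg.jitter_radii:
                seeds = jitter_seeds(ph.truth.centers_um, rho, seed=cfg.seed + int(rho * 100))
                labels = _segment(seg, guides[cond], seeds, cfg)
                res = segmentation_ao(labels, ph.truth.labels)
                rows.append(
                    {
                        "segmenter": seg,
                        "guide": cond,
                        "jitter_um": rho,
                        "ao": res.ao,
                        "precision": res.precision,
                        "recall": res.recall,
                    }
                )
    df = pd.DataFrame(rows)
    base = {
        seg: df.query("segmenter == @seg and guide == 'clean' and jitter_um == 0")["ao"].iloc[0]
        for seg in cfg.segmenters
    }
    df["ao_baseline"] = df["segmenter"].map(base)
    df["relative_decrease"] = (df["ao_baseline"] - df["ao"]) / df["ao_baseline"]
    return df


def run_detector_learning_curve(
    n_train: tuple = (1, 2, 4, 8),
    n_seeds: int = 3,
    phantom: PhantomSpec | None = None,
    detector: DetectorConfig | None = None,
    tau: float = -2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Detector AP on a held-out phantom vs number of training stacks.

    For each subset size, training stacks are resampled ``n_seeds``
    times from a shared pool; spread across resamples is reported.
    """
    base = phantom or PhantomSpec()
    det_cfg = detector or DetectorConfig()
    pool_size = max(n_train)
    pool = [generate_phantom(replace(base, seed=seed + 1000 + i)) for i in range(pool_size)]
    test = generate_phantom(replace(base, seed=seed + 5000))
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_train:
        for rep in range(n_seeds):
            take = rng.choice(pool_size, size=n, replace=False)
            stacks = [pool[i].dna for i in take]
            centers = [pool[i].truth.centers_um for i in take]
            model = train_detector(stacks, centers, det_cfg)
            dets = scan_detect(test.dna, model, tau=tau)
            ap = average_precision(dets, test.truth.centers_um)
            rows.append({"n_train": n, "rep": rep, "ap": ap})
    df = pd.DataFrame(rows)
    summary = df.groupby("n_train")["ap"].agg(["mean", "std"]).reset_index()
    return df.merge(summary, on="n_train", suffixes=("", "_agg"))
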
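"""Shared fixtures.

Heavy artifacts (phantoms, trained detector, segmenter grid results,
morphology patch sets) are session-scoped so unit, property and
acceptance tests share one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import voxcyto as vc
from voxcyto.detect import DetectorConfig, scan_detect, train_detector
from voxcyto.phantom import degrade_guide, jitter_seeds
from voxcyto.preprocess import make_guide_worm
from voxcyto.segment import ContourParams, active_contours, marker_watershed, truncated_voronoi
from voxcyto.evaluate import segmentation_ao


@pytest.fixture(scope="session")
def tube_phantom():
    """Default 30-cell tube phantom (noise + attenuation on)."""
    return vc.generate_phantom(vc.PhantomSpec(seed=5))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-, blur- and attenuation-free tube phantom for exact recovery."""
    return vc.generate_phantom(
        vc.PhantomSpec(seed=3, noise_sigma=0.0, z_attenuation=0.0, psf_sigma_um=0.0)
    )


@pytest.fixture(scope="session")
def grid_phantom():
    """Densely packed benchmark phantom (cells tile the volume)."""
    from voxcyto.bench import benchmark_phantom_spec

    return vc.generate_phantom(benchmark_phantom_spec(5))


@pytest.fixture(scope="session")
def grid_guide(grid_phantom):
    return make_guide_worm(grid_phantom.membrane)


@pytest.fixture(scope="session")
def single_cell_ac():
    """Active-contour segmentation of a clean single-cell phantom."""
    spec = vc.PhantomSpec(
        seed=2, n_cells=1, arrangement="scatter", shape=(32, 32, 32),
        noise_sigma=0.0, z_attenuation=0.0, clutter_amplitude=0.0,
    )
    ph = vc.generate_phantom(spec)
    labels = active_contours(make_guide_worm(ph.membrane), ph.truth.centers_um)
    return labels, ph.truth


@pytest.fixture(scope="session")
def grid_ac_clean(grid_phantom, grid_guide):
    """Active contours on the clean benchmark grid phantom."""
    return active_contours(grid_guide, grid_phantom.truth.centers_um, ContourParams())


@pytest.fixture(scope="session")
def segmenter_grid_results(grid_phantom, grid_guide, grid_ac_clean):
    """AO of each segmenter under clean/degraded guides and seed jitter."""
    from voxcyto.bench import BENCH_DEGRADE_KERNEL, BENCH_DEGRADE_ORIGIN

    ph = grid_phantom
    spec_radius = 1.6 * 1.3  # cell radius of the benchmark phantom
    degraded = degrade_guide(
        grid_guide, crop_origin=BENCH_DEGRADE_ORIGIN, kernel_shape=BENCH_DEGRADE_KERNEL
    )
    lab = ph.truth.labels
    params = ContourParams()
    segmenters = {
        "ac": lambda g, s: active_contours(g, s, params),
        "voronoi": lambda g, s: truncated_voronoi(s, spec_radius, lab.shape, (0.3, 0.3, 0.3)),
        "watershed": lambda g, s: marker_watershed(g, s),
    }
    out = {("ac", "clean", 0.0): segmentation_ao(grid_ac_clean, lab).ao}
    for name, fn in segmenters.items():
        for cond, guide in [("clean", grid_guide), ("degraded", degraded)]:
            for rho in (0.0, 1.0):
                if cond == "degraded" and rho > 0:
                    continue
                if (name, cond, rho) in out:
                    continue
                seeds = jitter_seeds(ph.truth.centers_um, rho, seed=22)
                out[(name, cond, rho)] = segmentation_ao(fn(guide, seeds), lab).ao
    return out


@pytest.fixture(scope="session")
def trained_detector():
    """Detector trained on one default phantom."""
    ph = vc.generate_phantom(vc.PhantomSpec(seed=21))
    model = train_detector([ph.dna], [ph.truth.centers_um], DetectorConfig())
    return model


@pytest.fixture(scope="session")
def detection_run(trained_detector):
    """Detections of the trained detector on a held-out phantom."""
    test = vc.generate_phantom(vc.PhantomSpec(seed=22))
    dets = scan_detect(test.dna, trained_detector, tau=-2.0)
    return dets, test


@pytest.fixture(scope="session")
def morphology_patches():
    """DNA patches + phase labels from finely sampled phantoms."""
    patches, labels = [], []
    for seed in range(31, 46):
        spec = vc.PhantomSpec(
            seed=seed, n_cells=40, shape=(192, 96, 32), spacing=(0.1, 0.1, 0.3),
            phase_mix=(0.25, 0.25, 0.25, 0.25),
        )
        ph = vc.generate_phantom(spec)
        for k in range(40):
            patches.append(vc.crop_cell_patch(ph.dna, ph.truth.labels, k + 1))
            labels.append(ph.truth.phases[k])
    return patches, labels


@pytest.fixture(scope="session")
def worm_quantification():
    """Full worm DNA/EdU quantification under a known axial gain."""
    from voxcyto.quantify import (
        cell_rows, geodesic_positions, measure_cells, normalize_dna_worm,
        quantify_edu, top_layeredness,
    )
    from voxcyto.stacks import VoxelStack

    spec = vc.PhantomSpec(seed=4, n_cells=200, shape=(480, 48, 32), z_attenuation=0.0)
    ph = vc.generate_phantom(spec)
    lab = ph.truth.labels
    xs = np.arange(lab.shape[0]) * 0.3
    gained = VoxelStack(ph.dna.data / (1.0 + 0.05 * xs)[:, None, None], ph.dna.spacing, "dna")
    m = measure_cells(lab, gained)
    m["theta"] = m["id"].map(top_layeredness(lab))
    m["geodesic_um"] = geodesic_positions(ph.truth.centers_um, distal_point_um=(0, 7.2, 4.8))
    distal = int(m.loc[m["x_um"].idxmin(), "id"])
    m["row"] = m["id"].map(cell_rows(lab, distal))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        records = normalize_dna_worm(m)
    edu = quantify_edu(ph.edu, lab, t1=0.05, t2=0.8)
    return ph, records, edu
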
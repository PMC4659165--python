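"""Synthetic 3-D phantoms of densely packed, roughly spherical nuclei.

The generator emulates the image properties of confocal stacks of
tightly packed germ-cell nuclei: a tube (or grid/scatter) of ~spherical
nuclei whose DNA stain concentrates in a shell near the nuclear
periphery with cell-cycle-phase-dependent puncta, a membrane channel
bright on inter-cell boundaries, optional EdU channel marking S-phase
cells, exponential attenuation along z, and Gaussian/Poisson noise.
Ground truth (centres, radii, masks, phases, DNA contents) is returned
alongside so every downstream stage can be scored without real data.

Phase-dependent DNA texture:

* G1 — shell plus 5–6 bright puncta (punctate chromatin);
* S  — smooth shell, no puncta;
* G2 — shell plus a variable, larger number of puncta;
* M  — condensed chromatin: a compact bright core, no shell.

Per-cell summed DNA intensity is proportional to the true DNA content
(2C in G1, 4C in G2/M, uniform between 2C and 4C in S) before
attenuation and noise are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stacks import VoxelStack

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Phantom",
    "generate_phantom",
    "jitter_seeds",
    "degrade_guide",
]

PHASES = ("G1", "S", "G2", "M")

# DNA content units (C-value scale): G1 = 2C, G2/M = 4C, S in between.
_CONTENT = {"G1": 2.0, "G2": 4.0, "M": 4.0}


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic stack.

    Lengths in μm. Defaults model a mitotic-zone-like tube of 30 nuclei
    of radius ~1.5 μm at 0.3 μm isotropic voxels.
    """

    arrangement: str = "tube"  # tube | grid | scatter
    n_cells: int = 30
    shape: tuple[int, int, int] = (96, 48, 32)
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    mean_radius: float = 1.5  # nuclear radius
    radius_jitter: float = 0.1  # fractional, uniform
    cell_radius_frac: float = 1.3  # cell radius / nuclear radius
    min_separation: float | None = None  # default 1.6 * mean_radius
    shell_fraction: float = 0.3  # DNA shell thickness / radius
    interior_level: float = 0.25  # DNA level inside the shell
    puncta_count: dict = field(
        default_factory=lambda: {"G1": (5, 6), "S": (0, 0), "G2": (8, 12), "M": (0, 0)}
    )
    # punctate phases carry a dimmer shell so chromocenters stand out
    shell_amplitude: dict = field(
        default_factory=lambda: {"G1": 0.5, "S": 1.0, "G2": 0.8}
    )
    # chromocenters (G1) are fine puncta; late-phase chromatin clumps
    # (G2) are larger, so texture differs in scale as well as count
    puncta_sigma: dict = field(
        default_factory=lambda: {"G1": 0.25, "G2": 0.45}
    )
    puncta_amplitude: float = 1.5
    membrane_thickness: float = 0.2
    envelope_amplitude: float = 0.25  # nuclear-envelope stain vs membrane
    envelope_radius_frac: float = 1.0  # relative to the nuclear radius
    clutter_amplitude: float = 0.4  # cytoplasmic membranous clutter
    clutter_scale_um: float = 0.4
    noise_sigma: float = 0.08
    psf_sigma_um: float = 0.15  # optical blur applied to all channels
    poisson_photons: float | None = None
    z_attenuation: float = 0.03  # per μm; intensity *= exp(-lambda * z)
    phase_mix: tuple[float, float, float, float] = (0.20, 0.45, 0.30, 0.05)
    edu_on_s: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.phase_mix, dtype=float)
        if np.any(mix < 0) or np.any(mix > 1) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("phase_mix fractions must lie in [0,1] and sum to 1")
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be > 0")
        if self.min_separation is None:
            self.min_separation = 1.6 * self.mean_radius
        # Mirrors the annotation convention that no two true centres are
        # closer than 1.5 μm (about one cell radius).
        self.min_separation = max(self.min_separation, 1.5)


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    centers_um: np.ndarray  # (n, 3)
    radii_um: np.ndarray  # (n,)
    labels: np.ndarray  # int volume, value k+1 = mask of cell k
    phases: list[str]
    dna_content: np.ndarray  # C-value units (2..4)
    edu_status: np.ndarray  # bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(len(self.phases)),
                "x_um": self.centers_um[:, 0],
                "y_um": self.centers_um[:, 1],
                "z_um": self.centers_um[:, 2],
                "radius_um": self.radii_um,
                "phase": self.phases,
                "dna_content": self.dna_content,
                "edu": self.edu_status.astype(int),
            }
        )


@dataclass
class Phantom:
    dna: VoxelStack
    membrane: VoxelStack
    edu: VoxelStack | None
    truth: PhantomTruth


def _place_centers(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample centres with a minimum pairwise separation."""
    bounds = np.asarray(spec.shape) * np.asarray(spec.spacing)
    margin = spec.mean_radius * 0.9
    centers: list[np.ndarray] = []
    max_tries = 2000 * spec.n_cells
    for _ in range(max_tries):
        if len(centers) == spec.n_cells:
            break
        if spec.arrangement == "tube":
            # Tube axis along x; cross-section disc in (y, z).
            cyz = np.array([bounds[1] / 2, bounds[2] / 2])
            r_tube = min(bounds[1], bounds[2]) / 2 - margin
            x = rng.uniform(margin, bounds[0] - margin)
            while True:
                yz = rng.uniform(-r_tube, r_tube, size=2)
                if np.hypot(*yz) <= r_tube:
                    break
            p = np.array([x, cyz[0] + yz[0], cyz[1] + yz[1]])
        elif spec.arrangement == "scatter":
            p = rng.uniform(margin, bounds - margin)
        elif spec.arrangement == "grid":
            # dense volume-filling packing: cells tile the whole box so
            # every boundary has a competing neighbour behind it
            gm = max(0.6 * spec.mean_radius, 2 * float(np.max(spec.spacing)))
            pitch = spec.min_separation
            counts = np.maximum(1, ((bounds - 2 * gm) // pitch).astype(int) + 1)
            if int(np.prod(counts)) < spec.n_cells:
                raise RuntimeError(
                    f"grid of {tuple(counts)} sites cannot hold {spec.n_cells} cells"
                )
            i = len(centers)
            ijk = np.array(
                [i % counts[0], (i // counts[0]) % counts[1], i // (counts[0] * counts[1])]
            )
            p = gm + ijk * pitch + rng.uniform(-0.1, 0.1, 3) * spec.mean_radius
        else:
            raise ValueError(f"unknown arrangement {spec.arrangement!r}")
        # grid sites are separated by construction; the jittered pitch may
        # dip slightly below min_separation, so only the hard annotation
        # floor applies there
        floor = 1.5 if spec.arrangement == "grid" else spec.min_separation
        if centers and np.min(np.linalg.norm(np.array(centers) - p, axis=1)) < floor:
            continue
        centers.append(p)
    if len(centers) < spec.n_cells:
        raise RuntimeError(
            f"could not place {spec.n_cells} cells with separation "
            f"{spec.min_separation:.2f} μm in the given volume"
        )
    return np.array(centers)


def _cell_bbox(center, radius, shape, spacing, pad=1.0):
    lo = np.maximum(0, np.floor((center - radius - pad) / spacing)).astype(int)
    hi = np.minimum(shape, np.ceil((center + radius + pad) / spacing) + 1).astype(int)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _dist_grid(bbox, center, spacing):
    axes = [
        (np.arange(s.start, s.stop) * sp - c)
        for s, sp, c in zip(bbox, spacing, center)
    ]
    return np.sqrt(
        axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    )


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate DNA/membrane(/EdU) channels plus ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    shape = tuple(spec.shape)

    centers = _place_centers(spec, rng)
    n = spec.n_cells
    radii = spec.mean_radius * rng.uniform(1 - spec.radius_jitter, 1 + spec.radius_jitter, n)
    phases = [PHASES[i] for i in rng.choice(4, size=n, p=np.asarray(spec.phase_mix))]
    content = np.array(
        [rng.uniform(2.0, 4.0) if ph == "S" else _CONTENT[ph] for ph in phases]
    )
    edu_status = np.array([ph == "S" and spec.edu_on_s for ph in phases])

    # --- true cell masks: ball of the cell radius (nucleus plus a rim
    # of cytoplasm); overlaps resolved by the additively weighted
    # nearest rule argmin(d - r), so larger cells push shared
    # boundaries beyond the midpoint the way packed cells do ---
    cell_radii = radii * spec.cell_radius_frac
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float32)
    for k in range(n):
        bbox = _cell_bbox(centers[k], cell_radii[k], shape, spacing, pad=0.0)
        d = _dist_grid(bbox, centers[k], spacing).astype(np.float32)
        take = (d <= cell_radii[k]) & (d - cell_radii[k] < best[bbox])
        labels[bbox][take] = k + 1
        best[bbox][take] = (d - cell_radii[k])[take]

    dna = np.zeros(shape, dtype=np.float64)
    edu = np.zeros(shape, dtype=np.float64) if spec.edu_on_s else None
    content_unit = 100.0  # summed intensity per C-value unit

    for k in range(n):
        r = radii[k]
        bbox = _cell_bbox(centers[k], r, shape, spacing, pad=0.0)
        d = _dist_grid(bbox, centers[k], spacing)
        own = labels[bbox] == k + 1
        if phases[k] == "M":
            pattern = np.where(d <= 0.65 * r, 1.3, 0.0)
        elif phases[k] == "S":
            # dispersed replicating chromatin: a uniformly filled
            # nucleus whose occupied radius grows with DNA content
            r_s = r * (content[k] / 4.0) ** (1 / 3)
            pattern = np.where(d <= r_s, 1.0, 0.0)
        else:
            # chromatin occupancy grows with content while peak stain
            # brightness stays constant: shell thickness scales with the
            # DNA content, so per-voxel percentiles are content-neutral
            shell_lo = (1 - spec.shell_fraction * content[k] / 3.0) * r
            amp = spec.shell_amplitude.get(phases[k], 1.0)
            pattern = np.where(d <= r, np.where(d >= shell_lo, amp, spec.interior_level), 0.0)
            lo, hi = spec.puncta_count.get(phases[k], (0, 0))
            sigma_p = spec.puncta_sigma.get(phases[k], 0.25)
            for _ in range(int(rng.integers(lo, hi + 1))):
                # uniform position inside the nuclear shell
                while True:
                    q = rng.uniform(-r, r, 3)
                    rq = np.linalg.norm(q)
                    if shell_lo * 0.9 <= rq <= r:
                        break
                pc = centers[k] + q
                dq = _dist_grid(bbox, pc, spacing)
                pattern = pattern + spec.puncta_amplitude * np.exp(
                    -(dq**2) / (2 * sigma_p**2)
                )
        pattern = pattern * own
        total = pattern.sum()
        if total > 0:
            dna[bbox] += pattern * (content[k] * content_unit / total)
        if edu is not None and edu_status[k]:
            edu[bbox] += np.where(d <= r, 1.0, 0.0) * own

    # --- membrane: bright shell on label boundaries (incl. outer rims) ---
    boundary = np.zeros(shape, dtype=bool)
    for axis in range(3):
        a = np.swapaxes(labels, 0, axis)
        diff = a[1:] != a[:-1]
        nz = (a[1:] != 0) | (a[:-1] != 0)
        edge = diff & nz
        b = np.swapaxes(boundary, 0, axis)
        b[1:] |= edge
        b[:-1] |= edge
    dist_to_boundary = ndimage.distance_transform_edt(~boundary, sampling=spacing)
    membrane = (dist_to_boundary <= spec.membrane_thickness / 2).astype(float)
    if spec.envelope_amplitude > 0:
        # faint nuclear-envelope sheets: membrane dyes also stain the
        # nuclear envelope, the sheet-like clutter that competes with
        # true cell boundaries when staining is poor
        for k in range(n):
            bbox = _cell_bbox(centers[k], radii[k], shape, spacing, pad=0.5)
            d = _dist_grid(bbox, centers[k], spacing)
            r_env = spec.envelope_radius_frac * radii[k]
            half = max(spec.membrane_thickness / 2, 0.55 * float(np.max(spacing)))
            shell = np.abs(d - r_env) <= half
            membrane[bbox] += spec.envelope_amplitude * shell * (labels[bbox] == k + 1)
    if spec.clutter_amplitude > 0:
        # fine-scale membranous clutter (organelles, ER) inside cells;
        # rectified band-passed noise so it has sheet-like local
        # structure rather than pixel noise
        field = ndimage.gaussian_filter(
            rng.normal(size=shape), sigma=spec.clutter_scale_um / spacing
        )
        field = np.clip(field, 0, None)
        peak = np.percentile(field, 99.5)
        if peak > 0:
            membrane += spec.clutter_amplitude * (field / peak) * (labels > 0)
    sigma_vox = (spec.membrane_thickness / 2) / spacing
    membrane = ndimage.gaussian_filter(membrane, sigma=sigma_vox)

    # --- attenuation and noise ---
    z_um = np.arange(shape[2]) * spacing[2]
    atten = np.exp(-spec.z_attenuation * z_um)[None, None, :]
    channels = {"dna": dna * atten, "membrane": membrane * atten}
    if edu is not None:
        channels["edu"] = edu * atten
    for name, ch in channels.items():
        if spec.psf_sigma_um > 0:
            ch = ndimage.gaussian_filter(ch, sigma=spec.psf_sigma_um / spacing)
        if spec.poisson_photons:
            ch = rng.poisson(np.clip(ch, 0, None) * spec.poisson_photons) / spec.poisson_photons
        if spec.noise_sigma > 0:
            # sigma relative to a typical foreground level, not the
            # extreme peak, so SNR is meaningful across channels
            fg = ch[ch > 0]
            scale = np.percentile(fg, 90) if fg.size else 1.0
            ch = ch + rng.normal(0.0, spec.noise_sigma * max(scale, 1e-12), ch.shape)
        channels[name] = np.clip(ch, 0.0, None)

    truth = PhantomTruth(centers, radii, labels, phases, content, edu_status)
    return Phantom(
        dna=VoxelStack(channels["dna"], spec.spacing, "dna"),
        membrane=VoxelStack(channels["membrane"], spec.spacing, "membrane"),
        edu=VoxelStack(channels["edu"], spec.spacing, "edu") if edu is not None else None,
        truth=truth,
    )


def jitter_seeds(centers_um: np.ndarray, rho: float, seed: int = 0) -> np.ndarray:
    """Displace each centre by an independent uniform draw from the ball
    of radius ``rho`` μm (rejection sampling from the bounding cube).

    The mean displacement magnitude converges to ``3*rho/4``.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    centers = np.asarray(centers_um, dtype=float)
    if rho == 0:
        return centers.copy()
    rng = np.random.default_rng(seed)
    out = centers.copy()
    for i in range(len(out)):
        while True:
            d = rng.uniform(-rho, rho, 3)
            if np.dot(d, d) <= rho * rho:
                break
        out[i] += d
    return out


def degrade_guide(
    guide: VoxelStack,
    crop_origin: tuple[int, int, int] = (0, 0, 0),
    kernel_shape: tuple[int, int, int] = (108, 108, 40),
) -> VoxelStack:
    """Artificially degrade a guide image to mimic suboptimal staining.

    A kernel is cropped from the guide, inverted, clamped so no value
    exceeds 0.85, rescaled to [0, 1], tiled to the guide shape (starting
    at voxel (0,0,0)), and multiplied into the guide elementwise. The
    default kernel is 108x108x40 voxels; pass a smaller ``kernel_shape``
    for small phantoms.
    """
    data = guide.data
    o = np.asarray(crop_origin, dtype=int)
    ks = np.asarray(kernel_shape, dtype=int)
    if np.any(o < 0) or np.any(o + ks > np.asarray(data.shape)):
        raise ValueError(
            f"crop {tuple(ks)} at origin {tuple(o)} does not fit guide of shape {data.shape}"
        )
    k = data[o[0] : o[0] + ks[0], o[1] : o[1] + ks[1], o[2] : o[2] + ks[2]].astype(float)
    k = k.max() - k  # invert
    k = np.minimum(k, 0.85)  # clamp: no value above 0.85
    lo, hi = k.min(), k.max()
    if hi - lo <= 0:
        raise ValueError("constant crop: min-max rescale to [0,1] is undefined")
    k = (k - lo) / (hi - lo)
    reps = [int(np.ceil(s / kk)) for s, kk in zip(data.shape, k.shape)]
    tiled = np.tile(k, reps)[: data.shape[0], : data.shape[1], : data.shape[2]]
    return VoxelStack(data * tiled, guide.spacing, guide.name + "_degraded")
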
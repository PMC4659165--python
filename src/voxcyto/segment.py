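"""Seeded 3-D segmentation: level-set active contours plus baselines.

The primary segmenter evolves one signed field φ per cell (mask =
{φ < 0}) under

    dφ/dt = -g ||∇φ|| (1 - c1 k) + c2 ∇g · ∇φ

where g is the inverted guide image (low at cell boundaries so the
motion speed vanishes there), k the mean curvature ∇·(∇φ/‖∇φ‖), and c2
the advection weight: the level sets are transported by the velocity
field -c2 ∇g, so c2 < 0 pushes contours back as they approach a
boundary from inside (conservative first phase) and c2 > 0 pulls them
onto the boundary from either side (refinement phase). The sign of the
motion term is chosen so masks grow from their seeds under the
inside-negative convention. Masks of different cells may never overlap:
voxels claimed by two cells are frozen for both (dφ/dt = 0 there).

Numerics: the PDE is integrated on the voxel-normalized grid (lengths
in units of the smallest voxel side, with per-axis scale factors for
anisotropic spacing), which is the scale on which the canonical
parameter values (c1 = 0.1, c2 = ±1, dt = 0.15) balance the growth and
advection terms. The speed map is the inverted guide with saturation:
g = 1 - min(guide / s, 1) for a saturation level s (default 0.15), so
every boundary voxel above s stops motion completely rather than only
the globally brightest one; the advection field keeps the raw inverted
guide so refinement can still pull the contour onto the boundary crest.

Baselines: truncated Voronoi (Voronoi cell ∩ fixed-radius ball; uses no
guide) and marker-controlled watershed (minima imposed at the seeds,
size-filtered).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed as _sk_watershed

from .stacks import VoxelStack

__all__ = [
    "ContourParams",
    "active_contours",
    "truncated_voronoi",
    "marker_watershed",
]


@dataclass
class ContourPhase:
    c1: float  # curvature weight
    c2: float  # advection sign/weight
    dt: float
    n_steps: int


@dataclass
class ContourParams:
    """Two-phase evolution schedule and numerical knobs.

    Defaults: phase 1 (conservative) c1 = 0.1, c2 = -1, 650 steps of
    0.15; phase 2 (refinement) c1 = 0.1, c2 = +1, 300 steps of 0.15.
    """

    phases: list[ContourPhase] = field(
        default_factory=lambda: [
            ContourPhase(0.1, -1.0, 0.15, 650),
            ContourPhase(0.1, 1.0, 0.15, 300),
        ]
    )
    band_halfwidth_voxels: float = 5.0
    margin_um: float = 3.0  # per-cell sub-window half-extent beyond the seed
    reinit_every: int = 50
    init_radius_voxels: float = 1.0
    collision_every: int = 1
    saturation: float = 0.5  # relative guide level treated as a full stop
    normalize_window_um: float | None = 6.0  # local max-normalization

    def __post_init__(self) -> None:
        for ph in self.phases:
            if ph.dt <= 0 or ph.n_steps < 0:
                raise ValueError("dt must be > 0 and n_steps >= 0")


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Signed distance (μm): negative inside ``mask``."""
    inside = ndimage.distance_transform_edt(mask, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return outside - inside


def _upwind_gradnorm(phi, spacing, expand_mask):
    """Godunov upwind |∇φ| for motion in the outward (expanding) or
    inward direction per voxel."""
    terms_plus = []
    terms_minus = []
    for ax, h in enumerate(spacing):
        dminus = (phi - np.roll(phi, 1, axis=ax)) / h
        dplus = (np.roll(phi, -1, axis=ax) - phi) / h
        # one-sided copies at volume faces
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = 0
        dminus[tuple(sl_lo)] = 0.0
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = -1
        dplus[tuple(sl_hi)] = 0.0
        terms_plus.append(np.maximum(dminus, 0) ** 2 + np.minimum(dplus, 0) ** 2)
        terms_minus.append(np.minimum(dminus, 0) ** 2 + np.maximum(dplus, 0) ** 2)
    gp = np.sqrt(sum(terms_plus))
    gm = np.sqrt(sum(terms_minus))
    return np.where(expand_mask, gp, gm)


def _mean_curvature(phi, spacing):
    gx, gy, gz = np.gradient(phi, *spacing)
    norm = np.sqrt(gx**2 + gy**2 + gz**2) + 1e-12
    kx = np.gradient(gx / norm, spacing[0], axis=0)
    ky = np.gradient(gy / norm, spacing[1], axis=1)
    kz = np.gradient(gz / norm, spacing[2], axis=2)
    k = kx + ky + kz
    hmin = min(spacing)
    return np.clip(k, -1 / hmin, 1 / hmin)


def _advect(phi, vel, spacing):
    """Upwind -v·∇φ for a velocity field v (tuple of components)."""
    out = np.zeros_like(phi)
    for ax, (v, h) in enumerate(zip(vel, spacing)):
        dminus = (phi - np.roll(phi, 1, axis=ax)) / h
        dplus = (np.roll(phi, -1, axis=ax) - phi) / h
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = 0
        dminus[tuple(sl_lo)] = 0.0
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = -1
        dplus[tuple(sl_hi)] = 0.0
        out -= np.maximum(v, 0) * dminus + np.minimum(v, 0) * dplus
    return out


class _CellField:
    """One cell's φ on a cropped sub-window of the guide.

    All lengths are in units of the smallest voxel side; ``h`` carries
    the per-axis scale factors for anisotropic spacing.
    """

    def __init__(self, seed_um, guide_shape, spacing_um, params: ContourParams):
        spacing_um = np.asarray(spacing_um, dtype=float)
        ell = spacing_um.min()
        seed_vox = np.rint(np.asarray(seed_um) / spacing_um).astype(int)
        if np.any(seed_vox < 0) or np.any(seed_vox >= np.asarray(guide_shape)):
            raise ValueError(f"seed {seed_um} outside the guide image")
        half = np.ceil(params.margin_um / spacing_um).astype(int)
        self.lo = np.maximum(0, seed_vox - half)
        self.hi = np.minimum(guide_shape, seed_vox + half + 1)
        self.sl = tuple(slice(int(a), int(b)) for a, b in zip(self.lo, self.hi))
        shape = tuple(self.hi - self.lo)
        axes = [
            (np.arange(a, b) * s - c) / ell
            for a, b, s, c in zip(self.lo, self.hi, spacing_um, seed_um)
        ]
        dist = np.sqrt(
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        self.phi = (dist - params.init_radius_voxels).astype(np.float64)
        self.frozen = np.zeros(shape, dtype=bool)
        self.spacing = tuple(spacing_um / ell)  # grid scale factors

    @property
    def mask(self) -> np.ndarray:
        return self.phi < 0


def active_contours(
    guide: VoxelStack,
    seeds_um: np.ndarray,
    params: ContourParams | None = None,
) -> np.ndarray:
    """Segment one cell per seed with two-phase level-set evolution.

    Returns an integer label volume (seed i -> label i+1) with pairwise
    disjoint masks, each containing its seed.
    """
    params = params or ContourParams()
    seeds_um = np.atleast_2d(np.asarray(seeds_um, dtype=float))
    gdata = guide.data.astype(float)
    if gdata.min() < -1e-9 or gdata.max() > 1 + 1e-9:
        warnings.warn("guide not in [0,1]; rescaling")
        gdata = (gdata - gdata.min()) / max(gdata.max() - gdata.min(), 1e-12)
    if params.normalize_window_um:
        # local max-normalization: boundary strength is judged relative
        # to the strongest boundary nearby, which makes the stopping
        # condition invariant to slowly varying staining efficiency
        size = [
            max(3, int(round(params.normalize_window_um / s)) | 1)
            for s in guide.spacing
        ]
        local_max = ndimage.maximum_filter(gdata, size=size)
        gdata = gdata / np.maximum(local_max, 1e-3)
    # The motion speed uses the saturated inverted guide (full stop at
    # any boundary above the saturation level); the advection field uses
    # the raw inverted guide so the refinement phase can still pull the
    # contour onto the boundary crest within the saturated band.
    g_speed = 1.0 - np.clip(gdata / params.saturation, 0.0, 1.0)
    g_adv = 1.0 - gdata
    spacing_um = np.asarray(guide.spacing, dtype=float)
    h = spacing_um / spacing_um.min()
    ggrad = np.gradient(g_adv, *h)

    cells = [_CellField(s, guide.data.shape, spacing_um, params) for s in seeds_um]
    # global ownership map: -1 unclaimed, else cell index
    claim = np.full(guide.data.shape, -1, dtype=np.int32)
    for i, c in enumerate(cells):
        m = c.mask
        claim[c.sl][m] = i

    subs = []
    for c in cells:
        subs.append(
            {
                "g": g_speed[c.sl],
                "vel": None,  # set per phase (depends on c2)
                "grad": tuple(gg[c.sl] for gg in ggrad),
            }
        )

    step_count = 0
    for phase in params.phases:
        for c, s in zip(cells, subs):
            s["vel"] = tuple(-phase.c2 * gg for gg in s["grad"])
        for _ in range(phase.n_steps):
            step_count += 1
            for i, (c, s) in enumerate(zip(cells, subs)):
                phi = c.phi
                band = np.abs(phi) < params.band_halfwidth_voxels
                active = band & ~c.frozen
                if not active.any():
                    continue
                k = _mean_curvature(phi, c.spacing)
                speed = s["g"] * (1 - phase.c1 * k)
                gradnorm = _upwind_gradnorm(phi, c.spacing, speed > 0)
                dphi = -speed * gradnorm + _advect(phi, s["vel"], c.spacing)
                c.phi = phi + phase.dt * np.where(active, dphi, 0.0)

            if step_count % params.collision_every == 0:
                _resolve_collisions(cells, claim)
            if params.reinit_every and step_count % params.reinit_every == 0:
                for c in cells:
                    c.phi = _signed_distance(c.mask, c.spacing)

    _resolve_collisions(cells, claim)
    labels = np.zeros(guide.data.shape, dtype=np.int32)
    for i, c in enumerate(cells):
        labels[c.sl][c.mask & (claim[c.sl] == i)] = i + 1
    return labels


def _resolve_collisions(cells, claim) -> None:
    """Update the ownership map; freeze collided voxels in both cells.

    A voxel already owned by cell j that becomes negative in cell i is
    reverted for i (masks stay disjoint) and frozen for both fields.
    """
    for i, c in enumerate(cells):
        local = claim[c.sl]
        mine = c.mask
        newly = mine & (local == -1)
        local[newly] = i
        stolen = mine & (local != i) & (local >= 0)
        if stolen.any():
            # revert the newcomer and freeze the voxel for this cell
            c.phi[stolen] = min(c.spacing) * 0.5
            c.frozen |= stolen
            # freeze the same voxels in the owning cells
            owners = np.unique(local[stolen])
            coords = np.argwhere(stolen) + c.lo
            for j in owners:
                cj = cells[j]
                pts = coords[(local[stolen] == j)]
                loc = pts - cj.lo
                ok = np.all((loc >= 0) & (loc < np.asarray(cj.phi.shape)), axis=1)
                loc = loc[ok]
                cj.frozen[loc[:, 0], loc[:, 1], loc[:, 2]] = True


def truncated_voronoi(
    seeds_um: np.ndarray, r_um: float, shape, spacing
) -> np.ndarray:
    """Voronoi cell ∩ ball of radius r around each seed (μm metric).

    Equidistant voxels go to the lower cell index. Independent of any
    guide image.
    """
    if r_um <= 0:
        raise ValueError("radius must be > 0")
    seeds_um = np.atleast_2d(np.asarray(seeds_um, dtype=float))
    if len(np.unique(seeds_um, axis=0)) != len(seeds_um):
        raise ValueError("duplicate seeds")
    spacing = np.asarray(spacing, dtype=float)
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for i, p in enumerate(seeds_um):
        d = np.sqrt(
            (axes[0][:, None, None] - p[0]) ** 2
            + (axes[1][None, :, None] - p[1]) ** 2
            + (axes[2][None, None, :] - p[2]) ** 2
        )
        take = d < best  # strict: ties stay with the lower index
        labels[take] = i + 1
        best[take] = d[take]
    labels[best > r_um] = 0
    return labels


def marker_watershed(
    guide: VoxelStack,
    seeds_um: np.ndarray,
    size_bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Marker-controlled watershed on the guide image.

    Minima are imposed exactly at the seed voxels (marker flooding, the
    classical morphological-reconstruction construction) and the guide
    is flooded. Segments with voxel counts outside ``size_bounds``
    (default 5%..500% of the median segment volume) are relabelled to
    background.
    """
    seeds_um = np.atleast_2d(np.asarray(seeds_um, dtype=float))
    if len(np.unique(seeds_um, axis=0)) != len(seeds_um):
        raise ValueError("duplicate seeds")
    spacing = np.asarray(guide.spacing)
    markers = np.zeros(guide.data.shape, dtype=np.int32)
    vox = np.rint(seeds_um / spacing).astype(int)
    vox = np.clip(vox, 0, np.asarray(guide.data.shape) - 1)
    for i, v in enumerate(vox):
        markers[v[0], v[1], v[2]] = i + 1
    labels = _sk_watershed(guide.data.astype(float), markers=markers)
    counts = np.bincount(labels.ravel(), minlength=len(seeds_um) + 1)[1:]
    nonzero = counts[counts > 0]
    if nonzero.size:
        med = float(np.median(nonzero))
        lo, hi = size_bounds if size_bounds is not None else (0.05 * med, 5.0 * med)
        for i, c in enumerate(counts):
            if c > 0 and not (lo <= c <= hi):
                labels[labels == i + 1] = 0
    return labels.astype(np.int32)
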
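"""Guide-image construction from raw membrane or DNA channels.

Two routes produce the guide image that seeds-based segmentation halts
on:

* the membrane route (worm gonad / olfactory epithelium style):
  local sliding-square normalization, Gaussian smoothing, Hessian
  sheet-enhancement, final smoothing;
* the DNA route (pre-implantation embryo style): an adaptive threshold
  whose spatial model ``m(x,y,z) = exp(c1 z) (c2 x + c3 y + c4)`` is
  fitted to local means around cell detections, followed by median
  filtering, inversion and blurring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .stacks import VoxelStack

__all__ = [
    "GuideParams",
    "sharpen_normalize",
    "sheetness",
    "make_guide_worm",
    "make_guide_embryo",
]


@dataclass
class GuideParams:
    """Lengths in μm.

    ``cell_diameter`` sets the sliding-square size of the local
    normalization; ``membrane_thickness`` sets the Gaussian blur sigma;
    the embryo route additionally uses ``threshold_scale`` (k, default
    1/3), ``mean_window`` (window for local means around detections,
    default half a cell diameter) and ``median_radius`` (voxels).
    """

    cell_diameter: float = 3.0
    membrane_thickness: float = 0.2
    threshold_scale: float = 1.0 / 3.0
    mean_window: float | None = None
    median_radius: int = 1

    def __post_init__(self) -> None:
        if self.cell_diameter <= 0 or self.membrane_thickness <= 0:
            raise ValueError("lengths must be > 0")
        if self.threshold_scale <= 0:
            raise ValueError("threshold scale k must be > 0")
        if self.mean_window is None:
            self.mean_window = self.cell_diameter / 2


def _box_mean_2d(plane: np.ndarray, window: int) -> np.ndarray:
    """Mean over the in-bounds part of a window x window square."""
    ones = np.ones_like(plane, dtype=float)
    s = ndimage.uniform_filter(plane.astype(float), size=window, mode="constant") * window**2
    c = ndimage.uniform_filter(ones, size=window, mode="constant") * window**2
    return s / np.maximum(np.rint(c), 1.0)


def sharpen_normalize(
    stack: VoxelStack, window_um: float | None = None, mean_floor_frac: float = 0.0
) -> VoxelStack:
    """Divide each voxel by the local 2-D (xy-plane) mean.

    The sliding square is parallel to the xy-plane with side equal to
    the average cell diameter; this evens fluorescence out across z and
    makes the result invariant to global (or per-plane) multiplicative
    gain. Local means below ``1e-6 * max`` are clamped;
    ``mean_floor_frac`` additionally floors the local mean at that
    fraction of the global mean, which stops structures bordering empty
    background (where the local mean is tiny) from being amplified far
    beyond structures inside dense tissue.
    """
    window_um = 3.0 if window_um is None else window_um
    window = max(1, int(round(window_um / min(stack.spacing[0], stack.spacing[1]))))
    if window > min(stack.shape[0], stack.shape[1]):
        raise ValueError("normalization window larger than the xy plane")
    data = stack.data.astype(float)
    eps = max(1e-6 * data.max(), mean_floor_frac * data.mean(), 1e-300)
    out = np.empty_like(data)
    for z in range(stack.shape[2]):
        m = _box_mean_2d(data[:, :, z], window)
        out[:, :, z] = data[:, :, z] / np.maximum(m, eps)
    return VoxelStack(out, stack.spacing, stack.name + "_sharp")


def _hessian_eigenvalues(data: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel ascending eigenvalues of the spacing-aware Hessian."""
    sx, sy, sz = spacing
    gx, gy, gz = np.gradient(data, sx, sy, sz)
    hxx, hxy, hxz = np.gradient(gx, sx, sy, sz)
    _, hyy, hyz = np.gradient(gy, sx, sy, sz)
    hzz = np.gradient(gz, sz, axis=2)
    H = np.empty(data.shape + (3, 3))
    H[..., 0, 0] = hxx
    H[..., 1, 1] = hyy
    H[..., 2, 2] = hzz
    H[..., 0, 1] = H[..., 1, 0] = hxy
    H[..., 0, 2] = H[..., 2, 0] = hxz
    H[..., 1, 2] = H[..., 2, 1] = hyz
    return np.linalg.eigvalsh(H)  # ascending: d1 <= d2 <= d3


def sheetness_from_eigenvalues(d1, d2, d3):
    """Sheet-enhancement response from ordered Hessian eigenvalues.

    ``I' = -d1 * exp(-(d2/(2 d1))^2) * exp(-(d3/(2 d1))^2)`` where d1 is
    the most negative eigenvalue (bright-sheet convention); zero where
    d1 >= 0.
    """
    d1 = np.asarray(d1, dtype=float)
    out = np.zeros_like(d1)
    neg = d1 < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(neg, np.asarray(d2) / (2 * d1), 0.0)
        r3 = np.where(neg, np.asarray(d3) / (2 * d1), 0.0)
    out[neg] = (-d1 * np.exp(-(r2**2)) * np.exp(-(r3**2)))[neg]
    return out


def sheetness(stack: VoxelStack, presmooth_sigma_um: float | None = None) -> VoxelStack:
    """Enhance bright sheet-like structures via Hessian principal curvatures.

    Optionally Gaussian-smooths the image first (sigma in μm, spacing
    aware); derivatives are central differences on the μm grid, so an
    anisotropic z-step is honoured.
    """
    data = stack.data.astype(float)
    if presmooth_sigma_um:
        data = ndimage.gaussian_filter(
            data, sigma=[presmooth_sigma_um / s for s in stack.spacing]
        )
    d = _hessian_eigenvalues(data, stack.spacing)
    out = sheetness_from_eigenvalues(d[..., 0], d[..., 1], d[..., 2])
    return VoxelStack(out, stack.spacing, stack.name + "_sheet")


def _rescale01(data: np.ndarray) -> np.ndarray:
    lo, hi = data.min(), data.max()
    if hi - lo <= 0:
        return np.zeros_like(data)
    return (data - lo) / (hi - lo)


def make_guide_worm(membrane: VoxelStack, params: GuideParams | None = None) -> VoxelStack:
    """Membrane-route guide: sharpen -> blur -> sheetness -> blur -> [0,1].

    The final rescale is robust: values are scaled by the 99th
    percentile of the sheet response and clipped to [0, 1], so boundary
    sheets saturate uniformly instead of being normalized against a few
    exceptionally bright voxels.
    """
    params = params or GuideParams()
    sigma = params.membrane_thickness
    x = sharpen_normalize(membrane, params.cell_diameter, mean_floor_frac=0.5)
    x = sheetness(x, presmooth_sigma_um=sigma)
    data = ndimage.gaussian_filter(x.data, sigma=[sigma / s for s in membrane.spacing])
    scale = np.percentile(data, 99.0)
    if scale <= 0:
        return VoxelStack(np.zeros_like(data), membrane.spacing, "guide")
    return VoxelStack(np.clip(data / scale, 0.0, 1.0), membrane.spacing, "guide")


def _embryo_model(c, x, y, z):
    return np.exp(c[0] * z) * (c[1] * x + c[2] * y + c[3])


def fit_embryo_gain(coords_um: np.ndarray, means: np.ndarray):
    """Fit ``m = exp(c1 z)(c2 x + c3 y + c4)`` by nonlinear least squares.

    Seeded from a log-linearized estimate of the z trend (the model is
    multiplicative in z but additive in x, y, so a pure log-linear fit
    is invalid and is only used for the seed). Falls back to the
    constant model ``(0, 0, 0, mean)`` when the fit is degenerate.
    """
    x, y, z = coords_um.T
    m = np.asarray(means, dtype=float)
    if len(m) < 4:
        raise ValueError("need at least 4 detections to fit 4 coefficients")
    pos = m > 0
    if pos.sum() >= 2 and np.ptp(z[pos]) > 0:
        c1_0 = np.polyfit(z[pos], np.log(m[pos]), 1)[0]
    else:
        c1_0 = 0.0
    c0 = np.array([c1_0, 0.0, 0.0, max(m.mean(), 1e-12)])
    try:
        res = optimize.least_squares(
            lambda c: _embryo_model(c, x, y, z) - m, c0, method="lm", max_nfev=10000
        )
        c = res.x
        pred = _embryo_model(c, x, y, z)
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            raise RuntimeError("degenerate fit")
    except Exception:
        warnings.warn("degenerate embryo gain fit; falling back to constant model")
        c = np.array([0.0, 0.0, 0.0, m.mean()])
    return c


def make_guide_embryo(
    dna: VoxelStack, detections_um: np.ndarray, params: GuideParams | None = None
) -> VoxelStack:
    """DNA-route guide via the adaptive threshold t = k exp(c1 z)(c2 x + c3 y + c4).

    Local mean DNA values in a small window around each detection are
    fitted to the spatial model; the image is thresholded at k times the
    model, median filtered, inverted, and blurred.
    """
    params = params or GuideParams()
    detections_um = np.atleast_2d(np.asarray(detections_um, dtype=float))
    data = dna.data.astype(float)
    spacing = np.asarray(dna.spacing)
    half = np.maximum(1, np.rint((params.mean_window / 2) / spacing)).astype(int)

    means = []
    for p in detections_um:
        c = np.rint(p / spacing).astype(int)
        lo = np.maximum(0, c - half)
        hi = np.minimum(dna.shape, c + half + 1)
        if np.any(hi <= lo):
            raise ValueError(f"window around detection {p} falls outside the image")
        means.append(data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].mean())
    coef = fit_embryo_gain(detections_um, np.asarray(means))

    xs = np.arange(dna.shape[0]) * spacing[0]
    ys = np.arange(dna.shape[1]) * spacing[1]
    zs = np.arange(dna.shape[2]) * spacing[2]
    model = _embryo_model(
        coef, xs[:, None, None], ys[None, :, None], zs[None, None, :]
    )
    binary = (data > params.threshold_scale * model).astype(float)
    size = 2 * params.median_radius + 1
    binary = ndimage.median_filter(binary, size=size)
    inverted = 1.0 - binary
    sigma = params.membrane_thickness
    out = ndimage.gaussian_filter(inverted, sigma=[sigma / s for s in spacing])
    return VoxelStack(_rescale01(out) if out.max() > out.min() else out, dna.spacing, "guide")
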
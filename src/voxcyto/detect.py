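"""Sliding-window SVM cell-centre detector with HOG features.

A window centred on a candidate voxel yields a feature vector v built
from two orthogonal 2-D slices through the centre:

* xy slice: mean window brightness plus a histogram-of-oriented-
  gradients block (a grid of non-overlapping sub-windows; per-pixel
  gradients vote their magnitude into one of 18 orientation bins; each
  sub-window histogram is L2-normalized and its normalization factor is
  appended as an extra feature);
* xz slice: the same HOG block.

A voxel is declared a cell centre when ``w^T v > tau`` for a weight
vector w learned by a linear SVM. Training mines hard negatives
iteratively (train, scan, add highest-scoring false positives, retrain)
-- which converges to the same optimum as training on every negative at
once -- and latently re-estimates each labelled centre as the maximum of
the detector response within a small radius. Scanning runs densely at
several image scales and is followed by suppression of any detection
within one cell radius of a higher-scoring detection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.svm import LinearSVC

from .stacks import DetectionSet, VoxelStack

__all__ = [
    "DetectorConfig",
    "DetectorModel",
    "WindowFeaturizer",
    "extract_window_features",
    "train_detector",
    "train_svm_with_mining",
    "fit_linear_svm",
    "scan_detect",
    "nonmax_suppress",
    "save_model",
    "load_model",
]


@dataclass
class DetectorConfig:
    """Detector geometry and training knobs (lengths in μm)."""

    window_um: float = 6.0  # 2x the mean cell diameter
    grid: int = 4  # grid x grid non-overlapping sub-windows
    n_bins: int = 18
    cell_radius_um: float = 1.5
    scale_range: tuple[float, float] = (0.7, 1.5)
    n_scales: int = 5
    svm_c: float = 1.0
    svm_tol: float = 1e-7
    mining_init: int = 400
    mining_add: int = 800
    mining_rounds: int = 8
    margin_tol: float = 1e-3
    latent_passes: int = 2
    latent_radius_um: float = 0.75  # half a cell radius
    symmetrize: bool = True
    seed: int = 0

    @property
    def scales(self) -> np.ndarray:
        lo, hi = self.scale_range
        return np.geomspace(lo, hi, self.n_scales)

    @property
    def feature_length(self) -> int:
        return 1 + 2 * self.grid**2 * (self.n_bins + 1)


@dataclass
class DetectorModel:
    w: np.ndarray
    config: DetectorConfig
    log: dict = field(default_factory=dict)


_EPS = 1e-12


def _window_voxels(window_um: float, spacing: float, grid: int) -> int:
    """Window side in voxels, rounded up to a multiple of the grid."""
    return grid * max(1, int(np.ceil(window_um / (grid * spacing))))


def _integral(data: np.ndarray, ax0: int, ax1: int) -> np.ndarray:
    """Zero-padded 2-D integral image along two axes of a volume."""
    pad = [(0, 0)] * data.ndim
    pad[ax0] = (1, 0)
    pad[ax1] = (1, 0)
    out = np.cumsum(np.cumsum(data, axis=ax0), axis=ax1)
    return np.pad(out, pad)


class WindowFeaturizer:
    """Feature extraction and dense w-scoring for one stack (one scale).

    Gradients are central differences over the full volume (pixel
    units), so window features near borders see the same gradients as
    the dense scan; windows extending past the volume are zero-padded.
    """

    def __init__(self, data: np.ndarray, spacing, config: DetectorConfig):
        self.data = np.asarray(data, dtype=float)
        self.spacing = tuple(spacing)
        self.cfg = config
        g = config.grid
        self.wx = _window_voxels(config.window_um, spacing[0], g)
        self.wy = _window_voxels(config.window_um, spacing[1], g)
        self.wz = _window_voxels(config.window_um, spacing[2], g)
        self.sub = (self.wx // g, self.wy // g, self.wz // g)
        gx = np.gradient(self.data, axis=0)
        gy = np.gradient(self.data, axis=1)
        gz = np.gradient(self.data, axis=2)
        nb = config.n_bins
        self.mag_xy = np.hypot(gx, gy)
        self.bin_xy = (
            np.floor((np.arctan2(gy, gx) + np.pi) / (2 * np.pi) * nb).astype(int) % nb
        )
        self.mag_xz = np.hypot(gx, gz)
        self.bin_xz = (
            np.floor((np.arctan2(gz, gx) + np.pi) / (2 * np.pi) * nb).astype(int) % nb
        )

    # ---------------- per-window path ----------------

    def _block_hist(self, mag, bins, x0, x1, y0, y1, plane_axis_slices) -> np.ndarray:
        sl = plane_axis_slices(slice(max(x0, 0), max(x1, 0)), slice(max(y0, 0), max(y1, 0)))
        m = mag[sl].ravel()
        b = bins[sl].ravel()
        return np.bincount(b, weights=m, minlength=self.cfg.n_bins)

    def _hog_block(self, mag, bins, cx, c1, w0, w1, plane_axis_slices) -> list[np.ndarray]:
        g = self.cfg.grid
        s0, s1 = w0 // g, w1 // g
        o0, o1 = cx - w0 // 2, c1 - w1 // 2
        feats = []
        for i in range(g):
            for j in range(g):
                h = self._block_hist(
                    mag, bins, o0 + i * s0, o0 + i * s0 + s0, o1 + j * s1, o1 + j * s1 + s1,
                    plane_axis_slices,
                )
                norm = float(np.sqrt(np.dot(h, h)))
                feats.append(np.concatenate([h / (norm + _EPS), [norm]]))
        return feats

    def feature(self, center_voxel) -> np.ndarray:
        """Feature vector at a voxel centre (zero-padded at borders)."""
        cx, cy, cz = (int(v) for v in center_voxel)
        X, Y, Z = self.data.shape
        czc = min(max(cz, 0), Z - 1)
        cyc = min(max(cy, 0), Y - 1)
        x0, y0 = cx - self.wx // 2, cy - self.wy // 2
        reg = self.data[
            max(x0, 0) : max(x0 + self.wx, 0), max(y0, 0) : max(y0 + self.wy, 0), czc
        ]
        brightness = reg.sum() / (self.wx * self.wy)
        xy = self._hog_block(
            self.mag_xy, self.bin_xy, cx, cy, self.wx, self.wy,
            lambda a, b: (a, b, czc),
        )
        xz = self._hog_block(
            self.mag_xz, self.bin_xz, cx, cz, self.wx, self.wz,
            lambda a, b: (a, cyc, b),
        )
        return np.concatenate([[brightness]] + xy + xz)

    def features(self, centers_voxel) -> np.ndarray:
        return np.array([self.feature(c) for c in centers_voxel])

    # ---------------- dense path ----------------

    def _anchored_sums(self, integral, off0, off1, b0, b1, ax0, ax1):
        """Block sums of size (b0, b1) anchored at (index+off) along
        (ax0, ax1), clipped to the volume (zero padding semantics)."""
        n0 = integral.shape[ax0] - 1
        n1 = integral.shape[ax1] - 1
        lo0 = np.clip(np.arange(n0) + off0, 0, n0)
        hi0 = np.clip(np.arange(n0) + off0 + b0, 0, n0)
        lo1 = np.clip(np.arange(n1) + off1, 0, n1)
        hi1 = np.clip(np.arange(n1) + off1 + b1, 0, n1)

        def take(i0, i1):
            return np.take(np.take(integral, i0, axis=ax0), i1, axis=ax1)

        return take(hi0, hi1) - take(hi0, lo1) - take(lo0, hi1) + take(lo0, lo1)

    def _dense_block(self, w_chunk, mag, bins, w0, w1, ax0, ax1, score):
        g, nb = self.cfg.grid, self.cfg.n_bins
        s0, s1 = w0 // g, w1 // g
        ints = [
            _integral(mag * (bins == b), ax0, ax1) for b in range(nb)
        ]
        idx = 0
        for i in range(g):
            for j in range(g):
                o0 = -(w0 // 2) + i * s0
                o1 = -(w1 // 2) + j * s1
                H = np.stack(
                    [self._anchored_sums(I, o0, o1, s0, s1, ax0, ax1) for I in ints]
                )
                # empty (out-of-volume) subwindows leave integral-image
                # cancellation residue that the norm floor would amplify
                H[np.abs(H) < 1e-10] = 0.0
                norm = np.sqrt(np.einsum("b...,b...->...", H, H))
                wsub = w_chunk[idx : idx + nb + 1]
                score += np.einsum("b,b...->...", wsub[:nb], H) / (norm + _EPS)
                score += wsub[nb] * norm
                idx += nb + 1
        return score

    def score_volume(self, w: np.ndarray) -> np.ndarray:
        """``w^T v`` at every voxel, identical to the per-window path."""
        g, nb = self.cfg.grid, self.cfg.n_bins
        blk = g * g * (nb + 1)
        Ixy = _integral(self.data, 0, 1)
        bright = (
            self._anchored_sums(Ixy, -(self.wx // 2), -(self.wy // 2), self.wx, self.wy, 0, 1)
            / (self.wx * self.wy)
        )
        score = w[0] * bright
        score = self._dense_block(w[1 : 1 + blk], self.mag_xy, self.bin_xy, self.wx, self.wy, 0, 1, score)
        score = self._dense_block(w[1 + blk :], self.mag_xz, self.bin_xz, self.wx, self.wz, 0, 2, score)
        return score


def extract_window_features(
    stack: VoxelStack, center_um, config: DetectorConfig | None = None, scale: float = 1.0
) -> np.ndarray:
    """Feature vector for one window (optionally on a rescaled stack)."""
    config = config or DetectorConfig()
    data = stack.data
    if scale != 1.0:
        data = ndimage.zoom(stack.data.astype(float), scale, order=1)
    fz = WindowFeaturizer(data, stack.spacing, config)
    voxel = np.rint(np.asarray(center_um) * scale / np.asarray(stack.spacing)).astype(int)
    return fz.feature(voxel)


def fit_linear_svm(X: np.ndarray, y: np.ndarray, config: DetectorConfig) -> np.ndarray:
    """Hinge-loss linear SVM without intercept; returns w."""
    clf = LinearSVC(
        loss="hinge",
        C=config.svm_c,
        fit_intercept=False,
        tol=config.svm_tol,
        max_iter=1_000_000,
    )
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        clf.fit(X, y)
    return clf.coef_.ravel().copy()


def train_svm_with_mining(
    X_pos: np.ndarray, X_neg_all: np.ndarray, config: DetectorConfig | None = None
) -> tuple[np.ndarray, dict]:
    """Iterative hard-negative mining on an explicit candidate matrix.

    Trains on a subset of negatives, adds negatives violating the hinge
    margin (score > -1), and retrains until no new violators remain or
    the round cap is hit. At convergence the optimum matches training on
    all negatives at once (omitted negatives have zero hinge loss).
    """
    config = config or DetectorConfig()
    rng = np.random.default_rng(config.seed)
    n_neg = len(X_neg_all)
    chosen = np.zeros(n_neg, dtype=bool)
    init = rng.choice(n_neg, size=min(config.mining_init, n_neg), replace=False)
    chosen[init] = True
    y = None
    w = None
    rounds = 0
    for rounds in range(1, config.mining_rounds + 1):
        X = np.vstack([X_pos, X_neg_all[chosen]])
        y = np.concatenate([np.ones(len(X_pos)), -np.ones(int(chosen.sum()))])
        w = fit_linear_svm(X, y, config)
        scores = X_neg_all @ w
        violators = (scores > -1 + config.margin_tol) & ~chosen
        if not violators.any():
            break
        idx = np.flatnonzero(violators)
        idx = idx[np.argsort(-scores[idx])][: config.mining_add]
        chosen[idx] = True
    else:
        warnings.warn("hard-negative mining hit the round cap before converging")
    return w, {"rounds": rounds, "n_negatives": int(chosen.sum())}


def _eligible_negative_voxels(shape, spacing, centers_um, radius_um) -> np.ndarray:
    """Boolean volume of voxels farther than one cell radius from every
    positive label."""
    seedvol = np.zeros(shape, dtype=bool)
    idx = np.rint(np.asarray(centers_um) / np.asarray(spacing)).astype(int)
    idx = np.clip(idx, 0, np.asarray(shape) - 1)
    seedvol[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~seedvol, sampling=spacing)
    return dist > radius_um


def _positive_features(stacks, centers_lists, config) -> np.ndarray:
    """Positive windows, symmetrized by axis flips when configured."""
    feats = []
    for stack, centers_um in zip(stacks, centers_lists):
        spacing = np.asarray(stack.spacing)
        voxels = np.rint(np.asarray(centers_um) / spacing).astype(int)
        variants = [(stack.data, voxels)]
        if config.symmetrize:
            shape = np.asarray(stack.data.shape)
            for axis in range(3):
                flipped = np.flip(stack.data, axis=axis)
                v = voxels.copy()
                v[:, axis] = shape[axis] - 1 - v[:, axis]
                variants.append((flipped, v))
        for data, v in variants:
            fz = WindowFeaturizer(data, stack.spacing, config)
            feats.append(fz.features(v))
    return np.vstack(feats)


def train_detector(
    stacks: list[VoxelStack],
    positive_centers_um: list[np.ndarray],
    config: DetectorConfig | None = None,
) -> DetectorModel:
    """Train the detector on stacks with hand-labelled centres.

    Runs symmetrized positive extraction, hard-negative mining against
    densely scanned negatives, and ``latent_passes`` rounds of centre
    re-estimation at the detector-response maximum within
    ``latent_radius_um`` of each label.
    """
    config = config or DetectorConfig()
    if sum(len(c) for c in positive_centers_um) < 1:
        raise ValueError("need at least one positive centre")
    rng = np.random.default_rng(config.seed)
    centers = [np.atleast_2d(np.asarray(c, dtype=float)) for c in positive_centers_um]
    featurizers = [WindowFeaturizer(s.data, s.spacing, config) for s in stacks]
    eligible = [
        _eligible_negative_voxels(s.data.shape, s.spacing, c, config.cell_radius_um)
        for s, c in zip(stacks, centers)
    ]
    if not any(e.any() for e in eligible):
        raise ValueError("no negative locations available")

    log: dict = {"mining": [], "latent": []}

    def mine(w0_positives: np.ndarray) -> np.ndarray:
        neg_feats: list[np.ndarray] = []
        neg_keys: set = set()
        # initial random negatives
        for si, (fz, elig) in enumerate(zip(featurizers, eligible)):
            coords = np.argwhere(elig)
            take = rng.choice(
                len(coords), size=min(config.mining_init, len(coords)), replace=False
            )
            for c in coords[take]:
                neg_keys.add((si, *map(int, c)))
            neg_feats.append(fz.features(coords[take]))
        X_neg = np.vstack(neg_feats)
        w = None
        for rnd in range(1, config.mining_rounds + 1):
            X = np.vstack([w0_positives, X_neg])
            y = np.concatenate([np.ones(len(w0_positives)), -np.ones(len(X_neg))])
            w = fit_linear_svm(X, y, config)
            new = []
            for si, (fz, elig) in enumerate(zip(featurizers, eligible)):
                scores = fz.score_volume(w)
                viol = elig & (scores > -1 + config.margin_tol)
                coords = np.argwhere(viol)
                coords = [
                    c for c in coords if (si, *map(int, c)) not in neg_keys
                ]
                if not coords:
                    continue
                coords = np.array(coords)
                svals = scores[coords[:, 0], coords[:, 1], coords[:, 2]]
                order = np.argsort(-svals)[: config.mining_add]
                for c in coords[order]:
                    neg_keys.add((si, *map(int, c)))
                new.append(fz.features(coords[order]))
            log["mining"].append({"round": rnd, "n_negatives": len(X_neg)})
            if not new:
                break
            X_neg = np.vstack([X_neg] + new)
        else:
            warnings.warn("hard-negative mining hit the round cap before converging")
        return w

    X_pos = _positive_features(stacks, centers, config)
    w = mine(X_pos)

    for _ in range(config.latent_passes):
        moved = 0.0
        for si, (stack, fz) in enumerate(zip(stacks, featurizers)):
            spacing = np.asarray(stack.spacing)
            scores = fz.score_volume(w)
            for k, c_um in enumerate(centers[si]):
                c_vox = np.rint(c_um / spacing).astype(int)
                r_vox = np.maximum(1, np.rint(config.latent_radius_um / spacing)).astype(int)
                lo = np.maximum(0, c_vox - r_vox)
                hi = np.minimum(stack.data.shape, c_vox + r_vox + 1)
                sub = scores[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
                best = np.unravel_index(np.argmax(sub), sub.shape)
                new_um = (lo + np.asarray(best)) * spacing
                moved += float(np.linalg.norm(new_um - c_um))
                centers[si][k] = new_um
        log["latent"].append({"total_shift_um": moved})
        X_pos = _positive_features(stacks, centers, config)
        w = mine(X_pos)

    log["n_positives"] = int(sum(len(c) for c in centers))
    return DetectorModel(w=w, config=config, log=log)


def scan_detect(
    stack: VoxelStack,
    model: DetectorModel,
    tau: float = 0.0,
    scales: np.ndarray | None = None,
    suppress: bool = True,
) -> DetectionSet:
    """Run the detector densely at every scale and return detections.

    Responses above ``tau`` that are local maxima of the score volume
    are kept; coordinates are mapped back to the original μm frame; a
    final pass suppresses detections within one cell radius of a
    higher-scoring detection.
    """
    cfg = model.config
    scales = cfg.scales if scales is None else np.asarray(scales, dtype=float)
    spacing = np.asarray(stack.spacing)
    coords, scores, scls = [], [], []
    for f in scales:
        data = stack.data.astype(float)
        if f != 1.0:
            data = ndimage.zoom(data, f, order=1)
        fz = WindowFeaturizer(data, stack.spacing, cfg)
        s = fz.score_volume(model.w)
        local_max = s >= ndimage.maximum_filter(s, size=3)
        keep = np.argwhere(local_max & (s > tau))
        if len(keep):
            coords.append(keep / f * spacing)
            scores.append(s[keep[:, 0], keep[:, 1], keep[:, 2]])
            scls.append(np.full(len(keep), f))
    if not coords:
        return DetectionSet(np.empty((0, 3)), np.empty(0), np.empty(0))
    dets = DetectionSet(np.vstack(coords), np.concatenate(scores), np.concatenate(scls))
    if suppress:
        dets = nonmax_suppress(dets, cfg.cell_radius_um)
    return dets


def nonmax_suppress(dets: DetectionSet, radius_um: float) -> DetectionSet:
    """Greedy suppression: walking detections by descending score (ties
    by insertion order), drop any within ``radius_um`` of a kept
    higher-scoring detection."""
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    if len(dets) == 0:
        return dets
    ordered = dets.order_by_score()
    from scipy.spatial import cKDTree

    tree = cKDTree(ordered.coords_um)
    alive = np.ones(len(ordered), dtype=bool)
    for i in range(len(ordered)):
        if not alive[i]:
            continue
        for j in tree.query_ball_point(ordered.coords_um[i], radius_um):
            if j > i:
                alive[j] = False
            elif j < i and alive[j]:
                # a kept higher-scoring detection is within the radius
                alive[i] = False
                break
    keep = np.flatnonzero(alive)
    return DetectionSet(
        ordered.coords_um[keep],
        ordered.scores[keep],
        None if ordered.scales is None else ordered.scales[keep],
        [ordered.labels[k] for k in keep],
    )


def save_model(model: DetectorModel, path) -> None:
    payload = {"w": model.w.tolist(), "config": asdict(model.config), "log": model.log}
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> DetectorModel:
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    cfg["scale_range"] = tuple(cfg["scale_range"])
    return DetectorModel(
        w=np.asarray(payload["w"], dtype=float),
        config=DetectorConfig(**cfg),
        log=payload.get("log", {}),
    )
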
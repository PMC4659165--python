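"""Cell-cycle phase classification from nuclear DNA morphology.

Each cell contributes a 2-D DNA-intensity patch (at most 34x34 pixels,
cut at the mid-z slice of its mask and masked to the cell). Features:

1. number of connected components of the Otsu-thresholded foreground
   (the number of DNA spots);
2. number of foreground pixels (spatial extent);
3. center-surround Haar-like responses — mean intensity of an inner
   square minus the mean of the surrounding ring of an outer square.

Under the frozen enumeration convention (outer square side 3..8 pixels,
inner side two pixels smaller — a one-pixel surround ring — at every
position) a 34x34 frame admits exactly 5239 Haar features.

One linear SVM per phase (one-vs-rest) is trained with per-phase
hyperparameters (box constraint 1e-5/1e-3/1e-2/1e-3 and tolerance
1e-7/1e-8/1e-8/1e-8 for G1/S/G2/M, at most 150000 iterations), with
statistics aggregated over repeated random 50/50 splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as _cc_label
from sklearn.svm import SVC

from .stacks import VoxelStack

__all__ = [
    "HaarFeature",
    "crop_cell_patch",
    "otsu_threshold",
    "otsu_features",
    "enumerate_haar",
    "haar_response",
    "haar_responses",
    "patch_feature_vector",
    "train_phase_classifiers",
]

PATCH_SIZE = 34
MAX_OUTER = 8

# Per-phase SVM hyperparameters.
SVM_BOX = {"G1": 1e-5, "S": 1e-3, "G2": 1e-2, "M": 1e-3}
SVM_TOL = {"G1": 1e-7, "S": 1e-8, "G2": 1e-8, "M": 1e-8}
SVM_MAX_ITER = 150_000


@dataclass(frozen=True)
class HaarFeature:
    """Outer square at (alpha, beta) with side s1; inner square of side
    s2 centred within it."""

    alpha: int
    beta: int
    s1: int
    s2: int

    @property
    def inner_offset(self) -> int:
        return (self.s1 - self.s2) // 2


def crop_cell_patch(
    stack: VoxelStack, labels: np.ndarray, cell_id: int, max_size: int = PATCH_SIZE
) -> np.ndarray:
    """2-D DNA patch at the mid-z slice of a cell, masked to the cell.

    The crop is the mask's bounding box at that slice, clipped to
    ``max_size`` per side centred on the mask centroid.
    """
    vox = np.argwhere(labels == cell_id)
    if vox.size == 0:
        raise ValueError(f"cell id {cell_id} not present")
    z_mid = int(np.median(vox[:, 2]))
    mask2d = labels[:, :, z_mid] == cell_id
    if not mask2d.any():  # mid-z plane can miss a sparse mask; use nearest
        zs = np.unique(vox[:, 2])
        z_mid = int(zs[np.argmin(np.abs(zs - z_mid))])
        mask2d = labels[:, :, z_mid] == cell_id
    plane = stack.data[:, :, z_mid]
    xs, ys = np.nonzero(mask2d)
    cx, cy = xs.mean(), ys.mean()
    x0, x1 = xs.min(), xs.max() + 1
    y0, y1 = ys.min(), ys.max() + 1
    if x1 - x0 > max_size:
        x0 = int(round(cx - max_size / 2))
        x1 = x0 + max_size
    if y1 - y0 > max_size:
        y0 = int(round(cy - max_size / 2))
        y1 = y0 + max_size
    x0, y0 = max(x0, 0), max(y0, 0)
    x1 = min(x1, plane.shape[0])
    y1 = min(y1, plane.shape[1])
    return (plane * mask2d)[x0:x1, y0:y1].astype(float)


def otsu_threshold(values: np.ndarray) -> float:
    """Exact Otsu threshold: exhaustive maximization of between-class
    variance over the unique values (lowest optimum on ties)."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    u = np.unique(v)
    if u.size < 2:
        raise ValueError("constant input: Otsu threshold undefined")
    best_t, best_var = u[0], -np.inf
    n = v.size
    csum = np.cumsum(v)
    for t in u[:-1]:
        k = np.searchsorted(v, t, side="right")
        w0, w1 = k / n, (n - k) / n
        mu0 = csum[k - 1] / k
        mu1 = (csum[-1] - csum[k - 1]) / (n - k)
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-15:
            best_var, best_t = var, t
    return float(best_t)


def otsu_features(patch: np.ndarray) -> tuple[int, int]:
    """(number of spots, foreground area) of the Otsu-thresholded patch.

    The threshold is computed over the in-mask (nonzero) pixels;
    components are 8-connected. A constant patch yields (0, 0) with a
    warning.
    """
    vals = patch[patch > 0]
    if vals.size == 0 or np.unique(vals).size < 2:
        warnings.warn("constant patch: Otsu features set to (0, 0)")
        return 0, 0
    t = otsu_threshold(vals)
    fg = patch > t
    n_components = int(_cc_label(fg, connectivity=2).max())
    return n_components, int(fg.sum())


def enumerate_haar(
    frame: int = PATCH_SIZE, max_outer: int = MAX_OUTER, convention: str = "ring1"
) -> list[HaarFeature]:
    """All centre-surround Haar features in a ``frame``-square image.

    ``ring1`` (default, frozen): outer side s1 = 3..max_outer, inner
    side s1 - 2 (one-pixel ring), every position — 5239 features for a
    34-frame with max_outer 8. ``parity``: every s2 < s1 with s1 - s2
    even. ``odd``: odd s1 with odd s2 < s1.
    """
    feats: list[HaarFeature] = []
    for s1 in range(2, max_outer + 1):
        if convention == "ring1":
            inner = [s1 - 2] if s1 >= 3 else []
        elif convention == "parity":
            inner = [s2 for s2 in range(1, s1) if (s1 - s2) % 2 == 0]
        elif convention == "odd":
            inner = [s2 for s2 in range(1, s1, 2)] if s1 % 2 == 1 else []
        else:
            raise ValueError(f"unknown convention {convention!r}")
        inner = [s2 for s2 in inner if s2 >= 1]
        for s2 in inner:
            for alpha in range(frame - s1 + 1):
                for beta in range(frame - s1 + 1):
                    feats.append(HaarFeature(alpha, beta, s1, s2))
    return feats


def _integral_2d(patch: np.ndarray) -> np.ndarray:
    out = np.zeros((patch.shape[0] + 1, patch.shape[1] + 1))
    out[1:, 1:] = np.cumsum(np.cumsum(patch, axis=0), axis=1)
    return out


def _box_sum(I, x0, y0, s):
    return I[x0 + s, y0 + s] - I[x0 + s, y0] - I[x0, y0 + s] + I[x0, y0]


def haar_response(patch: np.ndarray, feature: HaarFeature) -> float:
    """mean(inner square) - mean(outer square minus inner square)."""
    f = feature
    if f.alpha < 0 or f.beta < 0 or f.alpha + f.s1 > patch.shape[0] or f.beta + f.s1 > patch.shape[1]:
        raise ValueError("feature rectangle outside the patch")
    I = _integral_2d(np.asarray(patch, dtype=float))
    off = f.inner_offset
    inner = _box_sum(I, f.alpha + off, f.beta + off, f.s2)
    outer = _box_sum(I, f.alpha, f.beta, f.s1)
    ring = outer - inner
    return float(inner / f.s2**2 - ring / (f.s1**2 - f.s2**2))


def haar_responses(patch: np.ndarray, features: list[HaarFeature]) -> np.ndarray:
    """Responses to many features at once via one integral image.

    Patches smaller than the frame are zero-padded symmetrically so the
    cell sits at the frame centre and feature positions are comparable
    across cells.
    """
    p = np.asarray(patch, dtype=float)
    side = max(PATCH_SIZE, p.shape[0], p.shape[1])
    if p.shape != (side, side):
        q = np.zeros((side, side))
        ox = (side - p.shape[0]) // 2
        oy = (side - p.shape[1]) // 2
        q[ox : ox + p.shape[0], oy : oy + p.shape[1]] = p
        p = q
    I = _integral_2d(p)
    a = np.fromiter((f.alpha for f in features), int, len(features))
    b = np.fromiter((f.beta for f in features), int, len(features))
    s1 = np.fromiter((f.s1 for f in features), int, len(features))
    s2 = np.fromiter((f.s2 for f in features), int, len(features))
    off = (s1 - s2) // 2

    def box(x0, y0, s):
        return I[x0 + s, y0 + s] - I[x0 + s, y0] - I[x0, y0 + s] + I[x0, y0]

    inner = box(a + off, b + off, s2)
    ring = box(a, b, s1) - inner
    return inner / s2**2 - ring / (s1**2 - s2**2)


def patch_feature_vector(patch: np.ndarray, features: list[HaarFeature]) -> np.ndarray:
    """[n_spots, foreground_area, haar responses...] for one patch."""
    n_cc, area = otsu_features(patch)
    return np.concatenate([[n_cc, area], haar_responses(patch, features)])


def _block_scaler(X_train: np.ndarray):
    """Per-block feature scaling: the two count features are scaled
    individually while the Haar block shares one pooled scale, so the
    natural variance ordering among Haar positions is preserved instead
    of noise dimensions being inflated to unit variance."""
    mu = X_train.mean(axis=0)
    s_counts = X_train[:, :2].std(axis=0) + 1e-12
    s_haar = X_train[:, 2:].std() + 1e-12
    scale = np.concatenate([s_counts, np.full(X_train.shape[1] - 2, s_haar)])
    return mu, scale


def _balanced_threshold(scores: np.ndarray, truth: np.ndarray) -> float:
    """Decision threshold maximizing balanced accuracy."""
    order = np.argsort(scores)
    s = scores[order]
    cand = np.concatenate([[s[0] - 1], (s[1:] + s[:-1]) / 2, [s[-1] + 1]])
    best_t, best_ba = 0.0, -1.0
    for t in cand:
        pred = scores > t
        sens = (pred & (truth == 1)).sum() / max((truth == 1).sum(), 1)
        spec = (~pred & (truth == 0)).sum() / max((truth == 0).sum(), 1)
        if (sens + spec) / 2 > best_ba:
            best_ba, best_t = (sens + spec) / 2, t
    return float(best_t)


def _make_phase_svm(phase: str) -> SVC:
    # class_weight balances the per-class box constraint the way the
    # classical SVM trainers rescale it for unbalanced data
    return SVC(
        kernel="linear",
        C=SVM_BOX[phase],
        tol=SVM_TOL[phase],
        max_iter=SVM_MAX_ITER,
        class_weight="balanced",
    )


def train_phase_classifiers(
    patches: list[np.ndarray],
    phase_labels: list[str],
    n_splits: int = 25,
    seed: int = 0,
    features: list[HaarFeature] | None = None,
):
    """One-vs-rest linear SVM per phase over repeated 50/50 splits.

    Features are scaled per block on each training split only; the
    decision threshold of each classifier is calibrated for balanced
    accuracy on out-of-fold scores within the training split (the
    learned direction is untouched). Returns a statistics DataFrame
    (mean/std sensitivity and specificity per phase) and the
    classifiers fitted on the final split.
    """
    if len(patches) < 20:
        raise ValueError("need at least 20 patches")
    phase_labels = np.asarray(phase_labels)
    present = [p for p in ("G1", "S", "G2", "M") if (phase_labels == p).sum() >= 2]
    if len(present) < 2:
        raise ValueError("need at least 2 phases present")
    for p in set(phase_labels) - set(present):
        warnings.warn(f"phase {p} has too few examples; classifier skipped")
    features = enumerate_haar() if features is None else features
    X = np.array([patch_feature_vector(p, features) for p in patches])
    rng = np.random.default_rng(seed)
    stats = {p: {"sens": [], "spec": []} for p in present}
    models = {}
    for split in range(n_splits):
        perm = rng.permutation(len(X))
        half = len(X) // 2
        tr, te = perm[:half], perm[half:]
        mu, scale = _block_scaler(X[tr])
        Xtr, Xte = (X[tr] - mu) / scale, (X[te] - mu) / scale
        for p in present:
            ytr = (phase_labels[tr] == p).astype(int)
            yte = (phase_labels[te] == p).astype(int)
            if ytr.sum() == 0 or ytr.sum() == len(ytr) or yte.sum() == 0 or yte.sum() == len(yte):
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if ytr.sum() >= 3 and (1 - ytr).sum() >= 3:
                    folds = np.arange(len(Xtr)) % 3
                    oof = np.zeros(len(Xtr))
                    ok = True
                    for f in range(3):
                        ytrain = ytr[folds != f]
                        if ytrain.min() == ytrain.max():
                            ok = False
                            break
                        cv = _make_phase_svm(p)
                        cv.fit(Xtr[folds != f], ytrain)
                        oof[folds == f] = cv.decision_function(Xtr[folds == f])
                    thresh = _balanced_threshold(oof, ytr) if ok else 0.0
                else:
                    thresh = 0.0
                clf = _make_phase_svm(p)
                clf.fit(Xtr, ytr)
            pred = (clf.decision_function(Xte) > thresh).astype(int)
            tp = int(((pred == 1) & (yte == 1)).sum())
            tn = int(((pred == 0) & (yte == 0)).sum())
            fp = int(((pred == 1) & (yte == 0)).sum())
            fn = int(((pred == 0) & (yte == 1)).sum())
            stats[p]["sens"].append(tp / (tp + fn))
            stats[p]["spec"].append(tn / (tn + fp))
            models[p] = ((mu, scale), clf, thresh)
    rows = []
    for p in present:
        s = stats[p]
        rows.append(
            {
                "phase": p,
                "n_splits": len(s["sens"]),
                "sensitivity_mean": float(np.mean(s["sens"])) if s["sens"] else np.nan,
                "sensitivity_std": float(np.std(s["sens"])) if s["sens"] else np.nan,
                "specificity_mean": float(np.mean(s["spec"])) if s["spec"] else np.nan,
                "specificity_std": float(np.std(s["spec"])) if s["spec"] else np.nan,
            }
        )
    return pd.DataFrame(rows), models
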
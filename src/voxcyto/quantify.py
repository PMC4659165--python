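"""Per-cell spatial position and fluorescence quantification.

Covers: top-layeredness (fraction of a cell unobscured in the
z-projection), geodesic position along a fitted principal axis, cell
rows on the touching-masks adjacency graph, DNA-content normalization
(the germline spline recipe and the epithelium polynomial recipe), EdU
content quantification/classification, and cell-cycle phase indices.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import UnivariateSpline
from scipy.stats import chi2_contingency

from .stacks import VoxelStack

__all__ = [
    "measure_cells",
    "top_layeredness",
    "geodesic_positions",
    "cell_rows",
    "normalize_dna_worm",
    "normalize_dna_oe",
    "quantify_edu",
    "assign_phases",
    "phase_indices",
    "compare_phase_tables",
]


def cell_ids(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    return ids[ids > 0]


def measure_cells(labels: np.ndarray, dna: VoxelStack | None = None, spacing=None) -> pd.DataFrame:
    """Raw per-cell measurements: centroid (μm), volume, DNA sums.

    ``raw_dna`` is the sum of DNA voxel values inside the mask and
    ``dna_p95`` the 95th percentile of those values.
    """
    ids = cell_ids(labels)
    if spacing is None:
        spacing = dna.spacing if dna is not None else (1.0, 1.0, 1.0)
    spacing = np.asarray(spacing, dtype=float)
    coms = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    rows = {
        "id": ids,
        "x_um": [c[0] * spacing[0] for c in coms],
        "y_um": [c[1] * spacing[1] for c in coms],
        "z_um": [c[2] * spacing[2] for c in coms],
        "volume_voxels": ndimage.sum_labels(np.ones_like(labels), labels, ids).astype(int),
    }
    if dna is not None:
        rows["raw_dna"] = ndimage.sum_labels(dna.data, labels, ids)
        rows["dna_p95"] = [
            float(np.percentile(dna.data[labels == i], 95)) for i in ids
        ]
    return pd.DataFrame(rows)


def top_layeredness(labels: np.ndarray, from_top: bool = True) -> dict[int, float]:
    """θ per cell: the fraction of a cell's xy-footprint columns in
    which that cell is the first nonzero label along z.

    ``from_top=True`` places the objective above the stack at z = 0.
    θ = 1 means direct line of sight; θ = 0 means completely obscured.
    """
    lab = labels if from_top else labels[:, :, ::-1]
    nz = lab != 0
    has_any = nz.any(axis=2)
    first = np.argmax(nz, axis=2)
    xi, yi = np.nonzero(has_any)
    top = lab[xi, yi, first[xi, yi]]
    theta = {}
    for i in cell_ids(labels):
        footprint = (lab == i).any(axis=2)
        n_cols = int(footprint.sum())
        owned = int(np.count_nonzero(top[footprint[xi, yi]] == i))
        theta[int(i)] = owned / n_cols if n_cols else 0.0
    return theta


# ---------------------------------------------------------------- position


def _project_polyline(points: np.ndarray, nodes: np.ndarray):
    """Arc-length position and distance of each point on a polyline."""
    seg = np.diff(nodes, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    best_s = np.zeros(len(points))
    best_d = np.full(len(points), np.inf)
    for k in range(len(seg)):
        v = seg[k]
        L2 = max(seglen[k] ** 2, 1e-300)
        t = np.clip((points - nodes[k]) @ v / L2, 0.0, 1.0)
        proj = nodes[k] + t[:, None] * v
        d = np.linalg.norm(points - proj, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        best_s[better] = cum[k] + t[better] * seglen[k]
    return best_s, best_d


def fit_principal_curve(
    centers_um: np.ndarray, n_nodes: int | None = None, n_iter: int = 5
) -> np.ndarray:
    """Simplified principal curve: an iterated local-averaging polyline.

    Points are ordered along the leading principal axis; polyline nodes
    are Gaussian-weighted local means of the cloud along the current
    arc-length parameter, re-estimated for ``n_iter`` rounds; the end
    segments are extrapolated so every point projects onto the interior.
    """
    pts = np.atleast_2d(np.asarray(centers_um, dtype=float))
    if len(pts) < 3:
        raise ValueError("need at least 3 centres to fit a curve")
    mu = pts.mean(axis=0)
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate point cloud (all centres identical)")
    _, _, vt = np.linalg.svd(pts - mu, full_matrices=False)
    t = (pts - mu) @ vt[0]
    if n_nodes is None:
        n_nodes = int(np.clip(len(pts) // 3, 4, 25))

    def nodes_from(t_param):
        tk = np.linspace(t_param.min(), t_param.max(), n_nodes)
        h = max((t_param.max() - t_param.min()) / n_nodes, 1e-9)
        w = np.exp(-((t_param[None, :] - tk[:, None]) ** 2) / (2 * h**2))
        w /= w.sum(axis=1, keepdims=True)
        return w @ pts

    nodes = nodes_from(t)
    for _ in range(n_iter):
        s, _ = _project_polyline(pts, nodes)
        if np.ptp(s) <= 0:
            break
        nodes = nodes_from(s)
    # extrapolate the ends so projections fall on the interior
    span = np.linalg.norm(nodes[-1] - nodes[0])
    ext = max(0.25 * span, 1.0)
    d0 = nodes[0] - nodes[1]
    d1 = nodes[-1] - nodes[-2]
    d0 = d0 / max(np.linalg.norm(d0), 1e-12)
    d1 = d1 / max(np.linalg.norm(d1), 1e-12)
    return np.vstack([nodes[0] + ext * d0, nodes, nodes[-1] + ext * d1])


def geodesic_positions(
    centers_um: np.ndarray,
    distal_point_um,
    n_nodes: int | None = None,
) -> np.ndarray:
    """Distance of each cell to the distal end along the principal curve.

    The distal end is the manually annotated anchor; each centre is
    projected onto the fitted curve and its arc length measured from the
    distal projection.
    """
    pts = np.atleast_2d(np.asarray(centers_um, dtype=float))
    nodes = fit_principal_curve(pts, n_nodes=n_nodes)
    s, _ = _project_polyline(pts, nodes)
    s0, _ = _project_polyline(np.atleast_2d(np.asarray(distal_point_um, dtype=float)), nodes)
    return np.abs(s - s0[0])


def touching_graph(labels: np.ndarray) -> nx.Graph:
    """Cells as nodes; an edge iff masks share a face-adjacent voxel pair."""
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in cell_ids(labels))
    for axis in range(3):
        a = np.swapaxes(labels, 0, axis)
        l1, l2 = a[:-1], a[1:]
        touch = (l1 != l2) & (l1 > 0) & (l2 > 0)
        pairs = np.unique(
            np.stack([l1[touch], l2[touch]], axis=1), axis=0
        ) if touch.any() else []
        for p, q in pairs:
            g.add_edge(int(p), int(q))
    return g


def cell_rows(labels: np.ndarray, distal_cell: int) -> dict[int, int]:
    """Row per cell: 1 + unweighted shortest-path hops from the distal
    cell on the touching graph; unreachable cells get row -1."""
    g = touching_graph(labels)
    if distal_cell not in g:
        raise ValueError(f"distal cell {distal_cell} not present in labels")
    lengths = nx.single_source_shortest_path_length(g, distal_cell)
    return {int(i): (lengths[i] + 1 if i in lengths else -1) for i in g.nodes}


# ---------------------------------------------------------------- DNA / EdU


def normalize_dna_worm(
    records: pd.DataFrame,
    bin_rows: int = 4,
    theta_min: float = 0.1,
    min_bin_cells: int = 5,
) -> pd.DataFrame:
    """Germline DNA-content recipe; returns top-layer cells with C-values.

    Steps: keep cells with top-layeredness θ > ``theta_min``; fit a
    cubic smoothing spline of the per-cell 95th-percentile DNA value
    against geodesic distance and divide raw contents by it (axial
    attenuation correction); within each ``bin_rows``-row bin, affinely
    map the 10th percentile of spline-normalized contents to 2C and the
    85th to 4C. Bins with fewer than ``min_bin_cells`` cells are merged
    with their neighbour.
    """
    df = records[records["theta"] > theta_min].copy()
    if df.empty:
        raise ValueError("no top-layer cells after the theta filter")
    rows_arr = df["row"].to_numpy(float)
    bad = rows_arr < 1
    if bad.any():
        # cells unreachable on the touching graph get a pseudo-row
        # interpolated from the row-vs-geodesic trend of reachable cells
        warnings.warn(f"{int(bad.sum())} cells lack a row; using geodesic pseudo-rows")
        good = ~bad
        if good.sum() >= 2 and np.ptp(df.loc[good, "geodesic_um"]) > 0:
            coef = np.polyfit(df.loc[good, "geodesic_um"], rows_arr[good], 1)
            rows_arr[bad] = np.polyval(coef, df.loc[bad, "geodesic_um"])
        else:
            rows_arr[bad] = 1
        df["row"] = np.maximum(1, np.rint(rows_arr)).astype(int)
    x = df["geodesic_um"].to_numpy(float)
    y = df["dna_p95"].to_numpy(float)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # collapse duplicate abscissae for the spline
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.bincount(inv, weights=ys) / np.bincount(inv)
    if len(ux) >= 4:
        spline = UnivariateSpline(ux, uy, k=3)
        gain = spline(x)
    else:
        coef = np.polyfit(ux, uy, 1) if len(ux) > 1 else np.array([0.0, uy.mean()])
        gain = np.polyval(coef, x)
    gain = np.maximum(gain, 1e-12 + 0.0 * gain)
    df["spline_norm_dna"] = df["raw_dna"].to_numpy(float) / gain

    bins = (df["row"].to_numpy(int) - 1) // bin_rows
    # merge undersized bins into their lower neighbour
    uniq = np.unique(bins)
    remap = {}
    prev = None
    for b in uniq:
        n = int((bins == b).sum())
        if n < min_bin_cells and prev is not None:
            warnings.warn(f"bin {b} has {n} cells; merging with neighbour")
            remap[b] = remap.get(prev, prev)
        else:
            remap[b] = b
            prev = b
    bins = np.array([remap[b] for b in bins])
    df["dna_bin"] = bins

    c = np.full(len(df), np.nan)
    v = df["spline_norm_dna"].to_numpy(float)
    for b in np.unique(bins):
        sel = bins == b
        p10, p85 = np.percentile(v[sel], [10, 85])
        if p85 - p10 <= 0:
            warnings.warn(f"degenerate percentile range in bin {b}")
            c[sel] = 3.0
        else:
            c[sel] = 2.0 + 2.0 * (v[sel] - p10) / (p85 - p10)
    df["c_value"] = c
    return df


def normalize_dna_oe(
    dna: VoxelStack,
    labels: np.ndarray,
    mphase_ids,
    mid_slices: int = 25,
) -> pd.DataFrame:
    """Epithelium DNA-content recipe.

    Gain along x is corrected with a quadratic fit to the per-x-slice
    90th-percentile intensity, z-attenuation with a linear fit over the
    middle ``mid_slices`` z-planes; per-cell sums are scaled so the
    median M-phase content is exactly 4C (M cells carry 4C DNA).
    """
    mphase_ids = list(mphase_ids)
    if not mphase_ids:
        raise ValueError("at least one M-phase annotation is required for normalization")
    data = dna.data.astype(float)
    nx_, _, nz = data.shape
    p90x = np.percentile(data.reshape(nx_, -1), 90, axis=1)
    cx = np.polyfit(np.arange(nx_), p90x, 2)
    gx = np.polyval(cx, np.arange(nx_))
    gx = np.maximum(gx, 1e-12) / max(np.mean(np.maximum(gx, 1e-12)), 1e-12)
    data = data / gx[:, None, None]

    mid = min(mid_slices, nz)
    z0 = (nz - mid) // 2
    zmid = np.arange(z0, z0 + mid)
    p90z = np.percentile(data[:, :, zmid].reshape(-1, mid), 90, axis=0)
    cz = np.polyfit(zmid, p90z, 1)
    gz = np.polyval(cz, np.arange(nz))
    gz = np.maximum(gz, 1e-12) / max(np.mean(np.maximum(gz, 1e-12)), 1e-12)
    data = data / gz[None, None, :]

    ids = cell_ids(labels)
    content = ndimage.sum_labels(data, labels, ids)
    m_mask = np.isin(ids, mphase_ids)
    if not m_mask.any():
        raise ValueError("annotated M-phase ids not present in the label volume")
    scale = 4.0 / np.median(content[m_mask])
    return pd.DataFrame({"id": ids, "c_value": content * scale})


def quantify_edu(
    edu: VoxelStack,
    labels: np.ndarray,
    t1: float,
    t2: float,
    pos_threshold: float = 0.5,
    median_size: int = 3,
) -> pd.DataFrame:
    """EdU content per cell and ±-status.

    Median filter; clamp voxel values into [t1, t2]; rescale to [0, 1];
    sum per mask; affinely map the 10th/85th percentiles of cellular
    contents to 0/1 (contents may then fall outside [0, 1]); threshold
    to status.
    """
    if t1 >= t2:
        raise ValueError("t1 must be < t2")
    data = ndimage.median_filter(edu.data.astype(float), size=median_size)
    data = (np.clip(data, t1, t2) - t1) / (t2 - t1)
    ids = cell_ids(labels)
    sums = ndimage.sum_labels(data, labels, ids)
    p10, p85 = np.percentile(sums, [10, 85])
    if p85 - p10 <= 0:
        warnings.warn("degenerate EdU percentile range; all statuses negative")
        content = np.zeros_like(sums)
    else:
        content = (sums - p10) / (p85 - p10)
    return pd.DataFrame(
        {"id": ids, "edu_content": content, "edu_pos": content > pos_threshold}
    )


# ---------------------------------------------------------------- phases


def assign_phases(records: pd.DataFrame, dna_split: float = 3.0) -> pd.Series:
    """EdU-positive -> S; EdU-negative with C below ``dna_split`` -> G1,
    above -> G2M; a ``phase_override`` column (e.g. manual M-phase
    annotations) wins when present."""
    phases = np.where(
        records["edu_pos"].to_numpy(bool),
        "S",
        np.where(records["c_value"].to_numpy(float) < dna_split, "G1", "G2M"),
    ).astype(object)
    if "phase_override" in records:
        ov = records["phase_override"]
        mask = ov.notna() & (ov != "")
        phases[mask.to_numpy()] = ov[mask].to_numpy()
    return pd.Series(phases, index=records.index, name="phase")


def phase_indices(
    records: pd.DataFrame, bin_col: str = "row", dna_split: float = 3.0
) -> pd.DataFrame:
    """Per-bin phase proportions (the phase "index").

    Returns one row per spatial bin with counts and proportions; empty
    bins do not appear. Proportions sum to 1 over counted phases.
    """
    df = records.copy()
    df["phase"] = assign_phases(df, dna_split)
    out = []
    for b, grp in df.groupby(bin_col):
        counts = grp["phase"].value_counts()
        total = int(counts.sum())
        row = {"bin": b, "n": total}
        for ph in ("G1", "S", "G2M", "M"):
            row[f"n_{ph}"] = int(counts.get(ph, 0))
            row[f"idx_{ph}"] = counts.get(ph, 0) / total if total else np.nan
        out.append(row)
    return pd.DataFrame(out)


def compare_phase_tables(counts_a, counts_b):
    """Categorical chi-square comparison of two phase-count vectors."""
    table = np.vstack([np.asarray(counts_a, float), np.asarray(counts_b, float)])
    keep = table.sum(axis=0) > 0
    chi2, p, dof, _ = chi2_contingency(table[:, keep])
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
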
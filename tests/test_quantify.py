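"""Per-cell position and fluorescence quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxcyto.quantify import (
    assign_phases,
    cell_rows,
    compare_phase_tables,
    geodesic_positions,
    measure_cells,
    normalize_dna_oe,
    normalize_dna_worm,
    phase_indices,
    quantify_edu,
    top_layeredness,
    touching_graph,
)
from voxcyto.stacks import VoxelStack


class TestTopLayeredness:
    def test_isolated_cell_fully_visible(self):
        lab = np.zeros((6, 6, 4), int)
        lab[1:4, 1:4, 1:3] = 1
        assert top_layeredness(lab)[1] == 1.0

    def test_fully_buried_cell(self):
        lab = np.zeros((6, 6, 6), int)
        lab[1:4, 1:4, 0:2] = 1  # on top (low z)
        lab[1:4, 1:4, 3:5] = 2  # identical footprint, deeper
        theta = top_layeredness(lab)
        assert theta[1] == 1.0 and theta[2] == 0.0

    def test_half_overlap(self):
        lab = np.zeros((8, 4, 6), int)
        lab[0:4, 0:4, 0:2] = 1  # top cell
        lab[2:6, 0:4, 3:5] = 2  # half of its footprint covered
        assert top_layeredness(lab)[2] == pytest.approx(0.5, abs=0.01)

    def test_footprint_sum_bounded_by_projection(self, clean_phantom):
        lab = clean_phantom.truth.labels
        theta = top_layeredness(lab)
        total = 0.0
        for i, th in theta.items():
            total += th * (lab == i).any(axis=2).sum()
        assert total <= (lab != 0).any(axis=2).sum() + 1e-9


class TestGeodesicPositions:
    def test_straight_line_equals_euclidean(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 40, 60))
        pts = np.column_stack([t, np.full(60, 2.0), np.full(60, 3.0)])
        d = geodesic_positions(pts, distal_point_um=(0, 2, 3))
        ref = t - t.min() + t.min()  # distance from x=0 along the line
        err = np.abs(d - t) / np.maximum(t, 1.0)
        assert np.max(err) < 0.02

    def test_quarter_circle_arc_length(self):
        rng = np.random.default_rng(1)
        R = 20.0
        ang = np.sort(rng.uniform(0, np.pi / 2, 200))
        pts = np.column_stack(
            [R * np.cos(ang), R * np.sin(ang), np.zeros(200)]
        )
        d = geodesic_positions(pts, distal_point_um=(R, 0, 0))
        assert d.max() == pytest.approx(R * np.pi / 2, rel=0.05)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        pts = np.column_stack(
            [np.sort(rng.uniform(0, 30, 50)), rng.normal(0, 0.5, 50), rng.normal(0, 0.5, 50)]
        )
        d1 = geodesic_positions(pts, (0, 0, 0))
        perm = rng.permutation(50)
        d2 = geodesic_positions(pts[perm], (0, 0, 0))
        assert np.allclose(d1[perm], d2, atol=1e-9)

    def test_degenerate_cloud_rejected(self):
        with pytest.raises(ValueError):
            geodesic_positions(np.ones((5, 3)), (0, 0, 0))


def _chain_labels(n=5):
    lab = np.zeros((n * 3, 3, 3), int)
    for i in range(n):
        lab[i * 3 : (i + 1) * 3] = i + 1
    return lab


class TestCellRows:
    def test_chain_counts_from_distal(self):
        rows = cell_rows(_chain_labels(5), distal_cell=1)
        assert rows == {1: 1, 2: 2, 3: 3, 4: 4, 5: 5}

    def test_disconnected_cell_flagged(self):
        lab = _chain_labels(3)
        lab[0, 0, 0] = 0  # keep chain; add an island
        lab2 = np.zeros_like(lab)
        lab2[:] = lab
        island = np.zeros((9, 3, 3), int)
        full = np.concatenate([lab2, np.zeros((2, 3, 3), int), island], axis=0)
        full[-2:, :, :] = 7
        rows = cell_rows(full, distal_cell=1)
        assert rows[7] == -1

    def test_missing_distal_cell(self):
        with pytest.raises(ValueError):
            cell_rows(_chain_labels(3), distal_cell=99)

    def test_matches_bfs_oracle(self, clean_phantom):
        import networkx as nx

        lab = clean_phantom.truth.labels
        rows = cell_rows(lab, distal_cell=1)
        g = touching_graph(lab)
        # breadth-first search oracle
        oracle = {int(i): -1 for i in g.nodes}
        frontier, depth, seen = {1}, 1, {1}
        while frontier:
            for c in frontier:
                oracle[c] = depth
            frontier = {
                n for c in frontier for n in g.neighbors(c) if n not in seen
            }
            seen |= frontier
            depth += 1
        assert rows == oracle


class TestWormDnaRecipe:
    def test_bin_percentiles_forced_to_2c_4c(self, worm_quantification):
        _, records, _ = worm_quantification
        for _, grp in records.groupby("dna_bin"):
            v = grp["c_value"].to_numpy()
            assert np.percentile(v, 10) == pytest.approx(2.0, abs=1e-9)
            assert np.percentile(v, 85) == pytest.approx(4.0, abs=1e-9)

    def test_gain_invariance(self, worm_quantification):
        ph, records, _ = worm_quantification
        doubled = records.copy()
        doubled["raw_dna"] *= 7.0
        doubled["dna_p95"] *= 7.0
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = normalize_dna_worm(doubled.drop(columns=["spline_norm_dna", "dna_bin", "c_value"]))
        assert np.allclose(again["c_value"].to_numpy(), records["c_value"].to_numpy(), atol=1e-8)

    def test_theta_filter_applied(self, worm_quantification):
        _, records, _ = worm_quantification
        assert (records["theta"] > 0.1).all()


class TestOeDnaRecipe:
    def _phantom_stack(self, gain_x=None):
        # dense tissue: a uniform base level everywhere (so per-x-slice
        # percentiles track the gain) plus brighter nuclei boxes
        lab = np.zeros((40, 12, 30), int)
        content = {}
        data = np.ones(lab.shape)
        for i in range(8):
            x0 = 2 + 4 * i + (i % 2)
            lab[x0 : x0 + 3, 4:7, 3 + 3 * i : 6 + 3 * i] = i + 1
            extra = 1.0 if i % 2 == 0 else 3.0
            data[lab == i + 1] += extra
            content[i + 1] = 2.0 if i % 2 == 0 else 4.0  # sums 2x / 4x base
        if gain_x is not None:
            data = data * gain_x[:, None, None]
        return VoxelStack(data, (0.3, 0.3, 0.3), "dna"), lab, content

    def test_uniform_gain_identity_up_to_scale(self):
        stack, lab, content = self._phantom_stack()
        out = normalize_dna_oe(stack, lab, mphase_ids=[2], mid_slices=30)
        truth = np.array([content[i] for i in out["id"]])
        ratio = out["c_value"].to_numpy() / truth
        assert ratio.std() / ratio.mean() < 0.01

    def test_quadratic_x_gain_recovery(self):
        xs = np.arange(40)
        gain = 1.0 - 0.0004 * (xs - 20) ** 2
        stack, lab, content = self._phantom_stack(gain_x=gain)
        out = normalize_dna_oe(stack, lab, mphase_ids=[2], mid_slices=30)
        truth = np.array([content[i] for i in out["id"]])
        assert np.allclose(out["c_value"], truth, rtol=0.05)

    def test_mphase_median_forced_to_4(self, clean_phantom):
        truth = clean_phantom.truth
        m_ids = [i + 1 for i, p in enumerate(truth.phases) if p == "M"]
        if not m_ids:
            pytest.skip("phantom draw contains no M cells")
        out = normalize_dna_oe(clean_phantom.dna, truth.labels, m_ids)
        m_values = out.set_index("id").loc[m_ids, "c_value"]
        assert np.median(m_values) == pytest.approx(4.0, abs=1e-9)

    def test_no_mphase_cells_is_error(self, clean_phantom):
        with pytest.raises(ValueError):
            normalize_dna_oe(clean_phantom.dna, clean_phantom.truth.labels, [])


class TestEdu:
    def test_percentiles_forced_to_0_1(self, worm_quantification):
        _, _, edu = worm_quantification
        v = edu["edu_content"].to_numpy()
        assert np.percentile(v, 10) == pytest.approx(0.0, abs=1e-9)
        assert np.percentile(v, 85) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_channel_degenerate(self, clean_phantom):
        zero = VoxelStack(np.zeros_like(clean_phantom.dna.data), (0.3, 0.3, 0.3))
        with pytest.warns(UserWarning):
            out = quantify_edu(zero, clean_phantom.truth.labels, t1=0.1, t2=0.9)
        assert (~out["edu_pos"]).all()
        assert out["edu_content"].nunique() == 1

    def test_bad_thresholds(self, clean_phantom):
        with pytest.raises(ValueError):
            quantify_edu(clean_phantom.dna, clean_phantom.truth.labels, t1=1.0, t2=0.5)


class TestPhases:
    def test_direct_count_example(self):
        records = pd.DataFrame(
            {
                "edu_pos": [True] * 5 + [False] * 5,
                "c_value": [3.0] * 5 + [2.0, 2.5, 2.9, 3.5, 3.9],
                "row": [1] * 10,
            }
        )
        table = phase_indices(records, bin_col="row")
        row = table.iloc[0]
        assert row["idx_S"] == pytest.approx(0.5)
        assert row["idx_G1"] == pytest.approx(0.3)
        assert row["idx_G2M"] == pytest.approx(0.2)

    def test_single_phase_bin(self):
        records = pd.DataFrame(
            {"edu_pos": [True, True], "c_value": [3.0, 3.0], "row": [1, 1]}
        )
        table = phase_indices(records)
        assert table.iloc[0]["idx_S"] == 1.0

    def test_override_wins(self):
        records = pd.DataFrame(
            {
                "edu_pos": [False],
                "c_value": [2.0],
                "row": [1],
                "phase_override": ["M"],
            }
        )
        assert assign_phases(records).iloc[0] == "M"

    def test_chi_square_smoke(self):
        out = compare_phase_tables([10, 20, 10], [12, 18, 11])
        assert 0 <= out["p"] <= 1 and out["dof"] == 2
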
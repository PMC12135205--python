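"""Segmentation, registration, neighbor graphs, count/design assembly, QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from pfish.cells import (
    CellsError,
    CountMatrix,
    DesignMatrix,
    LabelMask,
    apply_affine,
    assemble_counts,
    assemble_design,
    build_neighbor_graph,
    fit_affine,
    qc_filter_cells,
    segment_dilated_nuclei,
    segment_watershed,
)


def gaussian_nuclei(shape, centers, sigma=3.0, amp=500.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for cx, cy in centers:
        img += amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return img


class TestWatershed:
    def test_two_clouds_split_at_density_valley(self):
        rng = np.random.default_rng(0)
        c1, c2 = (30, 30), (70, 70)
        pts = np.vstack(
            [rng.normal(c1, 5, (400, 2)), rng.normal(c2, 5, (400, 2))]
        )
        tx = pd.DataFrame({"gene": "a", "x": pts[:, 0], "y": pts[:, 1]})
        nuc = gaussian_nuclei((100, 100), [c1, c2])
        mask = segment_watershed(nuc, tx, blur_sigma=4)
        assert mask.n_cells == 2
        # each seed falls in its own label
        l1 = mask.labels[30, 30]
        l2 = mask.labels[70, 70]
        assert {l1, l2} == {1, 2}

    def test_one_nucleus_uniform_transcripts_single_label(self):
        rng = np.random.default_rng(1)
        tx = pd.DataFrame(
            {"gene": "a", "x": rng.uniform(0, 60, 2000), "y": rng.uniform(0, 60, 2000)}
        )
        nuc = gaussian_nuclei((60, 60), [(30, 30)])
        mask = segment_watershed(nuc, tx, blur_sigma=4)
        assert mask.n_cells == 1
        assert mask.areas().iloc[0] > 100

    def test_two_seeds_in_one_cloud_partition_it(self):
        rng = np.random.default_rng(2)
        # one connected cloud with a shallow ridge between the two seeds
        pts = np.vstack(
            [rng.normal((16, 25), 5, (1500, 2)), rng.normal((34, 25), 5, (1500, 2))]
        )
        tx = pd.DataFrame({"gene": "a", "x": pts[:, 0], "y": pts[:, 1]})
        nuc = gaussian_nuclei((50, 50), [(16, 25), (34, 25)])
        mask = segment_watershed(nuc, tx, blur_sigma=3)
        assert mask.n_cells == 2
        # the cloud is connected above the floor yet both labels get a
        # substantial share, split near the density valley
        areas = mask.areas()
        assert (areas > 0.25 * areas.sum()).all()

    def test_no_nuclei_raises(self):
        tx = pd.DataFrame({"gene": "a", "x": [1.0], "y": [1.0]})
        with pytest.raises(CellsError, match="nuclei"):
            segment_watershed(np.zeros((20, 20)), tx)


class TestDilatedNuclei:
    def test_disc_grows_by_dilation_radius(self):
        yy, xx = np.mgrid[0:80, 0:80]
        nuc = ((xx - 40) ** 2 + (yy - 40) ** 2 <= 8**2).astype(float)
        mask = segment_dilated_nuclei(nuc, dilation_px=6, threshold=0.5)
        assert mask.n_cells == 1
        area = mask.areas().iloc[0]
        expected = np.pi * (8 + 6) ** 2
        assert abs(np.sqrt(area / np.pi) - 14) <= 1  # radius within 1 px

    def test_far_nuclei_stay_disjoint(self):
        yy, xx = np.mgrid[0:100, 0:100]
        nuc = (
            ((xx - 25) ** 2 + (yy - 50) ** 2 <= 5**2)
            | ((xx - 75) ** 2 + (yy - 50) ** 2 <= 5**2)
        ).astype(float)
        mask = segment_dilated_nuclei(nuc, dilation_px=8, threshold=0.5)
        assert mask.n_cells == 2

    def test_close_nuclei_boundary_equidistant(self):
        yy, xx = np.mgrid[0:100, 0:120]
        nuc = (
            ((xx - 40) ** 2 + (yy - 50) ** 2 <= 5**2)
            | ((xx - 80) ** 2 + (yy - 50) ** 2 <= 5**2)
        ).astype(float)
        mask = segment_dilated_nuclei(nuc, dilation_px=20, threshold=0.5)
        # boundary along the midline x = 60: label flips within ±1 px
        row = mask.labels[50]
        left = row[55]
        right = row[65]
        assert left != right and left > 0 and right > 0
        flip = np.flatnonzero(np.diff(row[40:80]) != 0) + 40
        mid_flips = [f for f in flip if row[f] > 0 and row[f + 1] > 0]
        assert any(abs(f - 59.5) <= 1.5 for f in mid_flips)


class TestAffine:
    def test_identity(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [3, 4]])
        A = fit_affine(pts, pts)
        np.testing.assert_allclose(A, [[1, 0, 0], [0, 1, 0]], atol=1e-12)

    def test_known_scale_translation_recovered_exactly(self):
        # mirrors a 30× magnification change between modalities
        rng = np.random.default_rng(3)
        src = rng.uniform(0, 100, (10, 2))
        true = np.array([[30.0, 0.0, 12.5], [0.0, 30.0, -7.25]])
        dst = apply_affine(true, src)
        A = fit_affine(src, dst)
        np.testing.assert_allclose(A, true, atol=1e-9)

    def test_two_points_rank_error(self):
        with pytest.raises(CellsError, match="rank error"):
            fit_affine(np.array([[0.0, 0], [1, 1]]), np.array([[0.0, 0], [2, 2]]))

    def test_collinear_rank_error(self):
        src = np.array([[0.0, 0], [1, 1], [2, 2], [3, 3]])
        with pytest.raises(CellsError, match="collinear"):
            fit_affine(src, src)


def square_mask(positions, size, shape):
    labels = np.zeros(shape, dtype=int)
    for k, (x, y) in enumerate(positions, 1):
        labels[y : y + size, x : x + size] = k
    return LabelMask(labels)


def brute_force_edges(mask: LabelMask, dilation: float) -> set:
    """All-pairs dilation-overlap test via full-image distance transforms."""
    edges = set()
    for i in range(1, mask.n_cells + 1):
        grown = ndimage.distance_transform_edt(mask.labels != i) <= dilation
        for j in range(i + 1, mask.n_cells + 1):
            if np.any(grown & (mask.labels == j)):
                edges.add((i, j))
    return edges


class TestNeighborGraph:
    @pytest.mark.parametrize("gap,expected", [(49, True), (51, False)])
    def test_50px_dilation_boundary(self, gap, expected):
        mask = square_mask([(10, 10), (10 + 10 + gap, 10)], 10, (40, 140))
        g = build_neighbor_graph(mask, dilation_px=50)
        assert ((1, 2) in g.edges) is expected

    def test_isolated_cell_low_density(self):
        mask = square_mask([(5, 5)], 8, (30, 30))
        g = build_neighbor_graph(mask, dilation_px=10)
        assert g.edges == set()
        assert g.density_class().loc[1] == "low"

    def test_honeycomb_center_has_six_neighbors(self):
        # 7 discs: center + 6 at hexagon vertices, touching via dilation
        centers = [(60, 60)]
        for k in range(6):
            ang = k * np.pi / 3
            centers.append((60 + 26 * np.cos(ang), 60 + 26 * np.sin(ang)))
        labels = np.zeros((120, 120), dtype=int)
        yy, xx = np.mgrid[0:120, 0:120]
        for k, (cx, cy) in enumerate(centers, 1):
            labels[(xx - cx) ** 2 + (yy - cy) ** 2 <= 10**2] = k
        mask = LabelMask(labels)
        g = build_neighbor_graph(mask, dilation_px=8)
        assert len(g.neighbors_of(1)) == 6
        assert g.density_class().loc[1] == "high"
        assert g.edges == brute_force_edges(mask, 8)

    def test_matches_brute_force_on_random_field(self):
        rng = np.random.default_rng(7)
        labels = np.zeros((150, 150), dtype=int)
        yy, xx = np.mgrid[0:150, 0:150]
        pts = []
        k = 0
        while k < 20:
            x, y = rng.uniform(8, 142, 2)
            if all((x - px) ** 2 + (y - py) ** 2 > 13**2 for px, py in pts):
                k += 1
                pts.append((x, y))
                labels[(xx - x) ** 2 + (yy - y) ** 2 <= 6**2] = k
        mask = LabelMask(labels)
        for dil in (3, 6):
            g = build_neighbor_graph(mask, dilation_px=dil)
            assert g.edges == brute_force_edges(mask, dil)

    def test_density_classes_partition(self):
        mask = square_mask([(5, 5), (20, 5), (60, 60)], 8, (80, 80))
        g = build_neighbor_graph(mask, dilation_px=10)
        cls = g.density_class()
        assert set(cls.unique()) <= {"low", "high"}
        assert len(cls) == 3


class TestAssembly:
    def test_counts_by_pixel_lookup(self):
        mask = square_mask([(0, 0), (20, 0), (0, 20)], 10, (40, 40))
        tx = pd.DataFrame(
            {
                "gene": ["A"] * 10 + ["B"] * 3,
                "x": [2.0] * 10 + [25.0] * 3,
                "y": [22.0] * 10 + [5.0] * 3,
            }
        )
        cm = assemble_counts(mask, tx)
        assert cm.counts.loc[3, "A"] == 10
        assert cm.counts.loc[2, "B"] == 3
        assert cm.counts.to_numpy().sum() == 13
        assert cm.n_unassigned == 0

    def test_transcript_conservation_and_unassigned(self):
        rng = np.random.default_rng(4)
        mask = square_mask([(5, 5), (25, 25)], 10, (40, 40))
        tx = pd.DataFrame(
            {
                "gene": rng.choice(["A", "B", "C"], 300),
                "x": rng.uniform(-5, 45, 300),
                "y": rng.uniform(-5, 45, 300),
            }
        )
        cm = assemble_counts(mask, tx)
        in_mask = 0
        for _, r in tx.iterrows():
            ix, iy = int(np.floor(r["x"])), int(np.floor(r["y"]))
            if 0 <= ix < 40 and 0 <= iy < 40 and mask.labels[iy, ix] > 0:
                in_mask += 1
        assert cm.counts.to_numpy().sum() == in_mask
        assert cm.n_unassigned == 300 - in_mask

    def test_design_from_qc_spots(self, codebook_small):
        mask = square_mask([(0, 0), (20, 0)], 10, (40, 40))
        spots = pd.DataFrame(
            {
                "x": [2.0, 3.0, 25.0, 35.0],
                "y": [2.0, 3.0, 5.0, 35.0],
                "bits": [""] * 4,
                "identity": ["guide_001", "blank_001", "control_001", "guide_002"],
                "is_blank": [False, True, False, False],
                "mean_intensity": 1.0,
                "std_intensity": 0.0,
                "area": 10,
                "eccentricity": 0.0,
                "qc_pass": [True, True, True, True],
            }
        )
        dm = assemble_design(mask, spots, codebook_small)
        assert dm.assign.loc[1, "guide_001"] == 1
        assert not dm.is_control.loc[1]
        assert dm.is_control.loc[2]  # only a control guide
        assert dm.n_guides.loc[1] == 1  # blank never counted
        # spot on background (label 0) ignored
        assert dm.assign.loc[2].sum() == 0

    def test_empty_mask_raises(self):
        with pytest.raises(CellsError, match="empty mask"):
            assemble_counts(LabelMask(np.zeros((5, 5), dtype=int)), pd.DataFrame({"gene": [], "x": [], "y": []}))


class TestCellQC:
    def make_counts(self, totals, n_genes=4, areas=None):
        n = len(totals)
        rng = np.random.default_rng(0)
        mat = np.zeros((n, n_genes), dtype=int)
        for i, t in enumerate(totals):
            alloc = rng.multinomial(t, np.full(n_genes, 1 / n_genes))
            mat[i] = alloc
        df = pd.DataFrame(mat, index=np.arange(1, n + 1), columns=[f"g{j}" for j in range(n_genes)])
        area = None if areas is None else pd.Series(areas, index=df.index)
        return CountMatrix(df, cell_area=area)

    @pytest.mark.parametrize(
        "total,kept", [(69, False), (70, True), (2300, True), (2301, False)]
    )
    def test_thp1_boundaries_strict_outside(self, total, kept):
        cm = self.make_counts([total])
        out, _ = qc_filter_cells(cm, None, "thp1")
        assert (len(out.counts) == 1) is kept

    def test_thp1_toy_five_cells(self):
        cm = self.make_counts([50, 70, 500, 2300, 2400])
        out, _ = qc_filter_cells(cm, None, "thp1")
        assert len(out.counts) == 3

    def test_astrocyte_gene_floor(self):
        df = pd.DataFrame(
            {"hi": [300, 310, 320], "lo": [1, 0, 0]},
            index=[1, 2, 3],
        )
        out, _ = qc_filter_cells(CountMatrix(df), None, "astrocyte")
        assert list(out.counts.columns) == ["hi"]
        assert len(out.counts) == 3

    def test_tumor_area_bounds(self):
        cm = self.make_counts([100, 100, 100], areas=[1500, 2000, 30001])
        out, _ = qc_filter_cells(cm, None, "tumor")
        assert list(out.counts.index) == [2]

    def test_unknown_preset_raises(self):
        with pytest.raises(CellsError, match="unknown QC preset"):
            qc_filter_cells(self.make_counts([100]), None, "nope")

    def test_design_filtered_jointly(self):
        cm = self.make_counts([50, 500])
        dm = DesignMatrix(
            pd.DataFrame({"p1": [1, 0]}, index=[1, 2]),
            pd.Series([False, True], index=[1, 2]),
            pd.Series([1, 1], index=[1, 2]),
        )
        out_c, out_d = qc_filter_cells(cm, dm, "thp1")
        assert list(out_c.counts.index) == [2]
        assert list(out_d.assign.index) == [2]
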
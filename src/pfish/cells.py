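"""Cell segmentation, cross-modality registration, neighbor graphs and
count/design table assembly.

Segmentation offers two routes: marker-controlled watershed over a
transcript-density map seeded at nucleus centroids (monocyte-style dense
cultures), and isotropic dilation of thresholded nuclei with a
distance-transform tie-break (astrocyte/tumor-style).  Contact neighbors
are defined by mask dilation: cells i and j are neighbors iff the
Euclidean dilation of i's mask overlaps j's mask.  Cells with ≤ 2
neighbors are "low density", with ≥ 3 "high density".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, segmentation
from skimage.filters import gaussian, threshold_otsu

__all__ = [
    "LabelMask",
    "NeighborGraph",
    "CountMatrix",
    "DesignMatrix",
    "CellsError",
    "segment_watershed",
    "segment_dilated_nuclei",
    "fit_affine",
    "build_neighbor_graph",
    "assemble_counts",
    "assemble_design",
    "qc_filter_cells",
    "QC_PRESETS",
]

LOW_DENSITY_MAX_NEIGHBORS = 2  # ≤ 2 neighbors → low density; ≥ 3 → high


class CellsError(ValueError):
    pass


@dataclass
class LabelMask:
    """Integer-labeled segmentation: 0 = background, k ≥ 1 = cell k."""

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise CellsError("label mask must be 2D")
        if self.labels.min() < 0:
            raise CellsError("label mask must be non-negative")
        self._relabel_contiguous()

    def _relabel_contiguous(self) -> None:
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size and (present[-1] != present.size):
            lut = np.zeros(int(present[-1]) + 1, dtype=self.labels.dtype)
            lut[present] = np.arange(1, present.size + 1)
            self.labels = lut[self.labels]

    @property
    def n_cells(self) -> int:
        return int(self.labels.max())

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(1, self.n_cells + 1)

    def areas(self) -> pd.Series:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_cells + 1)
        return pd.Series(counts[1:], index=self.cell_ids, name="area")


@dataclass
class NeighborGraph:
    """Dilation-contact adjacency with per-cell density class."""

    n_cells: int
    edges: set[tuple[int, int]]  # (i, j) with i < j, labels 1-based
    dilation_px: float

    def __post_init__(self) -> None:
        for i, j in self.edges:
            if not (1 <= i < j <= self.n_cells):
                raise CellsError(f"invalid edge ({i}, {j})")

    def neighbor_counts(self) -> pd.Series:
        counts = np.zeros(self.n_cells, dtype=int)
        for i, j in self.edges:
            counts[i - 1] += 1
            counts[j - 1] += 1
        return pd.Series(counts, index=np.arange(1, self.n_cells + 1), name="n_neighbors")

    def density_class(self) -> pd.Series:
        counts = self.neighbor_counts()
        cls = np.where(counts.to_numpy() <= LOW_DENSITY_MAX_NEIGHBORS, "low", "high")
        return pd.Series(cls, index=counts.index, name="density_class")

    def neighbors_of(self, cell: int) -> set[int]:
        out = set()
        for i, j in self.edges:
            if i == cell:
                out.add(j)
            elif j == cell:
                out.add(i)
        return out

    def to_edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["cell_i", "cell_j"])


@dataclass
class CountMatrix:
    """Cells × genes integer counts with per-cell area bookkeeping."""

    counts: pd.DataFrame  # index: cell label, columns: gene
    cell_area: pd.Series | None = None
    n_unassigned: int = 0

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass
class DesignMatrix:
    """Cells × perturbation indicators plus control/multiplicity flags.

    A cell is a control iff it carries at least one decoded guide and all
    of its guides are control-class.
    """

    assign: pd.DataFrame  # index: cell label, columns: targeting perturbations
    is_control: pd.Series
    n_guides: pd.Series

    def __post_init__(self) -> None:
        if not self.assign.index.equals(self.is_control.index) or not self.assign.index.equals(
            self.n_guides.index
        ):
            raise CellsError("design matrix components index mismatch")

    @property
    def n_targeting_guides(self) -> pd.Series:
        return self.assign.sum(axis=1)


def _detect_nuclei(
    nuclei_img: np.ndarray, min_size: int = 20, threshold: float | None = None
) -> np.ndarray:
    """Otsu-threshold DAPI, fill holes, drop specks; return labeled nuclei."""
    img = np.asarray(nuclei_img, dtype=float)
    if threshold is None:
        if img.max() == img.min():
            raise CellsError("no nuclei: constant nuclei image")
        threshold = threshold_otsu(img)
    binary = img > threshold
    binary = ndimage.binary_fill_holes(binary)
    lab = measure.label(binary, connectivity=2)
    sizes = np.bincount(lab.ravel())
    small = np.flatnonzero(sizes < min_size)
    lab[np.isin(lab, small[small > 0])] = 0
    return measure.label(lab > 0, connectivity=2)


def segment_watershed(
    nuclei_img: np.ndarray,
    transcripts: pd.DataFrame,
    blur_sigma: float = 5.0,
    density_floor_frac: float = 0.05,
    nuclei_min_size: int = 20,
    nuclei_threshold: float | None = None,
    pixel_size_um: float = 1.0,
) -> LabelMask:
    """Watershed cells from a transcript-density map seeded at nuclei.

    The elevation map is the negated Gaussian-blurred 2D histogram of
    transcript positions; flooding starts from nucleus centroids and stops
    where density falls below ``density_floor_frac`` of its maximum.
    """
    nuclei = _detect_nuclei(nuclei_img, nuclei_min_size, nuclei_threshold)
    props = measure.regionprops(nuclei)
    if not props:
        raise CellsError("no nuclei detected")
    if len(transcripts) == 0:
        raise CellsError("no transcripts provided")

    shape = np.asarray(nuclei_img).shape
    hist = np.zeros(shape, dtype=float)
    xs = np.floor(transcripts["x"].to_numpy(float)).astype(int)
    ys = np.floor(transcripts["y"].to_numpy(float)).astype(int)
    ok = (xs >= 0) & (xs < shape[1]) & (ys >= 0) & (ys < shape[0])
    np.add.at(hist, (ys[ok], xs[ok]), 1.0)
    density = gaussian(hist, sigma=blur_sigma, preserve_range=True)

    markers = np.zeros(shape, dtype=int)
    for k, prop in enumerate(props, start=1):
        cy, cx = prop.centroid
        markers[int(round(cy)), int(round(cx))] = k

    mask = density >= density_floor_frac * density.max()
    # seeds must live inside the flooded region
    mask |= markers > 0
    labels = segmentation.watershed(-density, markers=markers, mask=mask)

    # keep only the component of each label containing its seed
    cleaned = np.zeros_like(labels)
    for k in range(1, len(props) + 1):
        comp = measure.label(labels == k, connectivity=2)
        seed_yx = np.argwhere(markers == k)[0]
        seed_comp = comp[seed_yx[0], seed_yx[1]]
        if seed_comp > 0:
            cleaned[comp == seed_comp] = k
    return LabelMask(cleaned, pixel_size_um)


def segment_dilated_nuclei(
    nuclei_img: np.ndarray,
    dilation_px: float,
    threshold: float | None = None,
    min_size: int = 20,
    pixel_size_um: float = 1.0,
) -> LabelMask:
    """Threshold nuclei and dilate each label isotropically.

    Expansion assigns each background pixel within ``dilation_px`` of any
    nucleus to the nearest one (distance-transform tie-break), so labels
    never overwrite each other.
    """
    nuclei = _detect_nuclei(nuclei_img, min_size, threshold)
    expanded = segmentation.expand_labels(nuclei, distance=dilation_px)
    return LabelMask(expanded, pixel_size_um)


def fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 2D affine transform mapping ``src`` → ``dst``.

    Returns a 2×3 matrix ``A`` with ``dst ≈ src_h @ A.T`` for homogeneous
    ``src_h = [x, y, 1]``.  Requires ≥ 3 non-collinear point pairs.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise CellsError("point sets must both be (N, 2)")
    if src.shape[0] < 3:
        raise CellsError("rank error: need at least 3 point pairs")
    H = np.column_stack([src, np.ones(src.shape[0])])
    if np.linalg.matrix_rank(H) < 3:
        raise CellsError("rank error: collinear points")
    coef, *_ = np.linalg.lstsq(H, dst, rcond=None)
    return coef.T  # 2×3


def apply_affine(transform: np.ndarray, points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    H = np.column_stack([points, np.ones(points.shape[0])])
    return H @ np.asarray(transform).T


def _dilated_footprint(cell_mask: np.ndarray, dilation_px: float) -> np.ndarray:
    """Euclidean-disc dilation via distance transform (``in all directions``)."""
    return ndimage.distance_transform_edt(~cell_mask) <= dilation_px


def build_neighbor_graph(mask: LabelMask, dilation_px: float) -> NeighborGraph:
    """Contact adjacency: i ~ j iff dilate(mask_i) ∩ mask_j ≠ ∅.

    Computed per cell on a padded bounding box; symmetry holds by the
    symmetry of the Euclidean distance (dilation-overlap in one direction
    implies it in the other for equal radii).
    """
    labels = mask.labels
    n = mask.n_cells
    edges: set[tuple[int, int]] = set()
    pad = int(np.ceil(dilation_px)) + 1
    objects = ndimage.find_objects(labels)
    for i in range(1, n + 1):
        sl = objects[i - 1]
        if sl is None:
            continue
        y0 = max(sl[0].start - pad, 0)
        y1 = min(sl[0].stop + pad, labels.shape[0])
        x0 = max(sl[1].start - pad, 0)
        x1 = min(sl[1].stop + pad, labels.shape[1])
        crop = labels[y0:y1, x0:x1]
        grown = _dilated_footprint(crop == i, dilation_px)
        hits = np.unique(crop[grown])
        for j in hits:
            if j > i:
                edges.add((i, int(j)))
            elif 0 < j < i:
                edges.add((int(j), i))
    return NeighborGraph(n, edges, dilation_px)


def assemble_counts(mask: LabelMask, transcripts: pd.DataFrame) -> CountMatrix:
    """Sum transcripts per (cell, gene) by pixel lookup of each position.

    Points on background (label 0) or out of bounds are unassigned and
    only counted in ``n_unassigned``.
    """
    if mask.n_cells == 0:
        raise CellsError("empty mask")
    labels = mask.labels
    genes = sorted(transcripts["gene"].unique())
    xs = np.floor(transcripts["x"].to_numpy(float)).astype(int)
    ys = np.floor(transcripts["y"].to_numpy(float)).astype(int)
    inb = (xs >= 0) & (xs < labels.shape[1]) & (ys >= 0) & (ys < labels.shape[0])
    cell = np.zeros(len(transcripts), dtype=int)
    cell[inb] = labels[ys[inb], xs[inb]]
    assigned = inb & (cell > 0)

    gene_idx = pd.Categorical(transcripts["gene"], categories=genes).codes
    counts = np.zeros((mask.n_cells, len(genes)), dtype=int)
    np.add.at(counts, (cell[assigned] - 1, gene_idx[assigned]), 1)
    df = pd.DataFrame(counts, index=mask.cell_ids, columns=genes)
    return CountMatrix(df, cell_area=mask.areas(), n_unassigned=int((~assigned).sum()))


def assemble_design(
    mask: LabelMask, spots: pd.DataFrame, codebook
) -> DesignMatrix:
    """Build the cells × perturbations design from qc-passing guide spots.

    Blank matches and unmatched spots never enter the design; the control
    flag marks cells whose decoded guides are all control-class.
    """
    if mask.n_cells == 0:
        raise CellsError("empty mask")
    labels = mask.labels
    classes = dict(zip(codebook.identities, codebook.classes))
    targeting = [i for i, c in zip(codebook.identities, codebook.classes) if c == "targeting"]

    usable = spots[
        spots["qc_pass"] & spots["identity"].notna() & ~spots["is_blank"]
    ]
    assign = pd.DataFrame(
        0, index=mask.cell_ids, columns=targeting, dtype=int
    )
    n_guides = pd.Series(0, index=mask.cell_ids, dtype=int)
    has_target = pd.Series(False, index=mask.cell_ids)
    has_control = pd.Series(False, index=mask.cell_ids)
    for _, row in usable.iterrows():
        ix, iy = int(np.floor(row["x"])), int(np.floor(row["y"]))
        if not (0 <= iy < labels.shape[0] and 0 <= ix < labels.shape[1]):
            continue
        cell = labels[iy, ix]
        if cell == 0:
            continue
        n_guides[cell] += 1
        if classes.get(row["identity"]) == "control":
            has_control[cell] = True
        else:
            has_target[cell] = True
            assign.loc[cell, row["identity"]] = 1
    is_control = has_control & ~has_target
    return DesignMatrix(assign, is_control, n_guides)


QC_PRESETS = {
    # keep cells with totals inside [lo, hi]; the printed bounds are
    # exclusive removals ("less than 70 or more than 2300"), so the
    # boundary values themselves are kept
    "thp1": {"min_total": 70, "max_total": 2300},
    "astrocyte": {"min_total": 200, "max_total": 1900, "min_gene_mean": 0.5},
    "tumor": {
        "min_total": 40,
        "max_total": 800,
        "min_gene_mean": 0.3,
        "min_area": 2000,
        "max_area": 30000,
    },
}


def qc_filter_cells(
    counts: CountMatrix,
    design: DesignMatrix | None = None,
    preset: str = "thp1",
    **overrides,
) -> tuple[CountMatrix, DesignMatrix | None]:
    """Apply a named QC preset to counts (and, jointly, the design).

    Gene filters (minimum mean counts/cell) are applied before cell-total
    filters so that totals reflect the retained gene panel.  All bounds
    are inclusive on the keep side.
    """
    if preset not in QC_PRESETS and preset != "custom":
        raise CellsError(f"unknown QC preset: {preset!r}")
    rules = dict(QC_PRESETS.get(preset, {}))
    rules.update(overrides)

    mat = counts.counts
    if "min_gene_mean" in rules:
        keep_genes = mat.mean(axis=0) >= rules["min_gene_mean"]
        mat = mat.loc[:, keep_genes]
    totals = mat.sum(axis=1)
    keep = pd.Series(True, index=mat.index)
    if "min_total" in rules:
        keep &= totals >= rules["min_total"]
    if "max_total" in rules:
        keep &= totals <= rules["max_total"]
    if "min_area" in rules or "max_area" in rules:
        if counts.cell_area is None:
            raise CellsError("area bounds requested but cell areas unavailable")
        area = counts.cell_area.reindex(mat.index)
        if "min_area" in rules:
            keep &= area >= rules["min_area"]
        if "max_area" in rules:
            keep &= area <= rules["max_area"]

    filtered = CountMatrix(
        mat.loc[keep],
        cell_area=None if counts.cell_area is None else counts.cell_area[keep],
        n_unassigned=counts.n_unassigned,
    )
    if design is None:
        return filtered, None
    kept_idx = filtered.counts.index
    fdesign = DesignMatrix(
        design.assign.loc[kept_idx],
        design.is_control.loc[kept_idx],
        design.n_guides.loc[kept_idx],
    )
    return filtered, fdesign
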
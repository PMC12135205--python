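"""Synthetic data generation for every stage of the pipeline.

Three generators with known ground truth make the whole toolkit testable
without any real acquisition:

* :func:`simulate_imaging_run` renders diffraction-limited Gaussian spots
  that light up in exactly the (possibly corrupted) on-bits of their
  barcode across a rounds × channels image series with 7 z-planes,
  multiplicative illumination gradients, per-channel background images,
  bit dropout/flip errors and spurious single-bit detections.
* :func:`simulate_screen` lays cells out with a left-to-right density
  gradient, draws negative-binomial expression with planted intrinsic,
  density-modulated and neighbor-transmitted multiplicative effects
  (all additive on the natural-log scale), and returns counts, design,
  label mask and the planted truth.
* :func:`simulate_calcium` draws per-cell traces from the six canonical
  response archetypes plus Gaussian noise, with known class labels.

All generators are deterministic under their config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calcium as _calcium
from .cells import LabelMask, NeighborGraph, build_neighbor_graph
from .codebook import Codebook

__all__ = [
    "ImagingSimConfig",
    "ScreenSimConfig",
    "CalciumSimConfig",
    "ImagingRun",
    "ScreenSim",
    "SimulationError",
    "simulate_imaging_run",
    "simulate_screen",
    "simulate_calcium",
    "render_calcium_movie",
    "sparse_effect_matrix",
]


class SimulationError(ValueError):
    pass


# --------------------------------------------------------------------------
# imaging


@dataclass
class ImagingSimConfig:
    """Physics of a simulated multi-round spot-imaging field."""

    shape: tuple[int, int] = (256, 256)
    n_z: int = 7
    spot_sigma: float = 1.5
    spot_amplitude: float = 400.0
    amplitude_jitter: float = 0.15
    n_spots: int = 50
    min_spot_separation: float = 12.0
    p_dropout: float = 0.0
    p_flip: float = 0.0
    false_spot_rate: float = 0.0  # spurious spots per pixel
    illumination_gradient: float = 0.0  # 0 → flat; 1 → 2× left-to-right ramp
    background_level: float = 100.0
    n_nuclei: int = 8
    nucleus_radius: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_dropout", "p_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.false_spot_rate < 0:
            raise SimulationError("false_spot_rate must be non-negative")
        if self.background_level <= 0:
            raise SimulationError("background_level must be positive")


@dataclass
class ImagingRun:
    """Simulated raw data plus ground truth for one field of view."""

    bit_stacks: list[np.ndarray]  # L stacks of (n_z, H, W)
    backgrounds: list[np.ndarray]  # one per channel
    nuclei_image: np.ndarray
    truth: pd.DataFrame  # x, y, identity, true_bits, rendered_bits, n_dropped, n_flipped
    fiducials: list[np.ndarray]  # one per round


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: float,
    max_tries: int = 20000,
) -> np.ndarray:
    pts: list[tuple[float, float]] = []
    h, w = shape
    for _ in range(max_tries):
        if len(pts) == n:
            break
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in pts):
            pts.append((x, y))
    if len(pts) < n:
        raise SimulationError(
            f"placement failure: placed {len(pts)}/{n} spots at separation {min_sep}"
        )
    return np.asarray(pts)


def _render_gaussians(
    shape: tuple[int, int], pts: np.ndarray, amps: np.ndarray, sigma: float
) -> np.ndarray:
    """Sum of 2D Gaussian blobs, each rendered on a local window."""
    img = np.zeros(shape)
    r = int(np.ceil(4 * sigma))
    h, w = shape
    for (x, y), a in zip(pts, amps):
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        ys = slice(max(y0 - r, 0), min(y0 + r + 1, h))
        xs = slice(max(x0 - r, 0), min(x0 + r + 1, w))
        yy, xx = np.mgrid[ys, xs]
        img[ys, xs] += a * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    return img


def simulate_imaging_run(codebook: Codebook, config: ImagingSimConfig) -> ImagingRun:
    """Render one field of view of barcode spots with configurable noise.

    Each planted spot appears as a Gaussian blob in exactly the on-bits of
    its (possibly corrupted) barcode, in all ``n_z`` planes with an
    amplitude falloff toward the stack ends.  The observed image is
    ``field × (signal + background_level)`` with ``field`` a multiplicative
    left-to-right ramp of strength ``illumination_gradient``; the returned
    per-channel background images equal ``field × background_level``, so
    flat-field division cancels the gradient exactly.
    """
    rng = np.random.default_rng(config.seed)
    L = codebook.n_bits
    h, w = config.shape
    pts = _place_points(
        rng, config.n_spots, config.shape, config.min_spot_separation, margin=8.0
    )
    # real spots only ever carry real-guide barcodes; blanks stay unused
    real_ids = [
        ident
        for ident, cls in zip(codebook.identities, codebook.classes)
        if cls != "blank"
    ]
    identities = [
        real_ids[i] for i in rng.integers(0, len(real_ids), size=config.n_spots)
    ]

    truth_rows = []
    rendered_bits = np.zeros((config.n_spots, L), dtype=np.uint8)
    for s, ident in enumerate(identities):
        true = codebook.codeword_of(ident)
        bits = true.copy()
        n_drop = n_flip = 0
        on = np.flatnonzero(true)
        off = np.flatnonzero(true == 0)
        for b in on:
            if rng.random() < config.p_dropout:
                bits[b] = 0
                n_drop += 1
        for b in off:
            if rng.random() < config.p_flip:
                bits[b] = 1
                n_flip += 1
        rendered_bits[s] = bits
        truth_rows.append(
            {
                "x": pts[s, 0],
                "y": pts[s, 1],
                "identity": ident,
                "true_bits": "".join(map(str, true)),
                "rendered_bits": "".join(map(str, bits)),
                "n_dropped": n_drop,
                "n_flipped": n_flip,
            }
        )
    truth = pd.DataFrame(truth_rows)

    # multiplicative illumination field (shared across channels)
    ramp = 1.0 + config.illumination_gradient * (np.arange(w) / max(w - 1, 1))
    fieldmap = np.tile(ramp, (h, 1))
    backgrounds = [fieldmap * config.background_level for _ in range(codebook.layout.n_channels)]

    # z amplitude falloff: brightest mid-stack
    zf = 1.0 - 0.4 * np.abs(np.linspace(-1, 1, config.n_z))

    bit_stacks = []
    for b in range(L):
        sel = rendered_bits[:, b].astype(bool)
        amps = config.spot_amplitude * (
            1.0 + config.amplitude_jitter * rng.standard_normal(config.n_spots)
        )
        amps = np.clip(amps, 0.2 * config.spot_amplitude, None)
        base = _render_gaussians(config.shape, pts[sel], amps[sel], config.spot_sigma)
        # spurious single-bit detections
        n_false = rng.poisson(config.false_spot_rate * h * w)
        if n_false:
            fp = np.column_stack(
                [rng.uniform(4, w - 4, n_false), rng.uniform(4, h - 4, n_false)]
            )
            fa = config.spot_amplitude * rng.uniform(0.3, 0.8, n_false)
            base = base + _render_gaussians(config.shape, fp, fa, config.spot_sigma)
        stack = np.stack(
            [fieldmap * (base * zf[z] + config.background_level) for z in range(config.n_z)]
        )
        bit_stacks.append(stack)

    # fiducial beads shared by all rounds
    beads = _place_points(rng, 20, config.shape, 6.0, margin=4.0)
    fid = _render_gaussians(config.shape, beads, np.full(20, 300.0), 1.2) + 10.0
    fiducials = [fid.copy() for _ in range(codebook.layout.n_rounds)]

    nuc_pts = _place_points(rng, config.n_nuclei, config.shape, 4 * config.nucleus_radius, margin=10.0)
    yy, xx = np.mgrid[0:h, 0:w]
    nuclei = np.zeros((h, w))
    for x, y in nuc_pts:
        nuclei += 1000.0 * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * (config.nucleus_radius / 1.5) ** 2)
        )
    return ImagingRun(bit_stacks, backgrounds, nuclei, truth, fiducials)


# --------------------------------------------------------------------------
# screen


@dataclass
class ScreenSimConfig:
    """Design of a simulated perturbation screen with spatial context.

    Effects are natural-log fold changes: expression of gene g in cell c
    is negative-binomial with mean ``baseline_g × exp(intrinsic + density
    modifier + Σ neighbor effects)``.  ``density_modifier`` applies only
    to cells of ``density_modifier_stratum``; ``neighbor_effect[p, g]``
    applies once per distinct perturbed contact neighbor carrying p.
    """

    n_genes: int = 20
    n_perturbations: int = 5
    cells_per_perturbation: int = 100
    n_control_cells: int = 200
    baseline_mean: np.ndarray | float | None = 5.0
    dispersion: float = 0.1  # NB: var = μ + dispersion μ²
    effects: np.ndarray | None = None  # (n_pert, n_genes) intrinsic LFC
    density_modifier: np.ndarray | None = None
    density_modifier_stratum: str = "low"
    neighbor_effect: np.ndarray | None = None
    cell_radius: float = 6.0
    neighbor_dilation: float = 8.0
    density_gradient: float = 1.0  # 0 → uniform; 1 → strong left-sparse/right-dense
    seed: int = 0

    def _matrix(self, m: np.ndarray | None) -> np.ndarray:
        shape = (self.n_perturbations, self.n_genes)
        if m is None:
            return np.zeros(shape)
        m = np.asarray(m, dtype=float)
        if m.shape != shape:
            raise SimulationError(f"effect matrix must have shape {shape}, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise SimulationError("planted effects must be finite")
        return m

    @property
    def n_cells(self) -> int:
        return self.n_perturbations * self.cells_per_perturbation + self.n_control_cells


@dataclass
class ScreenSim:
    counts: "pd.DataFrame"
    design: "object"  # cells.DesignMatrix
    positions: pd.DataFrame
    mask: LabelMask
    graph: NeighborGraph
    true_effects: np.ndarray
    true_density_modifier: np.ndarray
    true_neighbor_effect: np.ndarray
    density_class: pd.Series
    perturbation_names: list[str]
    gene_names: list[str]


def _gradient_positions(
    rng: np.random.Generator, n: int, cell_radius: float, gradient: float
) -> tuple[np.ndarray, tuple[int, int]]:
    """Jittered grid with column spacing that shrinks left → right.

    Produces one contiguous field holding both a sparse region (isolated,
    low-density cells) and a dense region (contact clusters), emulating the
    spontaneous density variation of cultured monolayers.  ``gradient`` = 0
    gives a uniform sparse grid.
    """
    sep_max = 6.0 * cell_radius
    sep_min = 2.6 * cell_radius

    def lay_out(side: float) -> list[tuple[float, float]]:
        pts = []
        x = sep_max / 2
        while x < side - cell_radius:
            s = sep_max - gradient * (sep_max - sep_min) * (x / side)
            y = s / 2
            while y < side - cell_radius:
                jx = rng.uniform(-0.12, 0.12) * s
                jy = rng.uniform(-0.12, 0.12) * s
                pts.append((x + jx, y + jy))
                y += s
            x += s
        return pts

    side = np.sqrt(n) * (sep_max + sep_min) / 2
    pts = lay_out(side)
    for _ in range(6):
        if len(pts) >= n:
            break
        side *= np.sqrt(max(n / max(len(pts), 1), 1.1))
        pts = lay_out(side)
    if len(pts) < n:
        raise SimulationError(f"placement failure: placed {len(pts)}/{n} cells")
    keep = rng.choice(len(pts), size=n, replace=False)
    arr = np.asarray(pts)[np.sort(keep)]
    dim = int(np.ceil(side)) + int(np.ceil(cell_radius)) + 2
    return arr, (dim, dim)


def _disc_mask(shape: tuple[int, int], pts: np.ndarray, radius: float) -> LabelMask:
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    r = int(np.ceil(radius))
    for k, (x, y) in enumerate(pts, start=1):
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        ys = slice(max(y0 - r, 0), min(y0 + r + 1, h))
        xs = slice(max(x0 - r, 0), min(x0 + r + 1, w))
        yy, xx = np.mgrid[ys, xs]
        inside = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
        labels[ys, xs][inside] = k
    return LabelMask(labels)


def simulate_screen(config: ScreenSimConfig) -> ScreenSim:
    """Simulate counts/design/mask with planted effects of all three kinds.

    Cell order is shuffled before assignment so that perturbations are
    spatially interleaved; neighbor contact uses the same dilation rule as
    :func:`pfish.cells.build_neighbor_graph`.
    """
    rng = np.random.default_rng(config.seed)
    from .cells import DesignMatrix  # local import to avoid cycle at module load

    n = config.n_cells
    P, Gn = config.n_perturbations, config.n_genes
    effects = config._matrix(config.effects)
    dens_mod = config._matrix(config.density_modifier)
    nbr = config._matrix(config.neighbor_effect)

    pts, shape = _gradient_positions(rng, n, config.cell_radius, config.density_gradient)
    mask = _disc_mask(shape, pts, config.cell_radius)
    graph = build_neighbor_graph(mask, config.neighbor_dilation)
    density = graph.density_class()

    pert_names = [f"pert_{i + 1:02d}" for i in range(P)]
    gene_names = [f"gene_{i + 1:03d}" for i in range(Gn)]
    # assignment: -1 = control, else perturbation index; shuffled over space
    assign_vec = np.full(n, -1, dtype=int)
    labels_pool = np.repeat(np.arange(P), config.cells_per_perturbation)
    order = rng.permutation(n)
    assign_vec[order[: labels_pool.size]] = labels_pool

    if config.baseline_mean is None:
        baseline = np.exp(rng.normal(np.log(5.0), 0.8, size=Gn))
    else:
        baseline = np.broadcast_to(
            np.asarray(config.baseline_mean, dtype=float), (Gn,)
        ).copy()

    log_mu = np.tile(np.log(baseline), (n, 1))
    dens_arr = density.to_numpy()
    for c in range(n):
        p = assign_vec[c]
        if p >= 0:
            log_mu[c] += effects[p]
            if dens_arr[c] == config.density_modifier_stratum:
                log_mu[c] += dens_mod[p]
    # neighbor-transmitted effects: once per distinct perturbed-neighbor
    # identity (a second neighbor with the same perturbation adds nothing)
    for c in range(n):
        exposed_to = {
            assign_vec[nb_cell - 1]
            for nb_cell in graph.neighbors_of(c + 1)
            if assign_vec[nb_cell - 1] >= 0
        }
        for p in exposed_to:
            log_mu[c] += nbr[p]
    mu = np.exp(log_mu)

    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    cell_ids = np.arange(1, n + 1)
    counts_df = pd.DataFrame(counts, index=cell_ids, columns=gene_names)

    assign_df = pd.DataFrame(0, index=cell_ids, columns=pert_names, dtype=int)
    for c in range(n):
        if assign_vec[c] >= 0:
            assign_df.iloc[c, assign_vec[c]] = 1
    is_control = pd.Series(assign_vec == -1, index=cell_ids)
    n_guides = pd.Series(1, index=cell_ids)
    design = DesignMatrix(assign_df, is_control, n_guides)

    positions = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]}, index=cell_ids)
    return ScreenSim(
        counts_df,
        design,
        positions,
        mask,
        graph,
        effects,
        dens_mod,
        nbr,
        density,
        pert_names,
        gene_names,
    )


def sparse_effect_matrix(
    n_perturbations: int,
    n_genes: int,
    frac_nonzero: float = 0.1,
    magnitude_range: tuple[float, float] = (0.3, 1.5),
    seed: int = 0,
) -> np.ndarray:
    """Random sparse LFC matrix: ``frac_nonzero`` entries drawn uniformly
    from ±[lo, hi], the rest exactly zero."""
    rng = np.random.default_rng(seed)
    m = np.zeros((n_perturbations, n_genes))
    nz = rng.random((n_perturbations, n_genes)) < frac_nonzero
    lo, hi = magnitude_range
    mags = rng.uniform(lo, hi, size=nz.sum())
    signs = rng.choice([-1.0, 1.0], size=nz.sum())
    m[nz] = mags * signs
    return m


# --------------------------------------------------------------------------
# calcium


@dataclass
class CalciumSimConfig:
    """Mixture of the six canonical calcium-response archetypes."""

    n_cells: int = 600
    n_frames: int = 200
    frame_rate: float = 2.0
    noise_sigma: float = 2.0
    proportions: np.ndarray | None = None  # defaults to equal sixths
    jitter_frames: float = 3.0  # onset timing jitter (sd, frames)
    amplitude_jitter: float = 0.1
    seed: int = 0

    def mixture(self) -> np.ndarray:
        if self.proportions is None:
            k = len(_calcium.ARCHETYPES)
            return np.full(k, 1.0 / k)
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (len(_calcium.ARCHETYPES),) or not np.isclose(p.sum(), 1.0):
            raise SimulationError("proportions must be a length-6 simplex vector")
        return p


def simulate_calcium(config: CalciumSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell traces from the archetype mixture.

    Returns ``(traces, labels)`` with traces shaped (n_cells, n_frames)
    and integer labels indexing :data:`pfish.calcium.ARCHETYPES`.
    Each trace is its archetype waveform with mild amplitude scaling and
    onset jitter, plus i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    k = len(_calcium.ARCHETYPES)
    labels = rng.choice(k, size=config.n_cells, p=config.mixture())
    base = {
        i: _calcium.archetype_waveform(name, config.n_frames)
        for i, name in enumerate(_calcium.ARCHETYPES)
    }
    traces = np.zeros((config.n_cells, config.n_frames))
    for c in range(config.n_cells):
        wf = base[labels[c]]
        shift = int(round(rng.normal(0, config.jitter_frames)))
        wf = np.roll(wf, shift)
        if shift > 0:
            wf = wf.copy()
            wf[:shift] = 0.0
        elif shift < 0:
            wf = wf.copy()
            wf[shift:] = 0.0
        scale = 1.0 + config.amplitude_jitter * rng.standard_normal()
        traces[c] = wf * max(scale, 0.5) + rng.normal(0, config.noise_sigma, config.n_frames)
    return traces, labels


def render_calcium_movie(
    traces: np.ndarray, mask: LabelMask, background: float = 0.0
) -> np.ndarray:
    """Paint per-cell traces into a (frames, H, W) movie over a label mask."""
    traces = np.asarray(traces, dtype=float)
    n = mask.n_cells
    if traces.shape[0] != n:
        raise SimulationError("one trace per mask label required")
    T = traces.shape[1]
    lut = np.zeros((T, n + 1))
    lut[:, 0] = background
    lut[:, 1:] = traces.T + background
    return lut[:, mask.labels]
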
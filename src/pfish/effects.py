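"""Perturbation-effect inference: naive log-fold changes with
permutation significance.

The estimator is deliberately simple and shrinkage-free: the effect of
perturbation p on gene g is the natural log of the ratio of the mean
expression of g over cells carrying p to its mean over control cells.
Significance comes from permuting the cell → perturbation assignment
(labels permuted jointly across genes), a two-sided add-one p-value, and
Benjamini-Hochberg adjustment pooled over the whole effect matrix;
effects with q < 0.1 are called significant.

Three modes share this core: intrinsic (all cells), density-stratified
(low/high contact-neighbor strata analyzed independently, each against
controls of the same stratum), and intercellular (expression of control
"receiver" cells as a function of which perturbations their contact
neighbors carry).

An external factorize-recover estimator can be plugged in through
:class:`ExternalEffectEstimator`; it is not re-implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cells import CountMatrix, DesignMatrix, NeighborGraph

__all__ = [
    "EffectTable",
    "EffectsError",
    "naive_lfc",
    "permutation_significance",
    "bh_adjust",
    "run_intrinsic",
    "density_stratified_effects",
    "intercellular_effects",
    "ExternalEffectEstimator",
    "run_external_estimator",
]

Q_SIGNIFICANT = 0.1
DEFAULT_EPS = 0.01


class EffectsError(ValueError):
    pass


@dataclass
class EffectTable:
    """Perturbations × genes natural-log fold changes with p and BH q."""

    lfc: pd.DataFrame
    p: pd.DataFrame | None
    q: pd.DataFrame | None
    n_cells: pd.Series
    mode: str = "intrinsic"
    normalization: str = "none"

    @property
    def significant(self) -> pd.DataFrame:
        if self.q is None:
            raise EffectsError("no q values: run the permutation test first")
        return self.q < Q_SIGNIFICANT

    def to_long(self) -> pd.DataFrame:
        out = self.lfc.stack().rename("lfc").reset_index()
        out.columns = ["perturbation", "gene", "lfc"]
        if self.p is not None:
            out["p"] = self.p.stack().to_numpy()
        if self.q is not None:
            out["q"] = self.q.stack().to_numpy()
        out["mode"] = self.mode
        out["n_cells"] = out["perturbation"].map(self.n_cells).to_numpy()
        return out


def _as_arrays(counts, design) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    """Extract (X, G, control) aligned arrays from the container types."""
    cdf = counts.counts if isinstance(counts, CountMatrix) else counts
    if isinstance(design, DesignMatrix):
        assign, ctrl = design.assign, design.is_control
    else:
        assign, ctrl = design
    assign = assign.loc[cdf.index]
    ctrl = ctrl.loc[cdf.index]
    return (
        cdf.to_numpy(dtype=float),
        assign.to_numpy(dtype=float),
        ctrl.to_numpy(dtype=bool),
        list(assign.columns),
        list(cdf.columns),
    )


def _normalize(X: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return X
    if how == "per10k":
        totals = X.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return X / totals * 1.0e4
    raise EffectsError(f"unknown normalization: {how!r}")


def _exclude_multi(G: np.ndarray, keep_multi: bool) -> np.ndarray:
    """Zero out assignment rows of cells carrying > 1 distinct guide."""
    if keep_multi:
        return G
    multi = G.sum(axis=1) > 1
    if multi.any():
        G = G.copy()
        G[multi] = 0.0
    return G


def _lfc_core(X: np.ndarray, G: np.ndarray, ctrl: np.ndarray, eps: float) -> np.ndarray:
    n_per = G.sum(axis=0)
    if not ctrl.any():
        raise EffectsError("no control cells")
    ctrl_mean = X[ctrl].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        means = (G.T @ X) / np.where(n_per == 0, np.nan, n_per)[:, None]
        return np.log((means + eps) / (ctrl_mean[None, :] + eps))


def naive_lfc(
    counts,
    design,
    normalization: str = "none",
    eps: float = DEFAULT_EPS,
    keep_multi_guide: bool = False,
) -> pd.DataFrame:
    """LFC[p, g] = ln((mean_g over cells with p + ε) / (mean_g over controls + ε)).

    ``normalization='per10k'`` rescales each cell to 10,000 total counts
    first.  ε guards against zero group means; ε = 0 is allowed when all
    means are positive.
    """
    X, G, ctrl, perts, genes = _as_arrays(counts, design)
    X = _normalize(X, normalization)
    G = _exclude_multi(G, keep_multi_guide)
    lfc = _lfc_core(X, G, ctrl, eps)
    return pd.DataFrame(lfc, index=perts, columns=genes)


def permutation_significance(
    counts,
    design,
    n_perm: int = 10000,
    seed: int = 0,
    normalization: str = "none",
    eps: float = DEFAULT_EPS,
    keep_multi_guide: bool = False,
) -> pd.DataFrame:
    """Two-sided permutation p-values for the naive LFC matrix.

    The cell → assignment labels are permuted jointly across genes
    (one shuffle per permutation, shared by every gene), and
    ``p = (1 + #{|LFC_perm| ≥ |LFC_obs|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise EffectsError("n_perm must be at least 1")
    X, G, ctrl, perts, genes = _as_arrays(counts, design)
    X = _normalize(X, normalization)
    G = _exclude_multi(G, keep_multi_guide)
    obs = np.abs(_lfc_core(X, G, ctrl, eps))
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs, dtype=np.int64)
    n = X.shape[0]
    for _ in range(n_perm):
        idx = rng.permutation(n)
        perm = np.abs(_lfc_core(X[idx], G, ctrl, eps))
        exceed += (perm >= obs - 1e-12).astype(np.int64)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[np.isnan(obs)] = np.nan  # perturbations with no cells are untestable
    return pd.DataFrame(p, index=perts, columns=genes)


def bh_adjust(p: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Benjamini-Hochberg step-up, pooled over all entries jointly."""
    arr = p.to_numpy() if isinstance(p, pd.DataFrame) else np.asarray(p)
    flat = arr.astype(float).ravel()
    finite = ~np.isnan(flat)
    if np.any((flat[finite] < 0) | (flat[finite] > 1)):
        raise EffectsError("p-values must lie in [0, 1]")
    qflat = np.full_like(flat, np.nan)
    if finite.any():
        qflat[finite] = multipletests(flat[finite], method="fdr_bh")[1]
    q = qflat.reshape(arr.shape)
    if isinstance(p, pd.DataFrame):
        return pd.DataFrame(q, index=p.index, columns=p.columns)
    return q


def run_intrinsic(
    counts,
    design,
    n_perm: int = 10000,
    seed: int = 0,
    normalization: str = "none",
    eps: float = DEFAULT_EPS,
    keep_multi_guide: bool = False,
    mode: str = "intrinsic",
) -> EffectTable:
    """Full pipeline: naive LFC + permutation p + BH q."""
    X, G, ctrl, perts, genes = _as_arrays(counts, design)
    G2 = _exclude_multi(G, keep_multi_guide)
    lfc = naive_lfc(counts, design, normalization, eps, keep_multi_guide)
    p = permutation_significance(
        counts, design, n_perm, seed, normalization, eps, keep_multi_guide
    )
    q = bh_adjust(p)
    n_cells = pd.Series(G2.sum(axis=0).astype(int), index=perts)
    return EffectTable(lfc, p, q, n_cells, mode=mode, normalization=normalization)


def _subset(counts, design, keep_mask: np.ndarray):
    cdf = counts.counts if isinstance(counts, CountMatrix) else counts
    if isinstance(design, DesignMatrix):
        assign, ctrl, ng = design.assign, design.is_control, design.n_guides
    else:
        assign, ctrl = design
        ng = assign.sum(axis=1)
    idx = cdf.index[keep_mask]
    sub_counts = cdf.loc[idx]
    sub_design = DesignMatrix(assign.loc[idx], ctrl.loc[idx], ng.loc[idx])
    return sub_counts, sub_design


def density_stratified_effects(
    counts,
    design,
    graph: NeighborGraph,
    n_perm: int = 10000,
    seed: int = 0,
    **kwargs,
) -> tuple[EffectTable | None, EffectTable | None]:
    """Run the full pipeline independently in low- and high-density strata.

    Each stratum is analyzed against control cells of the same stratum
    (expression relative to controls at matching density).  A stratum with
    no cells or no controls is skipped with a warning.
    """
    cdf = counts.counts if isinstance(counts, CountMatrix) else counts
    density = graph.density_class().reindex(cdf.index)
    if density.isna().any():
        raise EffectsError("neighbor graph does not cover all cells in the counts")
    out: list[EffectTable | None] = []
    for stratum in ("low", "high"):
        keep = (density == stratum).to_numpy()
        if not keep.any():
            warnings.warn(f"{stratum}-density stratum is empty; skipped")
            out.append(None)
            continue
        sub_counts, sub_design = _subset(counts, design, keep)
        if not sub_design.is_control.any():
            warnings.warn(f"{stratum}-density stratum has no control cells; skipped")
            out.append(None)
            continue
        out.append(
            run_intrinsic(
                sub_counts,
                sub_design,
                n_perm=n_perm,
                seed=seed,
                mode=f"{stratum}_density",
                **kwargs,
            )
        )
    return out[0], out[1]


def exposure_matrix(
    design: DesignMatrix, graph: NeighborGraph, receivers: pd.Index
) -> pd.DataFrame:
    """Receiver × perturbation indicator: ≥ 1 contact neighbor carries P."""
    perts = list(design.assign.columns)
    cell_ids = list(design.assign.index)
    pos = {c: i for i, c in enumerate(cell_ids)}
    A = design.assign.to_numpy()
    E = np.zeros((len(receivers), len(perts)), dtype=int)
    for r, cell in enumerate(receivers):
        for nb in graph.neighbors_of(int(cell)):
            if nb in pos:
                E[r] |= A[pos[nb]].astype(int)
    return pd.DataFrame(E, index=receivers, columns=perts)


def intercellular_effects(
    counts,
    design,
    graph: NeighborGraph,
    n_perm: int = 10000,
    seed: int = 0,
    receivers: pd.Index | None = None,
    normalization: str = "none",
    eps: float = DEFAULT_EPS,
) -> EffectTable:
    """Effects of a perturbed neighbor on an unperturbed receiver cell.

    Receivers default to control-guide cells.  A receiver is "exposed to
    P" iff at least one of its contact neighbors carries P (a receiver
    with neighbors carrying P and Q contributes to both exposure groups).
    The reference group is receivers none of whose neighbors carry a known
    perturbation (neighbors with control guides or no decoded guide are
    allowed).  Permutation shuffles the receiver → exposure labels.
    """
    cdf = counts.counts if isinstance(counts, CountMatrix) else counts
    if not isinstance(design, DesignMatrix):
        raise EffectsError("intercellular analysis needs a DesignMatrix")
    if receivers is None:
        receivers = design.is_control[design.is_control].index
    receivers = pd.Index(receivers)
    receivers = receivers.intersection(cdf.index)
    if len(receivers) == 0:
        raise EffectsError("no receiver cells")

    E = exposure_matrix(design, graph, receivers)
    reference = E.sum(axis=1) == 0
    if not reference.any():
        raise EffectsError("empty reference group: every receiver has a perturbed neighbor")
    if (E.sum(axis=0) == 0).all():
        return EffectTable(
            pd.DataFrame(index=E.columns, columns=cdf.columns, dtype=float),
            None,
            None,
            pd.Series(0, index=E.columns),
            mode="intercellular",
            normalization=normalization,
        )

    X = _normalize(cdf.loc[receivers].to_numpy(dtype=float), normalization)
    G = E.to_numpy(dtype=float)
    ctrl = reference.to_numpy()
    lfc = _lfc_core(X, G, ctrl, eps)
    rng = np.random.default_rng(seed)
    obs = np.abs(lfc)
    exceed = np.zeros_like(obs, dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.permutation(X.shape[0])
        perm = np.abs(_lfc_core(X[idx], G, ctrl, eps))
        exceed += (perm >= obs - 1e-12).astype(np.int64)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p[np.isnan(obs)] = np.nan
    pdf = pd.DataFrame(p, index=E.columns, columns=cdf.columns)
    lfcdf = pd.DataFrame(lfc, index=E.columns, columns=cdf.columns)
    return EffectTable(
        lfcdf,
        pdf,
        bh_adjust(pdf),
        pd.Series(E.sum(axis=0).astype(int), index=E.columns),
        mode="intercellular",
        normalization=normalization,
    )


@runtime_checkable
class ExternalEffectEstimator(Protocol):
    """Adapter for external effect estimators (e.g. factorize-recover tools).

    Implementations take a counts table and a design and return
    ``(lfc, q)`` DataFrames shaped perturbations × genes.
    """

    def __call__(
        self, counts: pd.DataFrame, design: DesignMatrix
    ) -> tuple[pd.DataFrame, pd.DataFrame]: ...


def run_external_estimator(
    estimator: ExternalEffectEstimator, counts, design: DesignMatrix
) -> EffectTable:
    cdf = counts.counts if isinstance(counts, CountMatrix) else counts
    lfc, q = estimator(cdf, design)
    n_cells = pd.Series(design.assign.sum(axis=0).astype(int), index=lfc.index)
    return EffectTable(lfc, None, q, n_cells, mode="external")
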
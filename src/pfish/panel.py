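"""Iterative PCA-residual selection of a MERFISH-compatible gene panel.

Imaging spatial transcriptomics can only multiplex a limited total
transcript abundance before optical crowding defeats decoding, so the
panel is built under two abundance caps: total expression across selected
genes below 2000 FPKM and no individual gene above 30 FPKM.  Selection
aims to preserve the major directions of variation of a reference
expression matrix: after a one-time PCA on the raw counts, the panel
grows two genes at a time, always targeting the principal component whose
scores are currently worst predicted (lowest R²) from the panel-restricted
matrix, and adding the eligible genes most correlated with that
component's regression residual.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PanelSelection", "PanelError", "select_panel", "evaluate_panel"]

TOTAL_FPKM_CAP = 2000.0
PER_GENE_FPKM_CAP = 30.0
GENES_PER_ITERATION = 2


class PanelError(ValueError):
    pass


@dataclass
class PanelSelection:
    """Ordered gene panel with the per-iteration selection log."""

    genes: list[str]
    log: list[dict]  # iteration, target_pc, added, explained_variance
    total_fpkm: float
    total_fpkm_cap: float = TOTAL_FPKM_CAP
    per_gene_fpkm_cap: float = PER_GENE_FPKM_CAP

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self.log:
            for g in entry["added"]:
                rows.append(
                    {
                        "gene": g,
                        "iteration": entry["iteration"],
                        "target_pc": entry["target_pc"],
                    }
                )
        return pd.DataFrame(rows)


def _pc_scores(X: np.ndarray, n_components: int) -> np.ndarray:
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(X)


def _regress(scores: np.ndarray, Xp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of each PC score vector on the panel matrix
    (with intercept); returns (residuals, per-PC R²)."""
    design = np.column_stack([Xp, np.ones(Xp.shape[0])])
    coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
    fitted = design @ coef
    resid = scores - fitted
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((scores - scores.mean(axis=0)) ** 2).sum(axis=0)
    ss_tot = np.where(ss_tot == 0, 1.0, ss_tot)
    return resid, 1.0 - ss_res / ss_tot


def _abs_corr(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """|Pearson correlation| of each column of X with v (0 when degenerate)."""
    Xc = X - X.mean(axis=0)
    vc = v - v.mean()
    num = Xc.T @ vc
    den = np.sqrt((Xc**2).sum(axis=0) * (vc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.abs(r)


def select_panel(
    counts: pd.DataFrame,
    fpkm: pd.Series,
    panel_size: int,
    n_components: int = 10,
    total_fpkm_cap: float = TOTAL_FPKM_CAP,
    per_gene_fpkm_cap: float = PER_GENE_FPKM_CAP,
    genes_per_iteration: int = GENES_PER_ITERATION,
) -> PanelSelection:
    """Grow a gene panel by iterative PCA-residual optimization.

    The seed pair is the two eligible genes most correlated with PC1's
    scores.  Each iteration targets the PC with the lowest explained
    variance (R² of predicting its full-data scores from the current
    panel) and adds the ``genes_per_iteration`` eligible genes most
    correlated (absolute Pearson, raw counts) with that PC's residual,
    skipping genes that would break the total-FPKM cap.  Stops at
    ``panel_size`` or, with a warning, when no eligible gene remains.
    """
    if n_components < 1:
        raise PanelError("n_components must be at least 1")
    fpkm = fpkm.reindex(counts.columns)
    if fpkm.isna().any():
        raise PanelError("fpkm must cover every gene in the count matrix")
    eligible = set(counts.columns[fpkm <= per_gene_fpkm_cap])
    if panel_size > len(eligible):
        raise PanelError(
            f"panel_size {panel_size} exceeds the {len(eligible)} genes under "
            f"the {per_gene_fpkm_cap} FPKM cap"
        )
    X = counts.to_numpy(dtype=float)
    genes = list(counts.columns)
    col = {g: i for i, g in enumerate(genes)}
    n_components = min(n_components, min(X.shape) - 1)
    scores = _pc_scores(X, n_components)

    def pick(rank_values: np.ndarray, selected: list[str], total: float) -> list[str]:
        order = np.argsort(-rank_values)
        out = []
        for gi in order:
            g = genes[gi]
            if g in selected or g in out or g not in eligible:
                continue
            if total + sum(fpkm[x] for x in out) + fpkm[g] > total_fpkm_cap:
                continue  # would break the total-abundance cap
            out.append(g)
            if len(out) == genes_per_iteration or len(selected) + len(out) == panel_size:
                break
        return out

    selected: list[str] = []
    log: list[dict] = []
    total = 0.0

    seed_rank = _abs_corr(X, scores[:, 0])
    added = pick(seed_rank, selected, total)
    if not added:
        raise PanelError("no eligible gene fits under the FPKM caps")
    selected += added
    total += float(sum(fpkm[g] for g in added))
    _, ev = _regress(scores, X[:, [col[g] for g in selected]])
    log.append(
        {"iteration": 0, "target_pc": 0, "added": added, "explained_variance": ev.copy()}
    )

    it = 0
    while len(selected) < panel_size:
        it += 1
        resid, ev = _regress(scores, X[:, [col[g] for g in selected]])
        worst = int(np.argmin(ev))
        if np.all(ev >= 1.0 - 1e-12):
            break  # panel already spans the PCA space
        rank = _abs_corr(X, resid[:, worst])
        added = pick(rank, selected, total)
        if not added:
            warnings.warn(
                f"FPKM caps reached: partial panel of {len(selected)} genes "
                f"(requested {panel_size})"
            )
            break
        selected += added
        total += float(sum(fpkm[g] for g in added))
        _, ev = _regress(scores, X[:, [col[g] for g in selected]])
        log.append(
            {
                "iteration": it,
                "target_pc": worst,
                "added": added,
                "explained_variance": ev.copy(),
            }
        )
    return PanelSelection(selected, log, total, total_fpkm_cap, per_gene_fpkm_cap)


def evaluate_panel(
    counts: pd.DataFrame, panel: list[str], n_components: int = 10
) -> np.ndarray:
    """Per-PC R² of predicting the full-data PC scores from the panel."""
    if not panel:
        raise PanelError("panel must be non-empty")
    missing = [g for g in panel if g not in counts.columns]
    if missing:
        raise PanelError(f"panel genes absent from the count matrix: {missing}")
    X = counts.to_numpy(dtype=float)
    n_components = min(n_components, min(X.shape) - 1)
    scores = _pc_scores(X, n_components)
    Xp = counts[panel].to_numpy(dtype=float)
    if Xp.shape[0] < Xp.shape[1] + 1:
        warnings.warn("rank warning: fewer cells than panel genes; least-squares "
                      "solution uses the pseudoinverse")
    _, ev = _regress(scores, Xp)
    return ev
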
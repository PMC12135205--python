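"""Calcium-trace extraction, featurization, phenotype clustering and
guide-enrichment testing.

Per-cell fluorescence traces (mean pixel value inside the registered cell
mask, baseline-subtracted) are reduced to seven features — number of
peaks, mean peak prominence, first-step size, first-response time,
average peak delay, area under the curve, and an active flag — z-scored,
and clustered with k-means into six response phenotypes.  Guide
composition per phenotype is tested against the control-cell distribution
with one-sided hypergeometric tests; cluster expression signatures are
mean z-scored expression with a per-gene one-way ANOVA.

Traces are NOT amplitude-normalized: the absolute height of the response
is informative.  Peak detection uses a minimum height of 15, a minimum
prominence of 6 and a minimum inter-peak spacing of 15 frames; when two
candidates violate the spacing, the higher one is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.signal import find_peaks
from sklearn.cluster import KMeans

from .cells import DesignMatrix, LabelMask

__all__ = [
    "TraceSet",
    "CalciumError",
    "ARCHETYPES",
    "archetype_waveform",
    "extract_traces",
    "detect_peaks",
    "featurize",
    "featurize_all",
    "cluster_phenotypes",
    "cluster_enrichment",
    "cluster_signatures",
    "PEAK_MIN_HEIGHT",
    "PEAK_MIN_PROMINENCE",
    "PEAK_MIN_SPACING",
]

PEAK_MIN_HEIGHT = 15.0
PEAK_MIN_PROMINENCE = 6.0
PEAK_MIN_SPACING = 15  # frames
DEFAULT_N_FRAMES = 200
DEFAULT_FRAME_RATE = 2.0  # Hz

FEATURE_NAMES = [
    "n_peaks",
    "mean_prominence",
    "first_step",
    "first_response_time",
    "mean_peak_delay",
    "auc",
    "active",
]

ARCHETYPES = (
    "large peak",
    "inactive",
    "large early transient",
    "small peak",
    "step",
    "delayed",
)


class CalciumError(ValueError):
    pass


@dataclass
class TraceSet:
    """Baseline-subtracted cells × frames fluorescence traces."""

    traces: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise CalciumError("traces must be a 2D cells × frames array")
        if not np.all(np.isfinite(self.traces)):
            raise CalciumError("traces contain non-finite values")
        if self.cell_ids is None:
            self.cell_ids = np.arange(1, self.traces.shape[0] + 1)

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


def archetype_waveform(name: str, n_frames: int = DEFAULT_N_FRAMES) -> np.ndarray:
    """Canonical noiseless waveform for one of the six response archetypes.

    Transients are difference-of-exponential pulses; the "step" is a
    sustained sigmoidal rise.  Amplitudes straddle the detection
    thresholds so that "inactive" genuinely produces no peak while
    "small peak" produces exactly one low-amplitude transient.
    """
    t = np.arange(n_frames, dtype=float)

    def pulse(t0: float, amp: float, rise: float, decay: float) -> np.ndarray:
        s = np.clip(t - t0, 0.0, None)
        w = (1.0 - np.exp(-s / rise)) * np.exp(-s / decay)
        w[t < t0] = 0.0
        peak = w.max()
        return amp * w / peak if peak > 0 else w

    if name == "inactive":
        return np.zeros(n_frames)
    if name == "large peak":
        return pulse(t0=30, amp=80.0, rise=4.0, decay=45.0)
    if name == "large early transient":
        return pulse(t0=6, amp=90.0, rise=2.0, decay=12.0)
    if name == "small peak":
        return pulse(t0=30, amp=25.0, rise=4.0, decay=30.0)
    if name == "step":
        return 40.0 / (1.0 + np.exp(-(t - 25.0) / 4.0))
    if name == "delayed":
        return pulse(t0=140, amp=60.0, rise=4.0, decay=30.0)
    raise CalciumError(f"unknown archetype: {name!r}")


def _rolling_median(trace: np.ndarray, window: int = 10) -> np.ndarray:
    return pd.Series(trace).rolling(window, min_periods=1, center=True).median().to_numpy()


def extract_traces(movie: np.ndarray, mask: LabelMask) -> TraceSet:
    """Per-frame mean intensity inside each cell label, baseline-subtracted.

    The baseline is the per-trace minimum of a 10-frame rolling median
    (robust to single-frame dips); it is subtracted so every trace's
    quiescent level sits at 0.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise CalciumError("movie must be a (frames, H, W) stack")
    if movie.shape[1:] != mask.labels.shape:
        raise CalciumError("movie frames and mask dimensions disagree")
    n = mask.n_cells
    areas = mask.areas()
    if (areas == 0).any():
        empty = areas.index[areas == 0].tolist()
        raise CalciumError(f"labels with 0 pixels: {empty}")
    flat_labels = mask.labels.ravel()
    T = movie.shape[0]
    sums = np.zeros((T, n + 1))
    for f in range(T):
        sums[f] = np.bincount(flat_labels, weights=movie[f].ravel(), minlength=n + 1)
    traces = (sums[:, 1:] / areas.to_numpy()[None, :]).T  # cells × frames
    baseline = np.array([_rolling_median(tr).min() for tr in traces])
    return TraceSet(traces - baseline[:, None])


def detect_peaks(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Peak frames (0-based) and prominences under the standard thresholds."""
    trace = np.asarray(trace, dtype=float)
    idx, props = find_peaks(
        trace,
        height=PEAK_MIN_HEIGHT,
        prominence=PEAK_MIN_PROMINENCE,
        distance=PEAK_MIN_SPACING,
    )
    return idx, props["prominences"]


def featurize(trace: np.ndarray, peaks: np.ndarray | None = None,
              prominences: np.ndarray | None = None) -> dict:
    """Seven-feature parametrization of one baseline-subtracted trace.

    ``first_step`` = max of frames 5–15 minus min of frames 1–10
    (1-based windows); ``first_response_time`` is the 1-based frame of
    the first peak, or the trace length when no peak was detected;
    ``mean_peak_delay`` is the mean inter-peak interval (0 with a single
    peak, trace length with none); ``auc`` is the trapezoidal area of
    the non-negative part of the trace.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    if peaks is None or prominences is None:
        peaks, prominences = detect_peaks(trace)
    n_peaks = int(len(peaks))
    first_step = float(np.max(trace[4:15]) - np.min(trace[0:10]))
    if n_peaks == 0:
        first_response = float(n)
        mean_delay = float(n)
    else:
        first_response = float(peaks[0] + 1)
        mean_delay = float(np.mean(np.diff(peaks))) if n_peaks > 1 else 0.0
    return {
        "n_peaks": n_peaks,
        "mean_prominence": float(np.mean(prominences)) if n_peaks else 0.0,
        "first_step": first_step,
        "first_response_time": first_response,
        "mean_peak_delay": mean_delay,
        "auc": float(np.trapezoid(np.clip(trace, 0.0, None))),
        "active": int(n_peaks >= 1),
    }


def featurize_all(traces: TraceSet | np.ndarray) -> pd.DataFrame:
    arr = traces.traces if isinstance(traces, TraceSet) else np.asarray(traces, float)
    ids = traces.cell_ids if isinstance(traces, TraceSet) else np.arange(1, len(arr) + 1)
    rows = [featurize(tr) for tr in arr]
    return pd.DataFrame(rows, index=ids, columns=FEATURE_NAMES)


def _zscore(F: np.ndarray) -> np.ndarray:
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (F - mu) / sd


def cluster_phenotypes(
    features: pd.DataFrame, k: int = 6, seed: int = 0
) -> tuple[pd.Series, dict[int, str]]:
    """Z-score the features and k-means the cells into k response groups.

    Returns per-cell integer labels and a best-effort cluster → name map
    obtained by Hungarian matching of the cluster centroids to the
    featurized canonical archetypes (only when k equals the archetype
    count; otherwise clusters are named ``cluster_<i>``).
    """
    F = features[FEATURE_NAMES].to_numpy(dtype=float)
    if F.shape[0] < k:
        raise CalciumError(f"need at least {k} cells, got {F.shape[0]}")
    if np.allclose(F, F[0]):
        warnings.warn("degenerate clustering: all cells identical in feature space")
        labels = pd.Series(0, index=features.index, name="cluster")
        return labels, {0: "cluster_0"}
    mu, sd = F.mean(axis=0), F.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (F - mu) / sd
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    labels = pd.Series(km.labels_, index=features.index, name="cluster")

    names: dict[int, str] = {c: f"cluster_{c}" for c in range(k)}
    if k == len(ARCHETYPES):
        # archetype signatures in the data's z-score coordinates
        ref_rows = []
        for name in ARCHETYPES:
            wf = archetype_waveform(name)
            ref_rows.append([featurize(wf)[f] for f in FEATURE_NAMES])
        ref = (np.asarray(ref_rows) - mu) / sd
        cost = np.linalg.norm(km.cluster_centers_[:, None, :] - ref[None, :, :], axis=2)
        rows, cols = linear_sum_assignment(cost)
        names = {int(r): ARCHETYPES[c] for r, c in zip(rows, cols)}
    return labels, names


def cluster_enrichment(
    labels: pd.Series,
    guide_of_cell: pd.Series,
    control_ids: set[str] | None = None,
    design: DesignMatrix | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment/depletion of each guide in each cluster.

    For guide A and cluster B with x = A-cells in B, M = total cells,
    K = cells in B, N = A-cells: ``p_enrich = P(X ≥ x)`` (the upper
    hypergeometric tail, ``1 - hygecdf(x-1, M, K, N)``) and
    ``p_deplete = P(X ≤ x)``.  The enrichment LFC is
    ``ln((x/N) / (K_ctrl/N_ctrl))`` against the control cells'
    distribution over clusters; clusters containing no control cells are
    flagged and carry no LFC.
    """
    if design is not None and guide_of_cell is None:
        raise CalciumError("pass either guide_of_cell or design, not both")
    labels = labels.reindex(guide_of_cell.index)
    if labels.isna().any():
        raise CalciumError("every cell needs a cluster label")
    control_ids = control_ids or set()
    M = int(len(labels))
    is_ctrl = guide_of_cell.isin(control_ids)
    n_ctrl = int(is_ctrl.sum())
    if n_ctrl == 0:
        raise CalciumError("no control cells: expected cluster distribution undefined")

    records = []
    for cluster in sorted(labels.unique()):
        in_b = labels == cluster
        K = int(in_b.sum())
        k_ctrl = int((in_b & is_ctrl).sum())
        for guide in sorted(guide_of_cell.dropna().unique()):
            mine = guide_of_cell == guide
            N = int(mine.sum())
            x = int((mine & in_b).sum())
            p_enr = float(stats.hypergeom.sf(x - 1, M, K, N))
            p_dep = float(stats.hypergeom.cdf(x, M, K, N))
            if k_ctrl == 0:
                lfc = np.nan
                flagged = True
            else:
                expected = k_ctrl / n_ctrl
                with np.errstate(divide="ignore"):
                    lfc = float(np.log((x / N) / expected)) if N else np.nan
                flagged = False
            records.append(
                {
                    "guide": guide,
                    "cluster": cluster,
                    "x": x,
                    "M": M,
                    "K": K,
                    "N": N,
                    "lfc": lfc,
                    "p_enrich": p_enr,
                    "p_deplete": p_dep,
                    "no_control_reference": flagged,
                }
            )
    return pd.DataFrame(records)


def cluster_signatures(
    counts: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-cluster mean z-scored (total-normalized) expression + ANOVA p.

    Counts are normalized to each cell's total, z-scored per gene over
    all cells, and averaged within clusters.  Per-gene significance is a
    one-way ANOVA across clusters on the raw expression values.
    """
    labels = labels.reindex(counts.index)
    if labels.isna().any():
        raise CalciumError("labels must cover every cell in the count matrix")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise CalciumError("ANOVA undefined with a single cluster")
    totals = counts.sum(axis=1).to_numpy(float)
    totals[totals == 0] = 1.0
    norm = counts.to_numpy(float) / totals[:, None]
    mu = norm.mean(axis=0)
    sd = norm.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (norm - mu) / sd

    sig = np.zeros((len(clusters), counts.shape[1]))
    raw = counts.to_numpy(float)
    pvals = np.ones(counts.shape[1])
    groups_idx = [np.flatnonzero((labels == c).to_numpy()) for c in clusters]
    for ci, idx in enumerate(groups_idx):
        sig[ci] = z[idx].mean(axis=0)
    for g in range(counts.shape[1]):
        samples = [raw[idx, g] for idx in groups_idx]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples if len(s)}) == 1:
            pvals[g] = 1.0
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pvals[g] = stats.f_oneway(*samples).pvalue
    signatures = pd.DataFrame(sig, index=clusters, columns=counts.columns)
    return signatures, pd.Series(pvals, index=counts.columns, name="anova_p")
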
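"""Series cleaning and multivariate distance-correlation networks.

Edges between ROVs are estimated with distance correlation over the full
multi-voxel pattern rather than a mean series: observations (trials of a
beta-series, or time points of a resting series) are treated as points in
voxel space, pairwise Euclidean distance matrices are U-centered with the
unbiased Szekely-Rizzo estimator, and dCor is formed from the resulting
distance covariance and variances. The unbiased squared distance
covariance can be negative; it is clipped at zero before the square root.

Resting series are cleaned before network construction: confound
regression (24 motion parameters + CSF + WM + global signal), zero-phase
bandpass (0.009-0.08 Hz at the acquisition TR), truncation to a common
length, and per-voxel z-normalization. Task beta-series receive
z-normalization only by default, since nuisance regression is part of the
first-level model that produced the betas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

log = logging.getLogger(__name__)

#: resting-state and task-state bandpass edges, Hz
REST_BAND = (0.009, 0.08)
TASK_BAND = (0.009, 0.25)


@dataclass
class ROISeriesSet:
    """Per-subject, per-ROV multi-voxel observation series.

    ``series[i][label]`` is a voxels x observations array for subject i:
    per-trial beta weights in the task state, BOLD samples in rest.
    """

    state: str  # "task" | "rest"
    series: list[dict[str, np.ndarray]]
    tr_seconds: float | None = None  # rest only

    def __post_init__(self):
        if self.state not in ("task", "rest"):
            raise ValueError(f"unknown state: {self.state}")
        for subj in self.series:
            n_obs = {arr.shape[1] for arr in subj.values()}
            if len(n_obs) > 1:
                raise ValueError("all ROVs of one subject must share observation count")
            if n_obs and min(n_obs) < 4:
                raise ValueError("need at least 4 observations per series")

    @property
    def labels(self) -> list[str]:
        return list(self.series[0].keys())

    @property
    def n_subjects(self) -> int:
        return len(self.series)


@dataclass
class FCNetwork:
    """One subject's K x K symmetric distance-correlation matrix."""

    state: str
    nodes: list[str]
    edges: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        k = len(self.nodes)
        if self.edges.shape != (k, k):
            raise ValueError("edge matrix shape must match node count")


def regress_confounds(series: np.ndarray, confounds: np.ndarray) -> np.ndarray:
    """Residualize each voxel series against the confound design.

    An intercept column is always included. Rank-deficient designs are
    repaired by dropping dependent columns (warned, not fatal).
    """
    y = np.asarray(series, dtype=float)
    conf = np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != y.shape[1]:
        raise ValueError("confound rows must align with observations")
    X = np.column_stack([np.ones(conf.shape[0]), conf])
    # a near-singular R diagonal flags dependent columns (drop-and-warn)
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0)
    if np.any(diag <= tol):
        keep = []
        rank = 0
        for j in range(X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > rank:
                keep.append(j)
                rank += 1
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        log.warning("regress_confounds: dropped dependent design columns %s", dropped)
        X = X[:, keep]
    # full-rank design: normal equations via Cholesky (fast for many voxels)
    beta = np.linalg.solve(X.T @ X, X.T @ y.T)
    return y - (X @ beta).T


def bandpass(
    series: np.ndarray,
    tr_seconds: float,
    f_min: float,
    f_max: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the observation axis."""
    y = np.asarray(series, dtype=float)
    nyquist = 0.5 / tr_seconds
    if not (0 < f_min < f_max < nyquist):
        raise ValueError("need 0 < f_min < f_max < Nyquist")
    sos = sps.butter(order, [f_min, f_max], btype="bandpass", fs=1.0 / tr_seconds, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if y.shape[-1] <= padlen:
        raise ValueError(f"series too short for filter warm-up (need > {padlen} observations)")
    return sps.sosfiltfilt(sos, y, axis=-1)


def truncate_rest(series: np.ndarray, n: int = 316) -> np.ndarray:
    """Keep the first n observations (scan-length matching across states)."""
    y = np.asarray(series)
    if y.shape[-1] < n:
        raise ValueError(f"series has {y.shape[-1]} observations, need >= {n}")
    return y[..., :n]


def znormalize(series: np.ndarray) -> np.ndarray:
    """Z-score each voxel's series (mean 0, sample SD 1 across observations).

    Zero-variance voxels are dropped with a warning; an all-constant ROV is
    an error since no pattern information remains.
    """
    y = np.asarray(series, dtype=float)
    mu = y.mean(axis=-1, keepdims=True)
    sd = y.std(axis=-1, ddof=1, keepdims=True)
    ok = sd.ravel() > 0
    if not ok.any():
        raise ValueError("all voxels have zero variance")
    if not ok.all():
        log.warning("znormalize: dropped %d zero-variance voxels", int((~ok).sum()))
        y, mu, sd = y[ok], mu[ok], sd[ok]
    return (y - mu) / sd


def observation_distances(series: np.ndarray) -> np.ndarray:
    """T x T Euclidean distances between observation columns of a voxels x T
    array, via the Gram-matrix identity (BLAS-backed)."""
    x = np.asarray(series, dtype=float)
    g = x.T @ x
    sq = np.diag(g)
    d2 = sq[:, None] + sq[None, :] - 2.0 * g
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.clip(d2, 0.0, None))


def u_centered(dist: np.ndarray) -> np.ndarray:
    """U-center a pairwise distance matrix (unbiased estimator; diag = 0)."""
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if n < 4:
        raise ValueError("U-centering needs at least 4 observations")
    row = d.sum(axis=1, keepdims=True) / (n - 2)
    col = d.sum(axis=0, keepdims=True) / (n - 2)
    total = d.sum() / ((n - 1) * (n - 2))
    out = d - row - col + total
    np.fill_diagonal(out, 0.0)
    return out


def u_inner(a: np.ndarray, b: np.ndarray) -> float:
    """Unbiased dCov^2 from two U-centered matrices: <A,B>/(n(n-3))."""
    n = a.shape[0]
    return float((a * b).sum() / (n * (n - 3)))


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Unbiased-estimator distance correlation between two voxel patterns.

    ``x`` and ``y`` are voxels x T arrays over the same T observations; the
    observations (columns) are the sample points. Returns 0 when either
    distance variance is nonpositive; the result is clipped to [0, 1].
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] != y.shape[1]:
        raise ValueError("x and y must share the observation count")
    if x.shape[1] < 4:
        raise ValueError("distance correlation needs at least 4 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    a = u_centered(observation_distances(x))
    b = u_centered(observation_distances(y))
    return _dcor_from_centered(a, b)


def _dcor_from_centered(a: np.ndarray, b: np.ndarray) -> float:
    dvar_x = u_inner(a, a)
    dvar_y = u_inner(b, b)
    if dvar_x <= 0 or dvar_y <= 0:
        return 0.0
    dcov2 = u_inner(a, b)
    return float(np.clip(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)), 0.0, 1.0))


#: the cleaning chain applied to rest series, in order
CLEANING_ORDER = ("bandpass", "regress_confounds", "truncate_rest", "znormalize")


def preprocess_series(
    series_set: ROISeriesSet,
    confounds: list[np.ndarray] | None = None,
    band: tuple[float, float] | None = None,
    n_truncate: int | None = None,
    clean_task: bool = False,
) -> ROISeriesSet:
    """Apply the cleaning chain (``CLEANING_ORDER``) and z-normalization.

    Rest series get the full chain; the confound design is band-filtered
    with the same zero-phase filter and regressed out of the filtered
    series, so the residuals are exactly orthogonal to the (filtered)
    confounds — sequentially regressing first and filtering afterwards
    would reintroduce confound variance at the band edges. Task
    beta-series receive z-normalization only, unless ``clean_task`` is set
    (then the full chain runs with the task band).
    """
    full_chain = series_set.state == "rest" or clean_task
    if band is None:
        band = REST_BAND if series_set.state == "rest" else TASK_BAND
    out: list[dict[str, np.ndarray]] = []
    for i, subj in enumerate(series_set.series):
        labels = list(subj.keys())
        if full_chain:
            # one stacked pass over all ROVs: the design is shared, so the
            # regression and filter run once per subject
            counts = [subj[lab].shape[0] for lab in labels]
            y = np.vstack([np.asarray(subj[lab], dtype=float) for lab in labels])
            if series_set.tr_seconds is not None:
                y = bandpass(y, series_set.tr_seconds, *band)
            if confounds is not None:
                conf = np.asarray(confounds[i], dtype=float)
                if series_set.tr_seconds is not None:
                    conf = bandpass(conf.T, series_set.tr_seconds, *band).T
                y = regress_confounds(y, conf)
            if n_truncate is not None:
                y = truncate_rest(y, n_truncate)
            parts = np.split(y, np.cumsum(counts)[:-1], axis=0)
            cleaned = {lab: znormalize(part) for lab, part in zip(labels, parts)}
        else:
            cleaned = {lab: znormalize(np.asarray(subj[lab], dtype=float)) for lab in labels}
        out.append(cleaned)
    return ROISeriesSet(state=series_set.state, series=out, tr_seconds=series_set.tr_seconds)


def build_fc_network(series_set: ROISeriesSet, nodes: list[str] | None = None) -> list[FCNetwork]:
    """Per-subject K x K distance-correlation network over the ROV nodes.

    Each of the K(K-1)/2 unordered node pairs is evaluated once on the
    U-centered distance matrices (computed once per ROV); the matrix is
    filled symmetrically with a zero diagonal.
    """
    if nodes is None:
        nodes = series_set.labels
    k = len(nodes)
    if k < 2:
        raise ValueError("need at least 2 nodes")
    nets: list[FCNetwork] = []
    for subj in series_set.series:
        centered = np.stack(
            [
                u_centered(observation_distances(np.asarray(subj[label], dtype=float)))
                for label in nodes
            ]
        )
        t = centered.shape[1]
        # all K(K-1)/2 unbiased dCov^2 values in one Gram product
        flat = centered.reshape(k, -1)
        cov = (flat @ flat.T) / (t * (t - 3))
        dvar = np.diag(cov).copy()
        edges = np.zeros((k, k))
        valid = dvar > 0
        denom = np.sqrt(np.outer(dvar, dvar), where=np.outer(valid, valid), out=np.zeros((k, k)))
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(denom > 0, np.clip(cov, 0.0, None) / denom, 0.0)
        edges = np.sqrt(np.clip(ratio, 0.0, 1.0))
        np.fill_diagonal(edges, 0.0)
        nets.append(FCNetwork(state=series_set.state, nodes=list(nodes), edges=edges))
    return nets


def edge_variability(task_nets: list[FCNetwork], rest_nets: list[FCNetwork]) -> dict:
    """Across-subject SD of each edge in both states, with a paired t-test.

    The K(K-1)/2 per-edge SD values of the two states are compared with a
    paired t-test (df = K(K-1)/2 - 1).
    """
    if task_nets[0].nodes != rest_nets[0].nodes:
        raise ValueError("task and rest networks must share the node set")
    if len(task_nets) != len(rest_nets):
        raise ValueError("task and rest networks must share the subject set")
    k = len(task_nets[0].nodes)
    iu = np.triu_indices(k, 1)
    task_edges = np.stack([n.edges[iu] for n in task_nets])
    rest_edges = np.stack([n.edges[iu] for n in rest_nets])
    sd_task = task_edges.std(axis=0, ddof=1)
    sd_rest = rest_edges.std(axis=0, ddof=1)
    if sd_task.size < 3:
        raise ValueError("need at least 3 edges")
    diffs = rest_edges.std(axis=0, ddof=1) - task_edges.std(axis=0, ddof=1)
    if np.allclose(diffs.std(ddof=1), 0.0):
        t_stat, p_value = (0.0, 1.0) if np.allclose(diffs, 0) else (np.nan, np.nan)
        note = "zero variance of SD differences; t undefined" if not np.allclose(diffs, 0) else None
    else:
        res = stats.ttest_rel(sd_rest, sd_task)
        t_stat, p_value, note = float(res.statistic), float(res.pvalue), None
    return {
        "sd_task": sd_task,
        "sd_rest": sd_rest,
        "mean_sd_task": float(sd_task.mean()),
        "mean_sd_rest": float(sd_rest.mean()),
        "t": t_stat,
        "df": sd_task.size - 1,
        "p": p_value,
        "note": note,
    }
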
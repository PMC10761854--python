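"""Connectome-based predictive modeling (CPM).

Leave-one-out cross-validation over subjects: on each training fold, every
unique network edge is correlated with the behavioral score, edges passing
p <= alpha are split by the sign of r into a positive and a negative mask,
a one-parameter linear model is fitted to each masked edge sum, and the
held-out subject's score is predicted from their own masked edge sum.
Model validity is the Pearson correlation between observed and predicted
scores; its significance comes from a permutation test that re-runs the
full LOOCV — including per-fold edge selection — on permuted scores.

Folds whose mask is empty (or whose edge sums are constant, leaving the
slope undefined) predict the training-mean score; a model fails outright
only when every fold lacked edges of its sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

log = logging.getLogger(__name__)


@dataclass
class CPMFold:
    """One LOOCV fold: selection masks, model coefficients, predictions."""

    held_out_subject: int
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    coef_pos: tuple[float, float] | None  # (slope, intercept)
    coef_neg: tuple[float, float] | None
    predicted_pos: float
    predicted_neg: float


@dataclass
class CPMResult:
    """LOOCV prediction outcome for the positive and negative models."""

    observed: np.ndarray
    predicted_pos: np.ndarray
    predicted_neg: np.ndarray
    r_positive: float | None
    r_negative: float | None
    status_pos: str  # "ok" | "failed_no_edges"
    status_neg: str
    folds: list[CPMFold] = field(default_factory=list)
    p_perm_positive: float | None = None
    p_perm_negative: float | None = None


def _edge_matrix(nets) -> tuple[np.ndarray, int, tuple]:
    """Stack networks into (n_subjects, n_edges) over the upper triangle.

    Accepts a list of FCNetwork, an (n, K, K) array, or an already-flat
    (n, K(K-1)/2) edge-row array.
    """
    if isinstance(nets, np.ndarray) and nets.ndim == 2:
        n_edges = nets.shape[1]
        k = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
        if k * (k - 1) // 2 != n_edges:
            raise ValueError("edge-row width is not K(K-1)/2 for integer K")
        return nets, k, np.triu_indices(k, 1)
    if isinstance(nets, np.ndarray) and nets.ndim == 3:
        mats = nets
    else:
        mats = np.stack([n.edges for n in nets])
    k = mats.shape[1]
    iu = np.triu_indices(k, 1)
    return mats[:, iu[0], iu[1]], k, iu


def _edge_correlations(edges: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided p of each edge column with the score vector.

    Zero-variance edges get r = 0, p = 1 (excluded from selection).
    """
    n = len(scores)
    xc = edges - edges.mean(axis=0)
    yc = scores - scores.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    denom = sx * sy
    ok = denom > 0
    r = np.zeros(edges.shape[1])
    r[ok] = (xc[:, ok] * yc[:, None]).sum(axis=0) / denom[ok]
    r = np.clip(r, -1.0, 1.0)
    p = np.ones_like(r)
    with np.errstate(divide="ignore"):
        t = np.abs(r[ok]) * np.sqrt((n - 2) / np.maximum(1.0 - r[ok] ** 2, 1e-300))
    p[ok] = 2.0 * special.stdtr(n - 2, -t)
    return r, p


def select_edges(train_nets, train_scores, alpha: float = 0.05):
    """Behaviorally relevant edges, split by correlation sign.

    Returns symmetric binary (pos_mask, neg_mask) K x K arrays; the masks
    are disjoint by construction and have zero diagonals.
    """
    edges, k, iu = _edge_matrix(train_nets)
    scores = np.asarray(train_scores, dtype=float)
    if len(scores) < 4:
        raise ValueError("need at least 4 training subjects")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    r, p = _edge_correlations(edges, scores)
    sig = p <= alpha
    pos = np.zeros((k, k), dtype=bool)
    neg = np.zeros((k, k), dtype=bool)
    pos[iu[0][sig & (r > 0)], iu[1][sig & (r > 0)]] = True
    neg[iu[0][sig & (r < 0)], iu[1][sig & (r < 0)]] = True
    pos |= pos.T
    neg |= neg.T
    return pos, neg


def _masked_edge_sum(edges: np.ndarray, mask: np.ndarray, iu) -> np.ndarray:
    """Sum of unique masked edges per subject (each unordered pair once)."""
    sel = mask[iu]
    return edges[:, sel].sum(axis=1)


def fit_models(train_nets, train_scores, masks) -> dict[str, tuple[float, float] | None]:
    """Ordinary least squares score ~ masked-edge sum for each model.

    Returns {"pos": (slope, intercept) | None, "neg": ...}; None marks a
    model that could not be fitted (empty mask or constant sums).
    """
    edges, k, iu = _edge_matrix(train_nets)
    scores = np.asarray(train_scores, dtype=float)
    out: dict[str, tuple[float, float] | None] = {}
    for name, mask in zip(("pos", "neg"), masks):
        if not mask.any():
            out[name] = None
            continue
        s = _masked_edge_sum(edges, np.asarray(mask, dtype=bool), iu)
        if np.ptp(s) == 0:
            log.info("fit_models: constant edge sums, %s model fold failed", name)
            out[name] = None
            continue
        slope, intercept = np.polyfit(s, scores, 1)
        out[name] = (float(slope), float(intercept))
    return out


def loocv_predict(nets, scores, alpha: float = 0.05, store_folds: bool = True) -> CPMResult:
    """Leave-one-out CPM prediction of each subject's score.

    Each fold runs edge selection and model fitting on the remaining
    subjects only, so the held-out subject never influences its own
    prediction. r_positive / r_negative are Pearson correlations between
    observed and predicted scores.
    """
    edges, k, iu = _edge_matrix(nets)
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 5:
        raise ValueError("need at least 5 subjects for LOOCV")
    if edges.shape[0] != n:
        raise ValueError("networks and scores must have matching subjects")

    pred_pos = np.empty(n)
    pred_neg = np.empty(n)
    any_pos = any_neg = False
    folds: list[CPMFold] = []
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        tr_edges = edges[tr]
        tr_scores = scores[tr]
        pos, neg = select_edges(tr_edges, tr_scores, alpha=alpha)
        coefs = fit_models(tr_edges, tr_scores, (pos, neg))
        fallback = float(tr_scores.mean())
        preds = {}
        for name, mask in (("pos", pos), ("neg", neg)):
            if coefs[name] is None:
                preds[name] = fallback
            else:
                slope, intercept = coefs[name]
                s_i = float(_masked_edge_sum(edges[i : i + 1], mask, iu)[0])
                preds[name] = slope * s_i + intercept
        if not np.isfinite(preds["pos"]) or not np.isfinite(preds["neg"]):
            raise FloatingPointError(f"non-finite prediction in fold {i}")
        pred_pos[i], pred_neg[i] = preds["pos"], preds["neg"]
        any_pos |= pos.any()
        any_neg |= neg.any()
        if store_folds:
            folds.append(
                CPMFold(
                    held_out_subject=i,
                    pos_mask=pos,
                    neg_mask=neg,
                    coef_pos=coefs["pos"],
                    coef_neg=coefs["neg"],
                    predicted_pos=preds["pos"],
                    predicted_neg=preds["neg"],
                )
            )

    def _r(pred: np.ndarray) -> float | None:
        if np.ptp(pred) == 0:
            return None
        return float(stats.pearsonr(scores, pred).statistic)

    return CPMResult(
        observed=scores,
        predicted_pos=pred_pos,
        predicted_neg=pred_neg,
        r_positive=_r(pred_pos) if any_pos else None,
        r_negative=_r(pred_neg) if any_neg else None,
        status_pos="ok" if any_pos else "failed_no_edges",
        status_neg="ok" if any_neg else "failed_no_edges",
        folds=folds,
    )


def edges_to_matrices(edge_rows: np.ndarray, k: int, iu) -> np.ndarray:
    """Rebuild symmetric (n, K, K) matrices from upper-triangle edge rows."""
    n = edge_rows.shape[0]
    mats = np.zeros((n, k, k))
    mats[:, iu[0], iu[1]] = edge_rows
    mats[:, iu[1], iu[0]] = edge_rows
    return mats


def permutation_test(
    nets,
    scores,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
    result: CPMResult | None = None,
) -> CPMResult:
    """Permutation significance of the LOOCV prediction performance.

    Scores are permuted across subjects and the full LOOCV (with per-fold
    edge selection) is re-run each time. The add-one estimator
    p = (1 + #{r_perm >= r_obs}) / (1 + n_perm) is applied to each model's
    own r; permutations where a model fails contribute r_perm = -inf
    (conservative). Returns the observed CPMResult with p values attached.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    if result is None:
        result = loocv_predict(nets, scores, alpha=alpha)
    perm_r_pos = np.full(n_perm, -np.inf)
    perm_r_neg = np.full(n_perm, -np.inf)
    for b in range(n_perm):
        perm = rng.permutation(len(scores))
        res_b = loocv_predict(nets, scores[perm], alpha=alpha, store_folds=False)
        if res_b.status_pos == "ok" and res_b.r_positive is not None:
            perm_r_pos[b] = res_b.r_positive
        if res_b.status_neg == "ok" and res_b.r_negative is not None:
            perm_r_neg[b] = res_b.r_negative
    if result.status_pos == "ok" and result.r_positive is not None:
        result.p_perm_positive = float(
            (1 + np.sum(perm_r_pos >= result.r_positive)) / (1 + n_perm)
        )
    if result.status_neg == "ok" and result.r_negative is not None:
        result.p_perm_negative = float(
            (1 + np.sum(perm_r_neg >= result.r_negative)) / (1 + n_perm)
        )
    return result


def report_contributing_network(result: CPMResult, nodes: list[str] | None = None, union: bool = False):
    """Edges selected into the positive mask in every fold (the network that
    consistently contributes to the prediction), as a ranked table.

    With ``union=True`` the union across folds is reported instead. Edges
    are ranked by the fraction of folds selecting them, then node order.
    """
    import pandas as pd

    if result.status_pos != "ok":
        raise ValueError("positive model did not run ok")
    if not result.folds:
        raise ValueError("result has no stored folds")
    k = result.folds[0].pos_mask.shape[0]
    iu = np.triu_indices(k, 1)
    freq = np.mean([f.pos_mask[iu] for f in result.folds], axis=0)
    keep = freq > 0 if union else freq >= 1.0
    if not keep.any():
        log.warning("report_contributing_network: empty intersection across folds")
    rows = []
    names = nodes if nodes is not None else [str(i) for i in range(k)]
    for e in np.flatnonzero(keep):
        rows.append(
            {
                "node_a": names[iu[0][e]],
                "node_b": names[iu[1][e]],
                "fold_fraction": float(freq[e]),
            }
        )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "fold_fraction"])
    return df.sort_values(["fold_fraction", "node_a", "node_b"], ascending=[False, True, True]).reset_index(
        drop=True
    )
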
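"""ROV marker extraction and brain-behavior correlation statistics.

Functional markers are mean contrast betas over each functional ROV's
voxels; anatomical markers are mean grey-matter volume over each
structural ROV. Scores are screened for outliers (|z| > 3, replaced by the
mean of the remaining values, with a normality statistic reported), then
correlated with each marker by Pearson correlation — partial correlation
when a brain-size covariate is supplied — with Bonferroni correction over
the marker-by-score family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rovnet.rov import ROV

log = logging.getLogger(__name__)


def extract_markers(volumes: list[np.ndarray], rovs: list[ROV]) -> pd.DataFrame:
    """Mean volume value over each ROV's member voxels, per subject."""
    rows = []
    for vol in volumes:
        vol = np.asarray(vol, dtype=float)
        row = {}
        for rov in rovs:
            ids = rov.voxel_ids
            if np.any(ids >= np.array(vol.shape)) or np.any(ids < 0):
                raise ValueError(f"ROV {rov.label!r} outside volume coverage")
            row[rov.label] = float(vol[tuple(ids.T)].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=[r.label for r in rovs])


@dataclass
class CleanReport:
    n_replaced: int
    shapiro_w: float
    shapiro_p: float


def clean_scores(scores, z_thresh: float = 3.0, max_outlier_frac: float = 0.2):
    """Replace outlying scores (|z| > z_thresh) by the mean of the rest.

    Normality is assessed (Shapiro-Wilk) and reported, not enforced. More
    than ``max_outlier_frac`` outliers aborts with diagnostics. Returns
    ``(cleaned, CleanReport)``.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 scores")
    w, p = stats.shapiro(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return x.copy(), CleanReport(0, float(w), float(p))
    z = (x - x.mean()) / sd
    out = np.abs(z) > z_thresh
    frac = out.mean()
    if frac > max_outlier_frac:
        raise ValueError(
            f"{out.sum()} of {x.size} scores ({frac:.0%}) are outliers at |z|>{z_thresh}; aborting"
        )
    cleaned = x.copy()
    if out.any():
        cleaned[out] = x[~out].mean()
        log.info("clean_scores: replaced %d outliers with the remaining mean", int(out.sum()))
    return cleaned, CleanReport(int(out.sum()), float(w), float(p))


def marker_correlations(
    markers: pd.DataFrame,
    scores: pd.DataFrame,
    covariate=None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Pearson (or covariate-partial) correlation of every marker with every
    score, Bonferroni-corrected over the family.

    ``family_size`` defaults to n_markers x n_scores. Returns a tidy table
    (marker, score, r, p_raw, p_bonferroni).
    """
    import pingouin as pg

    if isinstance(scores, pd.Series):
        scores = scores.to_frame()
    n = len(markers)
    if len(scores) != n:
        raise ValueError("markers and scores must have matching subjects")
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    if family_size is None:
        family_size = markers.shape[1] * scores.shape[1]
    cov = None if covariate is None else np.asarray(covariate, dtype=float)
    rows = []
    for m in markers.columns:
        x = markers[m].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            raise ValueError(f"marker {m!r} has zero variance")
        for s in scores.columns:
            y = scores[s].to_numpy(dtype=float)
            if cov is None:
                r, p = stats.pearsonr(x, y)
            else:
                df = pd.DataFrame({"x": x, "y": y, "z": cov})
                res = pg.partial_corr(data=df, x="x", y="y", covar="z")
                r, p = float(res["r"].iloc[0]), float(res["p_val"].iloc[0])
            rows.append(
                {
                    "marker": m,
                    "score": s,
                    "r": float(r),
                    "p_raw": float(p),
                    "p_bonferroni": min(1.0, float(p) * family_size),
                }
            )
    return pd.DataFrame(rows)
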
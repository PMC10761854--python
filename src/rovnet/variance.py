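"""Cohort-level variance maps: activity F-ratio maps, GM-volume SD maps,
and the second-level group t-map used to restrict them to the task network.

The activity-variance map is the voxelwise ratio of between-individuals to
within-individuals variance of a task contrast,

    S_B^2 = [ (1/(NSubj-1)) * sum_i (con_i - mean(con))^2 ] / 2 * NScan
    S_W^2 = mean_i(ResMS_i) / (NScan - 1)
    F     = S_B^2 / S_W^2

where ``con_i`` is subject i's contrast image, ``ResMS_i`` the first-level
residual mean-square image, NScan the scan count of the first-level model
and NSubj the cohort size. Voxels with S_W^2 = 0 have no defined F and are
marked NaN so downstream thresholding can skip them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from rovnet.grid import GridGeometry

log = logging.getLogger(__name__)

#: 26-connectivity structuring element (SPM cluster convention).
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SubjectContrast:
    """One subject's first-level output: contrast map + residual mean square."""

    con: np.ndarray
    resms: np.ndarray
    n_scans: int
    geometry: GridGeometry

    def __post_init__(self):
        self.con = np.asarray(self.con, dtype=float)
        self.resms = np.asarray(self.resms, dtype=float)
        if self.con.shape != self.resms.shape:
            raise ValueError("con and resms must share dimensions")
        if tuple(self.con.shape) != tuple(self.geometry.shape):
            raise ValueError("volume shape does not match geometry")
        if self.n_scans < 2:
            raise ValueError("n_scans must be >= 2")
        if np.any(self.resms < 0):
            raise ValueError("resms must be nonnegative")


@dataclass
class VarianceMap:
    """Voxel grid of F ratios (functional) or across-subject SDs (structural)."""

    values: np.ndarray
    kind: str  # "functional_F" | "structural_SD"
    geometry: GridGeometry
    threshold: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("functional_F", "structural_SD"):
            raise ValueError(f"unknown variance-map kind: {self.kind}")
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class GroupTMap:
    """Second-level one-sample t-map with its FWE + cluster-size binary mask."""

    t_values: np.ndarray
    df: int
    binary_mask: np.ndarray
    geometry: GridGeometry
    n_excluded: int = 0
    alpha: float = 0.05
    min_cluster_size: int = 10


def _check_cohort(cohort: list[SubjectContrast]) -> None:
    if len(cohort) < 2:
        raise ValueError("need at least 2 subjects")
    ref = cohort[0]
    for sc in cohort[1:]:
        if sc.con.shape != ref.con.shape:
            raise ValueError("subjects have mismatched volume dimensions")
        if sc.n_scans != ref.n_scans:
            raise ValueError("subjects have mismatched n_scans")


def between_subject_variance(
    cohort: list[SubjectContrast], halve_scale: bool = True
) -> np.ndarray:
    """Voxelwise between-individuals variance S_B^2 of the contrast maps.

    ``halve_scale=True`` applies the printed "/2 * NScan" scaling; setting it
    False drops that factor for sensitivity analyses (the plain sample
    variance of the contrast values is returned instead).
    """
    _check_cohort(cohort)
    cons = np.stack([sc.con for sc in cohort])
    # centering by one subject's map is exact for the sample variance and
    # makes identical cohorts give exactly zero (no float dust)
    s2 = np.var(cons - cons[0], axis=0, ddof=1)
    if halve_scale:
        return s2 / 2.0 * cohort[0].n_scans
    return s2


def within_subject_variance(cohort: list[SubjectContrast]) -> np.ndarray:
    """Voxelwise within-individuals variance S_W^2 = mean(ResMS)/(NScan-1)."""
    _check_cohort(cohort)
    resms = np.stack([sc.resms for sc in cohort])
    return resms.mean(axis=0) / (cohort[0].n_scans - 1)


def f_ratio_map(cohort: list[SubjectContrast], halve_scale: bool = True) -> VarianceMap:
    """Voxelwise F = S_B^2 / S_W^2; NaN where S_W^2 = 0 (F undefined)."""
    sb2 = between_subject_variance(cohort, halve_scale=halve_scale)
    sw2 = within_subject_variance(cohort)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(sw2 > 0, sb2 / np.where(sw2 > 0, sw2, 1.0), np.nan)
    n_undef = int(np.sum(sw2 == 0))
    if n_undef:
        log.info("f_ratio_map: %d voxels with S_W^2 = 0 set to NaN", n_undef)
    return VarianceMap(values=f, kind="functional_F", geometry=cohort[0].geometry)


def sd_map(gm_cohort: list[np.ndarray], geometry: GridGeometry) -> VarianceMap:
    """Across-subject sample SD (ddof=1) of grey-matter volume maps."""
    if len(gm_cohort) < 2:
        raise ValueError("need at least 2 subjects")
    vols = np.stack([np.asarray(v, dtype=float) for v in gm_cohort])
    if vols.shape[1:] != tuple(geometry.shape):
        raise ValueError("volume shape does not match geometry")
    return VarianceMap(
        values=np.std(vols - vols[0], axis=0, ddof=1), kind="structural_SD", geometry=geometry
    )


def group_tmap(
    cohort: list[SubjectContrast],
    alpha: float = 0.05,
    min_cluster_size: int = 10,
) -> GroupTMap:
    """Second-level one-sample t-test of the contrast maps against zero.

    Family-wise error is controlled by voxelwise Bonferroni over the
    in-analysis voxels (those with nonzero across-subject variance), a
    deterministic, conservative alternative to random-field theory.
    Surviving voxels are grouped into 26-connected components and components
    below ``min_cluster_size`` voxels are removed.
    """
    _check_cohort(cohort)
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects for a group t-map")
    cons = np.stack([sc.con for sc in cohort])
    n = len(cohort)
    mean = cons.mean(axis=0)
    sd = np.std(cons - cons[0], axis=0, ddof=1)
    in_analysis = sd > 0
    n_excluded = int(np.sum(~in_analysis))
    if n_excluded:
        log.info("group_tmap: excluded %d zero-variance voxels", n_excluded)

    t = np.full(mean.shape, np.nan)
    t[in_analysis] = mean[in_analysis] / (sd[in_analysis] / np.sqrt(n))
    df = n - 1

    n_tests = int(in_analysis.sum())
    sig = np.zeros(mean.shape, dtype=bool)
    if n_tests:
        p = 2.0 * stats.t.sf(np.abs(t[in_analysis]), df)
        sig[in_analysis] = p <= alpha / n_tests

    labels, n_comp = ndimage.label(sig, structure=CONNECTIVITY_26)
    mask = np.zeros(mean.shape, dtype=np.uint8)
    if n_comp:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        keep = np.flatnonzero(sizes >= min_cluster_size) + 1
        mask[np.isin(labels, keep)] = 1
    return GroupTMap(
        t_values=t,
        df=df,
        binary_mask=mask,
        geometry=cohort[0].geometry,
        n_excluded=n_excluded,
        alpha=alpha,
        min_cluster_size=min_cluster_size,
    )


def mask_variance_map(vmap: VarianceMap, tmap: GroupTMap) -> VarianceMap:
    """Zero the variance map outside the group mask; record the mask."""
    if vmap.values.shape != tmap.binary_mask.shape:
        raise ValueError("variance map and t-map have mismatched dimensions")
    values = np.where(tmap.binary_mask.astype(bool), vmap.values, 0.0)
    return VarianceMap(
        values=values,
        kind=vmap.kind,
        geometry=vmap.geometry,
        threshold=vmap.threshold,
        mask=tmap.binary_mask.copy(),
    )
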
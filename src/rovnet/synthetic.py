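"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a ~100-subject task-fMRI cohort at desk scale:

* per-subject contrast maps ``con_i = mu + b_i`` with spatially
  heterogeneous between-subject noise ``b_i ~ N(0, sigma_B(v)^2)``,
  elevated inside configured high-variance spheres, plus residual
  mean-square maps drawn as scaled chi-square with NScan-1 degrees of
  freedom so their expectation is the configured within-subject variance;
* grey-matter volume maps ``template + N(0, sigma_GM(v)^2)`` (clipped at
  zero) with region-dependent SD;
* multi-voxel ROV series from a latent-factor model: each ROV has one
  latent series, voxel series are loading x latent + voxel noise, and the
  latents across ROVs are drawn with a subject-specific coupling matrix
  (population target + across-subject jitter). Resting series carry
  configurable confound leakage so the cleaning stage has work to do;
* confound tables (24 motion parameters as smooth random walks with the
  usual lag/square expansion, plus low-frequency CSF/WM/global signals);
* a behavior table whose primary score is linearly coupled to a
  designated network edge set, plus an uncoupled second score and a
  brain-size covariate.

All randomness flows from one integer seed through per-subject
sub-streams, so cohorts are byte-identical for a fixed config and stable
under changes of ``n_subjects``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from rovnet.connectivity import FCNetwork, ROISeriesSet
from rovnet.grid import GridGeometry
from rovnet.rov import define_rov
from rovnet.variance import SubjectContrast

# sub-stream ids so each artifact family has an independent stream
(
    _S_FIELDS,
    _S_CON,
    _S_RESMS,
    _S_GM,
    _S_TASK,
    _S_REST,
    _S_CONF,
    _S_BEHAV,
    _S_COUPLING,
) = range(9)


@dataclass(frozen=True)
class ROVSpec:
    label: str
    center_mm: tuple[float, float, float]
    radius_mm: float = 10.0


@dataclass(frozen=True)
class CouplingSpec:
    """Population edge-strength targets (K x K, in [0,1)) and their
    across-subject SD."""

    targets: np.ndarray
    edge_sd: float = 0.24


@dataclass(frozen=True)
class BehaviorCoupling:
    """Linear coupling of the primary score to a designated edge set.

    ``noise_sd=None`` matches the noise SD to the SD of the coupled signal
    across subjects (signal-to-noise ratio 1).
    """

    edges: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 2))
    slope: float = 100.0
    intercept: float = 115.0
    noise_sd: float | None = None


def _default_rov_specs() -> list[ROVSpec]:
    """13 non-overlapping 10-mm spheres on a 24-mm lattice."""
    lattice = list(product((-24.0, 0.0, 24.0), repeat=3))
    centers = lattice[::2][:13]
    return [ROVSpec(label=f"R{i + 1:02d}", center_mm=c) for i, c in enumerate(centers)]


def gen_edge_networks(
    n_subjects: int,
    targets: np.ndarray,
    edge_sd,
    seed: int,
    nodes: list[str] | None = None,
    state: str = "rest",
) -> list[FCNetwork]:
    """Edge-level synthetic networks: every unique edge varies independently
    across subjects around its population target.

    ``edge_sd`` is a scalar or a K x K matrix of per-edge across-subject
    SDs. This is the direct model of connectivity estimates used for power
    and calibration analyses of the prediction machinery: it bypasses the
    voxel-series generator (whose edges carry correlated estimation noise)
    so that properties of the CPM algorithm itself can be measured under
    exactly specified edge statistics. Values are clipped to [0, 1].
    """
    t = np.asarray(targets, dtype=float)
    k = t.shape[0]
    if nodes is None:
        nodes = [f"R{i + 1:02d}" for i in range(k)]
    iu = np.triu_indices(k, 1)
    sd = np.broadcast_to(np.asarray(edge_sd, dtype=float), (k, k))[iu]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 90]))
    nets = []
    for _ in range(n_subjects):
        edges = np.zeros((k, k))
        edges[iu] = np.clip(t[iu] + sd * rng.standard_normal(len(iu[0])), 0.0, 1.0)
        edges += edges.T
        nets.append(FCNetwork(state=state, nodes=list(nodes), edges=edges))
    return nets


def cpm_power_conditions(
    k: int = 13,
    designated: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5)),
    strong_target: float = 0.5,
    strong_sd: float = 0.19,
    background_sd: float = 0.08,
    seed: int = 2024,
) -> dict:
    """Edge statistics for connectome-prediction power and calibration runs.

    Population targets are heterogeneous (U[0.2, 0.45]); the behaviorally
    designated edges sit at ``strong_target`` and carry the large
    across-subject SD (0.19, the observed rest-state mean for networks
    selected for variability), while background edges vary less —
    individual differences concentrate in specific connections, which is
    the premise of a region-of-variance analysis.
    """
    rng = np.random.default_rng(seed)
    targets = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    targets[iu] = rng.uniform(0.2, 0.45, len(iu[0]))
    targets += targets.T
    sd = np.full((k, k), background_sd)
    for a, b in designated:
        targets[a, b] = targets[b, a] = strong_target
        sd[a, b] = sd[b, a] = strong_sd
    np.fill_diagonal(sd, 0.0)
    return {"targets": targets, "edge_sd": sd, "designated": designated}


def nearest_correlation(c: np.ndarray, eig_floor: float = 1e-3) -> np.ndarray:
    """Project a symmetric matrix to the closest valid correlation matrix
    (eigenvalue clipping + diagonal renormalization)."""
    w, v = np.linalg.eigh(c)
    r = (v * np.clip(w, eig_floor, None)) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def default_coupling(
    k: int = 13,
    lo: float = 0.1,
    hi: float = 0.35,
    edge_sd: float = 0.24,
    strong_edges: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 2)),
    strong_value: float = 0.55,
    seed: int = 2024,
) -> CouplingSpec:
    """Heterogeneous population coupling targets with a strong core module.

    Background edge targets are spread over [lo, hi] — functional coupling
    in real cortex is heterogeneous, and a uniform target matrix would put
    all across-subject variation on one global factor — while a small
    strongly coupled module (default: the triangle over the first three
    nodes, mirroring the connected "contributing network" structure such
    analyses report) sits at ``strong_value``, where the distance-
    correlation response to coupling changes is steepest. The matrix is
    projected to the nearest valid correlation matrix once, as a fixed
    population parameter.
    """
    rng = np.random.default_rng(seed)
    t = np.zeros((k, k))
    iu = np.triu_indices(k, 1)
    t[iu] = rng.uniform(lo, hi, size=len(iu[0]))
    t += t.T
    for a, b in strong_edges:
        t[a, b] = t[b, a] = strong_value
    np.fill_diagonal(t, 1.0)
    t = nearest_correlation(t)
    np.fill_diagonal(t, 0.0)
    return CouplingSpec(targets=np.clip(t, 0.0, 0.97), edge_sd=edge_sd)


@dataclass
class SimConfig:
    """Cohort generation parameters (defaults emulate the study conditions:
    97 unrelated subjects, 316-volume runs at TR 0.72 s, 13 ROVs)."""

    n_subjects: int = 97
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_scans: int = 316
    n_trials_task: int = 40
    n_timepoints_rest: int = 316
    n_runs_rest: int = 2
    tr_seconds: float = 0.72
    rov_specs: list[ROVSpec] = field(default_factory=_default_rov_specs)
    high_variance_regions: dict[str, float] = field(
        default_factory=lambda: {"R01": 6.0, "R05": 6.0, "R09": 6.0}
    )
    coupling: CouplingSpec | None = None
    behavior_coupling: BehaviorCoupling = field(default_factory=BehaviorCoupling)
    seed: int = 0

    # amplitude knobs of the generative fields (arbitrary task-contrast units)
    mu_amplitude: float = 1.0
    sigma_b_base: float = 0.08
    sigma_w: float = 1.0
    gm_template_base: float = 0.45
    sigma_gm_base: float = 0.04
    voxel_loading_spread: float = 0.2
    voxel_noise_sd: float = 0.5
    confound_leakage: float = 0.3

    def __post_init__(self):
        if self.coupling is None:
            self.coupling = default_coupling(len(self.rov_specs))
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if any(d < 3 for d in self.grid_dims):
            raise ValueError("degenerate grid: every dimension must be >= 3")
        if any(s.radius_mm <= 0 for s in self.rov_specs):
            raise ValueError("all ROV radii must be > 0")
        t = np.asarray(self.coupling.targets, dtype=float)
        off = t[~np.eye(t.shape[0], dtype=bool)]
        if np.any(off < 0) or np.any(off >= 1):
            raise ValueError("coupling targets must lie in [0, 1)")
        bc = self.behavior_coupling
        if bc.noise_sd is not None and bc.noise_sd < 0:
            raise ValueError("behavior noise SD must be >= 0")
        k = len(self.rov_specs)
        for a, b in bc.edges:
            if not (0 <= a < k and 0 <= b < k and a != b):
                raise ValueError(f"behavior edge ({a},{b}) refers to nonexistent node pair")
        labels = {s.label for s in self.rov_specs}
        unknown = set(self.high_variance_regions) - labels
        if unknown:
            raise ValueError(f"high_variance_regions refer to unknown ROVs: {unknown}")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry.isotropic(self.grid_dims, self.voxel_size_mm)

    def rng(
        self, stream: int, subject: int | None = None, run: int | None = None
    ) -> np.random.Generator:
        key = [self.seed, stream]
        if subject is not None:
            key.append(subject)
        if run is not None:
            key.append(run)
        return np.random.default_rng(np.random.SeedSequence(key))


@dataclass
class SyntheticCohort:
    """Everything a downstream analysis consumes, plus the ground truth."""

    config: SimConfig
    contrasts: list[SubjectContrast]
    gm_maps: list[np.ndarray]
    task_series: ROISeriesSet
    rest_series: list[ROISeriesSet]  # one per rest run
    confounds: list[list[pd.DataFrame]]  # [run][subject]
    rest_networks: list[FCNetwork]  # edge estimates averaged across runs
    behavior: pd.DataFrame
    truth: dict


def _smooth_field(rng: np.random.Generator, shape, sigma_vox: float = 2.0) -> np.ndarray:
    """Smooth standardized random field (mean 0, SD 1)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox, mode="wrap")
    return (f - f.mean()) / f.std()


def _region_multiplier(config: SimConfig) -> np.ndarray:
    """Voxel grid of SD multipliers: ~1 far from the designated regions,
    rising to the configured value at each region's center.

    Each high-variance region contributes a Gaussian bump (scale = half the
    sphere radius), so variance hotspots peak at the configured centers —
    the shape a cluster-peak recovery analysis assumes.
    """
    mult = np.ones(config.grid_dims)
    centers = config.geometry.voxel_centers_mm()
    for spec in config.rov_specs:
        m = config.high_variance_regions.get(spec.label)
        if m is None:
            continue
        d2 = np.sum((centers - np.asarray(spec.center_mm)) ** 2, axis=-1)
        scale2 = (spec.radius_mm / 2.0) ** 2
        mult += (m - 1.0) * np.exp(-d2 / (2.0 * scale2))
    return mult


def sigma_b_field(config: SimConfig) -> np.ndarray:
    """The true between-subject SD field of the contrast maps."""
    rng = config.rng(_S_FIELDS, 0)
    modulation = 1.0 + 0.2 * _smooth_field(rng, config.grid_dims)
    return config.sigma_b_base * np.clip(modulation, 0.5, None) * _region_multiplier(config)


def mean_contrast_field(config: SimConfig) -> np.ndarray:
    """The true population-mean contrast field mu(v)."""
    rng = config.rng(_S_FIELDS, 1)
    return config.mu_amplitude * (0.8 + 0.4 * _smooth_field(rng, config.grid_dims))


def gen_contrast_cohort(config: SimConfig) -> list[SubjectContrast]:
    """Per-subject contrast + ResMS volumes under the variance model."""
    config.validate()
    mu = mean_contrast_field(config)
    sig_b = sigma_b_field(config)
    df = config.n_scans - 1
    cohort = []
    geom = config.geometry
    for i in range(config.n_subjects):
        con = mu + sig_b * config.rng(_S_CON, i).standard_normal(config.grid_dims)
        resms = config.sigma_w**2 * config.rng(_S_RESMS, i).chisquare(df, size=config.grid_dims) / df
        cohort.append(SubjectContrast(con=con, resms=resms, n_scans=config.n_scans, geometry=geom))
    return cohort


def gm_template_and_sd(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = config.rng(_S_GM)
    template = config.gm_template_base * (1.0 + 0.5 * _smooth_field(rng, config.grid_dims))
    template = np.clip(template, 0.0, None)
    modulation = 1.0 + 0.2 * _smooth_field(rng, config.grid_dims)
    sigma = config.sigma_gm_base * np.clip(modulation, 0.5, None) * _region_multiplier(config)
    return template, sigma


def gen_gm_cohort(config: SimConfig) -> list[np.ndarray]:
    """Per-subject grey-matter volume maps (values clipped at >= 0)."""
    config.validate()
    template, sigma = gm_template_and_sd(config)
    maps = []
    for i in range(config.n_subjects):
        z = config.rng(_S_GM, i).standard_normal(config.grid_dims)
        maps.append(np.clip(template + sigma * z, 0.0, None))
    return maps


def subject_coupling(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One subject's latent correlation matrix.

    Drawn as a normalized Wishart sample centered on the population target,
    with the Wishart degrees of freedom set so the across-subject SD of an
    edge is approximately ``coupling.edge_sd`` (the sampling SD of a
    correlation, (1 - rho^2)/sqrt(nu), inverted at the mean target). The
    draw is a valid correlation matrix by construction, so no
    positive-definite projection — which would leak shared variance into
    every edge — is needed.
    """
    t = np.asarray(config.coupling.targets, dtype=float).copy()
    np.fill_diagonal(t, 1.0)
    k = t.shape[0]
    if config.coupling.edge_sd == 0:
        return t
    rho = float(t[np.triu_indices(k, 1)].mean())
    nu = max(int(round(((1.0 - rho**2) / config.coupling.edge_sd) ** 2)), k + 1)
    a = np.linalg.cholesky(t) @ rng.standard_normal((k, nu))
    s = a @ a.T / nu
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def _rov_voxel_counts(config: SimConfig) -> list[int]:
    geom = config.geometry
    return [
        len(define_rov(s.label, "functional", s.center_mm, geom, s.radius_mm).voxel_ids)
        for s in config.rov_specs
    ]


def gen_roi_series(config: SimConfig, state: str = "task", run: int = 0) -> ROISeriesSet:
    """Latent-factor multi-voxel series for every subject and ROV.

    Task series are white across trials (beta-series); rest series are
    temporally smoothed to mimic BOLD autocorrelation and receive confound
    leakage (CSF/WM/global + slow motion drift) that the cleaning stage is
    expected to remove.

    A subject's latent coupling matrix is a trait: it is drawn from a
    dedicated per-subject stream and shared across states and runs, so
    task/rest/run-repeat estimates of the same edge agree up to estimation
    noise. ``run`` indexes independent repetitions of the acquisition.
    """
    config.validate()
    if state not in ("task", "rest"):
        raise ValueError(f"unknown state: {state}")
    k = len(config.rov_specs)
    if k < 2:
        raise ValueError("need at least 2 ROVs")
    n_obs = config.n_trials_task if state == "task" else config.n_timepoints_rest
    if n_obs < 4:
        raise ValueError("need at least 4 observations (distance correlation undefined below)")

    n_vox = _rov_voxel_counts(config)
    # per-ROV voxel loadings are a cohort-level property (stable across subjects)
    rng_load = config.rng(_S_FIELDS, 2)
    loadings = [
        1.0 + config.voxel_loading_spread * rng_load.uniform(-1, 1, size=nv) for nv in n_vox
    ]
    confounds = gen_confounds(config, run=run) if state == "rest" else None

    stream = _S_TASK if state == "task" else _S_REST
    series: list[dict[str, np.ndarray]] = []
    for i in range(config.n_subjects):
        r = subject_coupling(config, config.rng(_S_COUPLING, i))
        rng = config.rng(stream, i, run=run)
        z = rng.standard_normal((k, n_obs))
        if state == "rest":
            z = gaussian_filter1d(z, sigma=2.0, axis=1, mode="wrap")
            z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        latents = np.linalg.cholesky(r) @ z
        subj: dict[str, np.ndarray] = {}
        for j, spec in enumerate(config.rov_specs):
            noise = config.voxel_noise_sd * rng.standard_normal((n_vox[j], n_obs))
            y = loadings[j][:, None] * latents[j] + noise
            if state == "rest" and config.confound_leakage > 0:
                conf = confounds[i]
                leak = (
                    _unit(conf["global"].to_numpy())
                    + 0.5 * _unit(conf["csf"].to_numpy())
                    + 0.5 * _unit(conf["mot01"].to_numpy())
                )
                y = y + config.confound_leakage * leak[None, :]
            subj[spec.label] = y
        series.append(subj)
    return ROISeriesSet(
        state=state,
        series=series,
        tr_seconds=config.tr_seconds if state == "rest" else None,
    )


def _unit(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def gen_confounds(config: SimConfig, run: int = 0) -> list[pd.DataFrame]:
    """Per-subject confound tables: 24 motion columns (6 smooth random
    walks, their one-step lags, and the 12 squares) + CSF + WM + global."""
    tables = []
    t = config.n_timepoints_rest
    for i in range(config.n_subjects):
        rng = config.rng(_S_CONF, i, run=run)
        motion = np.cumsum(0.02 * rng.standard_normal((t, 6)), axis=0)
        lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
        block12 = np.hstack([motion, lagged])
        cols = np.hstack([block12, block12**2])
        names = (
            [f"mot{j + 1:02d}" for j in range(6)]
            + [f"mot{j + 1:02d}_lag" for j in range(6)]
            + [f"mot{j + 1:02d}_sq" for j in range(6)]
            + [f"mot{j + 1:02d}_lag_sq" for j in range(6)]
        )
        df = pd.DataFrame(cols, columns=names)
        for name in ("csf", "wm", "global"):
            df[name] = gaussian_filter1d(rng.standard_normal(t), sigma=10.0, mode="wrap")
        tables.append(df)
    return tables


def gen_behavior(
    networks: list[FCNetwork],
    config: SimConfig,
    gm_maps: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Behavior table: a score linearly coupled to the designated edge set,
    an uncoupled second score, and a brain-size covariate.

    ``score_orrt_like = intercept + slope * sum(designated edges) + noise``;
    with ``noise_sd=None`` the noise SD equals the across-subject SD of the
    coupled signal (SNR 1). ``score_pvt_like`` is independent of the
    networks. Brain size is total grey-matter volume when GM maps are
    supplied, otherwise a plausible draw. The noise SD actually used is
    recorded in ``df.attrs["noise_sd_used"]``.
    """
    bc = config.behavior_coupling
    if bc.slope != 0 and len(bc.edges) == 0:
        raise ValueError("empty edge set with nonzero slope")
    n = len(networks)
    sums = np.array([sum(net.edges[a, b] for a, b in bc.edges) for net in networks])
    signal = bc.slope * sums
    noise_sd = bc.noise_sd if bc.noise_sd is not None else float(np.std(signal, ddof=1))
    rng = config.rng(_S_BEHAV)
    score = bc.intercept + signal + noise_sd * rng.standard_normal(n)
    pvt = 115.0 + 10.0 * rng.standard_normal(n)
    if gm_maps is not None:
        vol = float(np.abs(np.linalg.det(config.geometry.affine[:3, :3])))
        brain = np.array([m.sum() * vol / 1000.0 for m in gm_maps])  # cm^3
    else:
        brain = 1250.0 + 100.0 * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "score_orrt_like": score,
            "score_pvt_like": pvt,
            "brain_size": brain,
        }
    )
    df.attrs["noise_sd_used"] = noise_sd
    return df


def build_rest_networks(config: SimConfig, clean: bool = True) -> tuple[list, list, list]:
    """Rest networks with per-run cleaning and edge averaging across runs.

    Each run is generated, cleaned and turned into a distance-correlation
    network separately; a subject's edge estimate is the mean over runs.
    Returns ``(networks, rest_series_per_run, confounds_per_run)``.
    """
    from rovnet.connectivity import FCNetwork, build_fc_network, preprocess_series

    run_series, run_confounds, run_nets = [], [], []
    for run in range(config.n_runs_rest):
        sset = gen_roi_series(config, "rest", run=run)
        conf = gen_confounds(config, run=run)
        run_series.append(sset)
        run_confounds.append(conf)
        cleaned = (
            preprocess_series(sset, confounds=[c.to_numpy() for c in conf]) if clean else sset
        )
        run_nets.append(build_fc_network(cleaned))
    nodes = run_nets[0][0].nodes
    networks = [
        FCNetwork(
            state="rest",
            nodes=nodes,
            edges=np.mean([nets[i].edges for nets in run_nets], axis=0),
        )
        for i in range(config.n_subjects)
    ]
    return networks, run_series, run_confounds


def generate_cohort(config: SimConfig, clean: bool = True) -> SyntheticCohort:
    """Full seeded cohort: volumes, series, confounds, networks, behavior.

    Rest networks are built from (optionally cleaned) per-run rest series,
    averaged across runs, and the behavior score is coupled to the
    designated edges of those networks, giving CPM a recoverable ground
    truth.
    """
    contrasts = gen_contrast_cohort(config)
    gm_maps = gen_gm_cohort(config)
    task_series = gen_roi_series(config, "task")
    rest_networks, rest_series, confounds = build_rest_networks(config, clean=clean)
    behavior = gen_behavior(rest_networks, config, gm_maps=gm_maps)
    truth = {
        "sigma_b": sigma_b_field(config),
        "high_variance_labels": sorted(config.high_variance_regions),
        "behavior_edges": list(config.behavior_coupling.edges),
        "behavior_slope": config.behavior_coupling.slope,
        "noise_sd_used": behavior.attrs["noise_sd_used"],
    }
    return SyntheticCohort(
        config=config,
        contrasts=contrasts,
        gm_maps=gm_maps,
        task_series=task_series,
        rest_series=rest_series,
        confounds=confounds,
        rest_networks=rest_networks,
        behavior=behavior,
        truth=truth,
    )
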
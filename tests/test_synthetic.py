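"""Synthetic-cohort generator: determinism, calibration and recovery."""

import numpy as np
import pandas as pd
import pytest

from rovnet.connectivity import build_fc_network, preprocess_series
from rovnet.rov import changepoint_threshold
from rovnet.synthetic import (
    BehaviorCoupling,
    CouplingSpec,
    ROVSpec,
    SimConfig,
    default_coupling,
    gen_behavior,
    gen_confounds,
    gen_contrast_cohort,
    gen_gm_cohort,
    gen_roi_series,
    generate_cohort,
    subject_coupling,
    _S_COUPLING,
)
from rovnet.variance import f_ratio_map, sd_map


class TestConfigValidation:
    def test_rejects_bad_configs(self, small_config):
        import dataclasses

        with pytest.raises(ValueError, match="n_subjects"):
            dataclasses.replace(small_config, n_subjects=3)
        with pytest.raises(ValueError, match="degenerate"):
            dataclasses.replace(small_config, grid_dims=(2, 12, 12))
        bad = np.array([[0, 1.2, 0.3], [1.2, 0, 0.3], [0.3, 0.3, 0]])
        with pytest.raises(ValueError, match="coupling"):
            dataclasses.replace(small_config, coupling=CouplingSpec(targets=bad))
        with pytest.raises(ValueError, match="node pair"):
            dataclasses.replace(
                small_config, behavior_coupling=BehaviorCoupling(edges=((0, 9),))
            )


class TestDeterminism:
    def test_same_seed_identical_cohort(self, small_config):
        a = generate_cohort(small_config)
        b = generate_cohort(small_config)
        for sa, sb in zip(a.contrasts, b.contrasts):
            np.testing.assert_array_equal(sa.con, sb.con)
            np.testing.assert_array_equal(sa.resms, sb.resms)
        for ga, gb in zip(a.gm_maps, b.gm_maps):
            np.testing.assert_array_equal(ga, gb)
        for na, nb in zip(a.rest_networks, b.rest_networks):
            np.testing.assert_array_equal(na.edges, nb.edges)
        pd.testing.assert_frame_equal(a.behavior, b.behavior)

    def test_different_seed_differs(self, small_config):
        import dataclasses

        a = gen_contrast_cohort(small_config)
        b = gen_contrast_cohort(dataclasses.replace(small_config, seed=8))
        assert not np.array_equal(a[0].con, b[0].con)

    def test_cohort_stable_under_n_subjects_extension(self, small_config):
        """Adding subjects must not change existing subjects' data."""
        import dataclasses

        small = gen_contrast_cohort(small_config)
        big = gen_contrast_cohort(dataclasses.replace(small_config, n_subjects=14))
        for sa, sb in zip(small, big):
            np.testing.assert_array_equal(sa.con, sb.con)


class TestContrastCohort:
    def test_zero_between_sd_gives_identical_maps_and_zero_f(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, sigma_b_base=0.0)
        cohort = gen_contrast_cohort(cfg)
        for sc in cohort[1:]:
            np.testing.assert_array_equal(sc.con, cohort[0].con)
        f = f_ratio_map(cohort)
        assert np.nanmax(f.values) == 0.0
        # the whole map is flat: no change point exists, nothing survives
        thr, _ = changepoint_threshold(f.values[np.isfinite(f.values)])
        assert thr == np.inf

    def test_high_variance_sphere_raises_contrast_sd(self, small_config):
        """Across-subject contrast SD inside the elevated sphere exceeds the
        outside SD (Monte-Carlo over seeds)."""
        import dataclasses

        geom = small_config.geometry
        inside = tuple(geom.sphere_voxels((-9.0, 0.0, 0.0), 10.0).T)
        wins = 0
        for seed in range(20):
            cfg = dataclasses.replace(small_config, seed=seed, n_subjects=40)
            cons = np.stack([sc.con for sc in gen_contrast_cohort(cfg)])
            sd = cons.std(axis=0, ddof=1)
            mask = np.zeros(geom.shape, dtype=bool)
            mask[inside] = True
            wins += sd[mask].mean() > sd[~mask].mean()
        assert wins == 20

    def test_resms_expectation_matches_sigma_w(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, n_subjects=40)
        resms = np.stack([sc.resms for sc in gen_contrast_cohort(cfg)])
        assert resms.mean() == pytest.approx(cfg.sigma_w**2, rel=0.05)

    def test_f_monotone_in_multiplier(self, small_config):
        """Regional mean F rises with the configured SD multiplier."""
        import dataclasses

        geom = small_config.geometry
        inside = tuple(geom.sphere_voxels((-9.0, 0.0, 0.0), 10.0).T)
        means = []
        for mult in (1.0, 3.0, 6.0):
            cfg = dataclasses.replace(
                small_config, n_subjects=40, high_variance_regions={"A": mult}
            )
            f = f_ratio_map(gen_contrast_cohort(cfg))
            means.append(np.nanmean(f.values[inside]))
        assert means[0] < means[1] < means[2]


class TestGMCohort:
    def test_zero_sigma_gives_zero_sd_map(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, sigma_gm_base=0.0)
        maps = gen_gm_cohort(cfg)
        assert np.all(sd_map(maps, cfg.geometry).values == 0)

    def test_values_clipped_nonnegative(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(small_config, gm_template_base=0.0, sigma_gm_base=5.0)
        for m in gen_gm_cohort(cfg):
            assert m.min() >= 0.0

    def test_elevated_region_ranks_first_in_sd(self, small_config):
        """Mean SD-map value over the elevated sphere exceeds every other
        sphere's mean (Monte-Carlo over seeds)."""
        import dataclasses

        geom = small_config.geometry
        spheres = {
            s.label: tuple(geom.sphere_voxels(s.center_mm, s.radius_mm).T)
            for s in small_config.rov_specs
        }
        for seed in range(10):
            cfg = dataclasses.replace(small_config, seed=seed, n_subjects=40)
            sd = sd_map(gen_gm_cohort(cfg), geom).values
            means = {label: sd[vox].mean() for label, vox in spheres.items()}
            assert max(means, key=means.get) == "A"


class TestROISeries:
    def test_observation_and_node_counts(self, small_config):
        sset = gen_roi_series(small_config, "task")
        assert sset.n_subjects == small_config.n_subjects
        for subj in sset.series:
            assert set(subj) == {"A", "B", "C"}
            for arr in subj.values():
                assert arr.shape[1] == small_config.n_trials_task

    def test_subject_coupling_is_valid_correlation(self, small_config):
        for i in range(5):
            r = subject_coupling(small_config, small_config.rng(_S_COUPLING, i))
            np.testing.assert_allclose(r, r.T)
            np.testing.assert_allclose(np.diag(r), 1.0)
            assert np.linalg.eigvalsh(r).min() > 0

    def test_coupling_trait_shared_across_states_and_runs(self, small_config):
        """The same subject's latent coupling matrix drives task, rest and
        every rest run."""
        r0 = subject_coupling(small_config, small_config.rng(_S_COUPLING, 0))
        r0_again = subject_coupling(small_config, small_config.rng(_S_COUPLING, 0))
        np.testing.assert_array_equal(r0, r0_again)

    def test_runs_are_distinct_but_deterministic(self, small_config):
        a0 = gen_roi_series(small_config, "rest", run=0)
        a0b = gen_roi_series(small_config, "rest", run=0)
        a1 = gen_roi_series(small_config, "rest", run=1)
        np.testing.assert_array_equal(a0.series[0]["A"], a0b.series[0]["A"])
        assert not np.array_equal(a0.series[0]["A"], a1.series[0]["A"])

    def test_too_few_observations_rejected(self, small_config):
        import dataclasses

        with pytest.raises(ValueError, match="observations"):
            gen_roi_series(dataclasses.replace(small_config, n_trials_task=3), "task")

    @pytest.mark.parametrize("target, bound, side", [(0.0, 0.1, "below"), (0.95, 0.8, "above")])
    def test_mean_dcor_tracks_coupling_target(self, target, bound, side):
        """Long-series simulation: dCor is near zero for uncoupled ROVs and
        high for near-unity coupling."""
        specs = [ROVSpec("A", (-12.0, 0.0, 0.0)), ROVSpec("B", (12.0, 0.0, 0.0))]
        t = np.array([[0.0, target], [target, 0.0]])
        cfg = SimConfig(
            seed=0,
            n_subjects=50,
            n_trials_task=300,
            grid_dims=(12, 12, 12),
            rov_specs=specs,
            high_variance_regions={},
            coupling=CouplingSpec(targets=t, edge_sd=0.0),
            behavior_coupling=BehaviorCoupling(edges=((0, 1),)),
        )
        nets = build_fc_network(preprocess_series(gen_roi_series(cfg, "task")))
        mean_edge = np.mean([n.edges[0, 1] for n in nets])
        assert (mean_edge < bound) if side == "below" else (mean_edge > bound)

    def test_edge_estimates_monotone_in_coupling_ladder(self):
        """Spearman correlation between the configured coupling level and the
        cohort-mean edge estimate across a 5-level ladder."""
        from scipy.stats import spearmanr

        levels = [0.1, 0.3, 0.5, 0.7, 0.9]
        means = []
        for c in levels:
            specs = [ROVSpec("A", (-12.0, 0.0, 0.0)), ROVSpec("B", (12.0, 0.0, 0.0))]
            t = np.array([[0.0, c], [c, 0.0]])
            cfg = SimConfig(
                seed=1,
                n_subjects=40,
                n_trials_task=120,
                grid_dims=(12, 12, 12),
                rov_specs=specs,
                high_variance_regions={},
                coupling=CouplingSpec(targets=t, edge_sd=0.0),
                behavior_coupling=BehaviorCoupling(edges=((0, 1),)),
            )
            nets = build_fc_network(preprocess_series(gen_roi_series(cfg, "task")))
            means.append(np.mean([n.edges[0, 1] for n in nets]))
        rho = spearmanr(levels, means).statistic
        assert rho > 0.9


class TestConfounds:
    def test_shape_and_columns(self, small_config):
        tables = gen_confounds(small_config)
        assert len(tables) == small_config.n_subjects
        df = tables[0]
        assert df.shape == (small_config.n_timepoints_rest, 27)
        motion = [c for c in df.columns if c.startswith("mot")]
        assert len(motion) == 24
        assert {"csf", "wm", "global"} <= set(df.columns)

    def test_cleaning_removes_leaked_confounds(self, small_config):
        """Rest series leak global/CSF/motion; after the cleaning chain the
        residuals are orthogonal to the band-filtered confounds and far less
        correlated with the raw leak than before cleaning."""
        import dataclasses

        from rovnet.connectivity import REST_BAND, bandpass

        cfg = dataclasses.replace(small_config, n_timepoints_rest=316)
        sset = gen_roi_series(cfg, "rest")
        confounds = gen_confounds(cfg)
        cleaned = preprocess_series(sset, confounds=[c.to_numpy() for c in confounds])
        raw_corr, filt_corr = [], []
        for i in range(cfg.n_subjects):
            g = confounds[i]["global"].to_numpy()
            g_f = bandpass(g[None, :], cfg.tr_seconds, *REST_BAND)[0]
            raw = sset.series[i]["A"].mean(axis=0)
            cln = cleaned.series[i]["A"].mean(axis=0)
            raw_corr.append(abs(np.corrcoef(raw, g)[0, 1]))
            filt_corr.append(abs(np.corrcoef(cln, g_f)[0, 1]))
        assert np.mean(raw_corr) > 0.1  # the leak is really there
        assert np.max(filt_corr) < 1e-8  # and regression removes it exactly


class TestBehavior:
    def _nets(self, small_config, n=20, seed=0):
        rng = np.random.default_rng(seed)
        from rovnet.connectivity import FCNetwork

        nets = []
        for _ in range(n):
            e = np.abs(rng.normal(0.4, 0.1, size=(3, 3)))
            e = (e + e.T) / 2
            np.fill_diagonal(e, 0)
            nets.append(FCNetwork(state="rest", nodes=["A", "B", "C"], edges=e))
        return nets

    def test_noiseless_coupling_is_perfectly_correlated(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config,
            behavior_coupling=BehaviorCoupling(edges=((0, 1),), noise_sd=0.0),
        )
        nets = self._nets(cfg)
        table = gen_behavior(nets, cfg)
        sums = np.array([n.edges[0, 1] for n in nets])
        assert abs(np.corrcoef(table["score_orrt_like"], sums)[0, 1]) == pytest.approx(1.0)

    def test_zero_slope_gives_null_edge_correlations(self, small_config):
        """With slope 0 the score is pure noise: ~5% of many independent
        edge-score correlations pass p <= 0.05."""
        import dataclasses
        from rovnet.cpm import _edge_correlations

        rng = np.random.default_rng(3)
        edges = rng.normal(size=(60, 1000))
        cfg = dataclasses.replace(
            small_config,
            behavior_coupling=BehaviorCoupling(edges=((0, 1),), slope=0.0, noise_sd=5.0),
        )
        nets = self._nets(cfg, n=60)
        score = gen_behavior(nets, cfg)["score_orrt_like"].to_numpy()
        _, p = _edge_correlations(edges, score)
        assert 0.02 < (p <= 0.05).mean() < 0.08

    def test_snr_one_default_noise(self, small_config):
        """noise_sd=None matches the noise SD to the signal SD."""
        nets = self._nets(small_config, n=50)
        table = gen_behavior(nets, small_config)
        bc = small_config.behavior_coupling
        sums = np.array([sum(n.edges[a, b] for a, b in bc.edges) for n in nets])
        assert table.attrs["noise_sd_used"] == pytest.approx(
            np.std(bc.slope * sums, ddof=1)
        )

    def test_empty_edges_with_slope_rejected(self, small_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_config, behavior_coupling=BehaviorCoupling(edges=(), slope=1.0)
        )
        with pytest.raises(ValueError, match="empty edge set"):
            gen_behavior(self._nets(cfg), cfg)

    def test_brain_size_from_gm_maps(self, small_config):
        nets = self._nets(small_config, n=small_config.n_subjects)
        gm = gen_gm_cohort(small_config)
        table = gen_behavior(nets, small_config, gm_maps=gm)
        vol = abs(np.linalg.det(small_config.geometry.affine[:3, :3]))
        assert table["brain_size"].iloc[0] == pytest.approx(gm[0].sum() * vol / 1000.0)
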
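"""Synthetic cohort generator: geometry, covariance structure, responses."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from lesionqol import (
    GroundTruth,
    PlantedEffect,
    SimulationConfig,
    build_toy_atlas,
    connectivity_matrix,
    generate_cohort,
    score_cohort,
    simulate_lesions,
    simulate_qlq_responses,
    simulate_sides,
    simulate_timeseries,
    within_network_connectivity,
)
from lesionqol.qlq import load_scale_map


class TestLesionGeometry:
    def test_seed_reproducibility_voxel_identical(self, small_config, small_atlases):
        nodes, _ = small_atlases
        a, sides_a = simulate_lesions(small_config, nodes)
        b, sides_b = simulate_lesions(small_config, nodes)
        assert (sides_a == sides_b).all()
        for la, lb in zip(a, b):
            for t in la.masks:
                assert np.array_equal(la.masks[t], lb.masks[t])

    def test_cohort_extension_keeps_existing_subjects(self, small_config, small_atlases):
        nodes, _ = small_atlases
        a, _ = simulate_lesions(small_config, nodes)
        bigger = replace(small_config, n_subjects=small_config.n_subjects + 3)
        b, _ = simulate_lesions(bigger, nodes)
        for la, lb in zip(a, b):
            assert np.array_equal(la.masks["flair"], lb.masks["flair"])

    def test_forced_right_side(self, small_config, small_atlases):
        nodes, _ = small_atlases
        cfg = replace(small_config, fraction_right_sided=1.0)
        lesions, sides = simulate_lesions(cfg, nodes)
        assert (sides == "right").all()
        xw = nodes.x_world()
        for ls in lesions:
            idx = np.nonzero(ls.union())
            assert xw[idx[0]].mean() > 0

    def test_zero_radius_empty_masks(self, small_config, small_atlases):
        nodes, tracts = small_atlases
        cfg = replace(
            small_config,
            lesion_radii_mm={t: 0.0 for t in ("flair", "cavity", "t1ce", "fet")},
        )
        lesions, _ = simulate_lesions(cfg, nodes)
        for ls in lesions:
            for m in ls.masks.values():
                assert m.sum() == 0
        from lesionqol import overlap_table

        ov, totals = overlap_table(lesions, nodes, tracts)
        assert (ov["overlap_ml"] == 0).all()
        assert (totals["total_ml"] == 0).all()

    def test_nesting_invariants(self, small_config, small_atlases):
        nodes, _ = small_atlases
        lesions, _ = simulate_lesions(small_config, nodes)
        for ls in lesions:
            flair = ls.masks["flair"].astype(bool)
            for t in ("cavity", "t1ce"):
                assert not (ls.masks[t].astype(bool) & ~flair).any()
            fet = ls.masks["fet"].astype(bool)
            if fet.any() and flair.any():
                assert (fet & flair).any()

    def test_sides_helper_matches_full_simulation(self, small_config, small_atlases):
        nodes, _ = small_atlases
        _, sides_full = simulate_lesions(small_config, nodes)
        sides_fast = simulate_sides(small_config)
        assert (sides_full == sides_fast).all()


class TestTimeseries:
    def _flat_config(self, **kw):
        base = dict(
            n_subjects=1, grid_shape=(16, 16, 16), voxel_size_mm=(6.0, 6.0, 6.0),
            n_nodes_per_hemisphere=6, n_networks=2, n_tracts_per_hemisphere=1,
            n_midline_tracts=0, seed=21,
        )
        base.update(kw)
        return SimulationConfig(**base)

    def test_independent_when_rho_zero(self):
        cfg = self._flat_config(rho_within=0.0, rho_between=0.0, n_timepoints=2000)
        nodes, _ = build_toy_atlas(cfg)
        ts = simulate_timeseries(cfg, nodes)[0]
        cm = connectivity_matrix(ts)
        iu = np.triu_indices(len(cm.node_ids), 1)
        assert np.abs(np.nanmean(cm.z[iu])) < 3 / np.sqrt(cfg.n_timepoints)

    def test_recovers_generating_correlation(self):
        cfg = self._flat_config(rho_within=0.6, rho_between=0.0, n_timepoints=3000)
        nodes, _ = build_toy_atlas(cfg)
        ts = simulate_timeseries(cfg, nodes)[0]
        r = np.corrcoef(ts.data)
        reg = nodes.regions
        pool = {n: (reg.loc[n, "hemisphere"], reg.loc[n, "class_"]) for n in reg.index}
        ids = list(reg.index)
        within = [
            r[i, j]
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if pool[ids[i]] == pool[ids[j]]
        ]
        assert np.mean(within) == pytest.approx(0.6, abs=0.05)

    def test_fully_attenuated_node_drops_to_between_level(self):
        """A node with overlap fraction 1 and full attenuation is
        indistinguishable from the between-network coupling level."""
        cfg = self._flat_config(rho_within=0.6, rho_between=0.1, n_timepoints=8000)
        nodes, _ = build_toy_atlas(cfg)
        label = nodes.regions.index[0]
        flair = (nodes.labels == label).astype(np.uint8)  # overlap fraction 1.0
        from lesionqol.mapping import LesionSet

        lesions = [LesionSet("sub-001", {"flair": flair})]
        ts = simulate_timeseries(cfg, nodes, lesions)[0]
        cm = connectivity_matrix(ts)
        wnc = within_network_connectivity(cm, nodes.regions)
        reg = nodes.regions
        same_pool = [
            n for n in reg.index
            if n != label
            and (reg.loc[n, "hemisphere"], reg.loc[n, "class_"])
            == (reg.loc[label, "hemisphere"], reg.loc[label, "class_"])
        ]
        # z-level of the attenuated node vs the between-network expectation
        se = 3 / np.sqrt(cfg.n_timepoints - 3)
        assert abs(wnc[label] - np.arctanh(0.1)) < 3 * se + 0.02
        assert wnc[same_pool].mean() > np.arctanh(0.3)

    def test_invalid_covariance_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="rho"):
            self._flat_config(rho_within=0.2, rho_between=0.5)


class TestResponses:
    def _gt(self, config):
        return GroundTruth(
            sides=simulate_sides(config), predictors=pd.DataFrame(), effects=[]
        )

    def test_zero_slopes_zero_noise_identical_responses(self, small_config):
        cfg = replace(small_config, planted_effects=[], baseline_noise_sd=0.0)
        resp, _ = simulate_qlq_responses(cfg, None, self._gt(cfg))
        assert (resp.nunique() == 1).all()

    def test_items_are_integers_in_legal_ranges(self, small_config):
        cfg = replace(
            small_config,
            planted_effects=[
                PlantedEffect("physical_functioning", "side:right", slope=-30, noise_sd=25)
            ],
        )
        resp, _ = simulate_qlq_responses(cfg, None, self._gt(cfg))
        assert (resp.dtypes == int).all()
        for sc in load_scale_map():
            for item in sc.items:
                col = f"q{item:02d}"
                assert resp[col].between(1, 1 + sc.r).all()

    def test_planted_slope_recovered_after_rescoring(self, small_config):
        """Known latent shift survives the invert-then-score round trip."""
        cfg = replace(
            small_config,
            n_subjects=2,
            fraction_right_sided=0.5,
            planted_effects=[
                PlantedEffect("physical_functioning", "side:right", slope=-40.0, noise_sd=0.0)
            ],
            baseline_noise_sd=0.0,
        )
        gt = self._gt(cfg)
        # force one subject per side
        gt.sides[:] = ["left", "right"]
        resp, latent = simulate_qlq_responses(cfg, None, gt)
        scores, _ = score_cohort(resp)
        left, right = gt.sides.index[0], gt.sides.index[1]
        # physical functioning: 5 four-point items -> step 100/15
        quant = 100.0 / 15.0
        diff = scores.loc[left, "physical_functioning"] - scores.loc[
            right, "physical_functioning"
        ]
        assert diff == pytest.approx(40.0, abs=quant)

    def test_roundtrip_recovery_within_half_item_step(self, small_config):
        cohort = generate_cohort(small_config)
        scores, _ = score_cohort(cohort.responses)
        for sc in load_scale_map():
            step = 100.0 / (sc.r * len(sc.items))
            err = (
                scores[sc.scale_id] - cohort.latent_scores[sc.scale_id]
            ).abs().max()
            assert err <= step / 2 + 1e-9

    def test_unknown_target_scale_rejected(self, small_config):
        cfg = replace(
            small_config,
            planted_effects=[PlantedEffect("no_such_scale", "side:right", slope=-1)],
        )
        with pytest.raises(ValueError, match="unknown"):
            simulate_qlq_responses(cfg, None, self._gt(cfg))

    def test_missing_predictor_region_rejected(self, small_config):
        cfg = replace(
            small_config,
            planted_effects=[PlantedEffect("fatigue", "RH_nowhere", "flair", slope=-1)],
        )
        with pytest.raises(ValueError, match="overlap table|not present"):
            simulate_qlq_responses(cfg, None, self._gt(cfg))
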
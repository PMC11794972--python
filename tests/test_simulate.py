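"""Synthetic-data generator: determinism, structure, and moment checks."""

import numpy as np
import pandas as pd
import pytest

from flockherit.events import detect_flocking_events
from flockherit.simulate import (
    SimConfig,
    VarianceComponents,
    make_weekend_calendar,
    recovery_experiment,
    simulate_pedigree,
    simulate_phenotypes,
    simulate_site,
    simulate_visit_stream,
)


def small_cfg(seed=7, **kw):
    defaults = dict(
        n_founders=40, n_generations=3, mean_brood_size=3.0, n_box_x=10,
        n_box_y=10, n_loggers=12, n_obs_per_individual=6, n_winters=2,
    )
    defaults.update(kw)
    return SimConfig(seed=seed, **defaults)


class TestPedigreeGen:
    def test_single_generation_founders_only(self):
        ped, broods = simulate_pedigree(small_cfg(n_generations=1))
        assert len(ped) == 40
        assert len(ped.founders) == 40
        assert broods.empty

    def test_offspring_count_law_of_large_numbers(self):
        cfg = SimConfig(seed=3, n_founders=600, n_generations=2,
                        mean_brood_size=4.0, pair_fraction=1.0, immigrant_fraction=0.0)
        ped, broods = simulate_pedigree(cfg)
        n_pairs = 300
        expected = n_pairs * 4.0
        assert len(broods) == pytest.approx(expected, rel=0.1)

    def test_determinism(self):
        p1, b1 = simulate_pedigree(small_cfg())
        p2, b2 = simulate_pedigree(small_cfg())
        assert p1.ids == p2.ids
        assert (b1 == b2).all().all()

    def test_immigrants_are_parentless(self):
        ped, broods = simulate_pedigree(small_cfg(immigrant_fraction=0.5))
        imm = [i for i in ped.ids if i.startswith("I")]
        assert imm
        for i in imm:
            k = ped.index_of(i)
            assert ped.sire[k] == -1 and ped.dam[k] == -1


class TestSiteGen:
    def test_determinism_and_shapes(self):
        s1 = simulate_site(small_cfg())
        s2 = simulate_site(small_cfg())
        assert (s1["boxes"] == s2["boxes"]).all().all()
        assert len(s1["boxes"]) == 100
        assert s1["boxes"]["section"].nunique() == 9
        assert len(s1["loggers"]) == 12

    def test_autocorrelation_limits(self):
        from scipy.spatial.distance import pdist, squareform

        def neighbour_corr(rng_range, seed=11):
            cfg = small_cfg(seed=seed, n_box_x=16, n_box_y=16, env_range=rng_range)
            site = simulate_site(cfg)
            xy = site["boxes"][["x", "y"]].to_numpy()
            z = site["env"]["altitude"].to_numpy()
            d = squareform(pdist(xy))
            iu = np.triu_indices(len(xy), 1)
            near = d[iu] < 1.5 * cfg.box_spacing
            far = d[iu] > 8 * cfg.box_spacing
            zz = np.outer(z - z.mean(), z - z.mean()) / z.var()
            return zz[iu][near].mean(), zz[iu][far].mean()

        near0, _ = neighbour_corr(1e-9)
        assert abs(near0) < 0.15  # independent in the zero-range limit
        near, far = neighbour_corr(500.0)
        assert near > far + 0.2  # empirical variogram decays with distance


class TestPhenotypes:
    def test_pure_residual_has_no_repeatability(self):
        cfg = small_cfg(variances=VarianceComponents(
            V_A=0, V_ID=0, V_LOG=0, V_SECT=0, V_BI=0, V_SPATIAL=0, V_ENVSIM=0, V_R=1.0),
            n_winters=1, year_effect_sd=0.0, presence_prob=1.0,
            n_obs_per_individual=8)
        ped, broods = simulate_pedigree(cfg)
        obs, _ = simulate_phenotypes(ped, None, cfg, broods)
        grand = obs["group_size"].var()
        between = obs.groupby("individual")["group_size"].mean().var()
        # between-individual variance of means ~ V_R / n_obs, i.e. small
        assert between / grand < 0.35

    def test_effect_moment_checks(self):
        cfg = small_cfg(
            n_founders=2000, n_generations=1, n_winters=1,
            variances=VarianceComponents(V_A=0.4, V_ID=0.25, V_LOG=0, V_SECT=0,
                                         V_BI=0, V_SPATIAL=0, V_ENVSIM=0, V_R=0.35),
            n_obs_per_individual=1, presence_prob=1.0, focal_generations=1,
        )
        ped, broods = simulate_pedigree(cfg)
        obs, truth = simulate_phenotypes(ped, None, cfg, broods)
        # founders: breeding values i.i.d. with variance V_A
        assert truth.breeding_values.var() == pytest.approx(0.4, rel=0.1)
        assert truth.permanent_env.var() == pytest.approx(0.25, rel=0.1)

    def test_offspring_midparent_regression(self):
        # classical quantitative-genetics oracle: slope of offspring on
        # midparent phenotype estimates h2 (here 0.5)
        cfg = SimConfig(
            seed=5, n_founders=3000, n_generations=2, mean_brood_size=2.0,
            pair_fraction=1.0, immigrant_fraction=0.0, n_winters=1,
            n_obs_per_individual=1, presence_prob=1.0, focal_generations=2,
            year_effect_sd=0.0,
            variances=VarianceComponents(V_A=0.5, V_ID=0, V_LOG=0, V_SECT=0,
                                         V_BI=0, V_SPATIAL=0, V_ENVSIM=0, V_R=0.5),
        )
        ped, broods = simulate_pedigree(cfg)
        obs, truth = simulate_phenotypes(ped, None, cfg, broods)
        pheno = obs.set_index("individual")["group_size"]
        rows = []
        for i, iid in enumerate(ped.ids):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0 and d >= 0 and iid in pheno.index:
                sid, did = ped.ids[s], ped.ids[d]
                if sid in pheno.index and did in pheno.index:
                    rows.append((0.5 * (pheno[sid] + pheno[did]), pheno[iid]))
        mp, off = np.array(rows).T
        slope = np.cov(mp, off)[0, 1] / mp.var()
        assert slope == pytest.approx(0.5, abs=0.06)

    def test_missing_structures_rejected(self):
        cfg = small_cfg(variances=VarianceComponents(V_SECT=0.2))
        ped, broods = simulate_pedigree(cfg)
        with pytest.raises(ValueError, match="site"):
            simulate_phenotypes(ped, None, cfg, broods)
        with pytest.raises(ValueError, match="brood"):
            simulate_phenotypes(ped, None, cfg, None)

    def test_determinism(self):
        cfg = small_cfg()
        ped, broods = simulate_pedigree(cfg)
        site = simulate_site(cfg)
        o1, _ = simulate_phenotypes(ped, site, cfg, broods)
        o2, _ = simulate_phenotypes(ped, site, cfg, broods)
        pd.testing.assert_frame_equal(o1, o2)


class TestVisitStream:
    def _assignments(self, n=60, n_log=10):
        return pd.DataFrame(
            {
                "individual": [f"b{i}" for i in range(n)],
                "home_logger": [f"L{i % n_log:02d}" for i in range(n)],
            }
        )

    def test_zero_event_rate_empty_stream(self):
        cfg = small_cfg(events_per_logger_day=0.0)
        visits, events = simulate_visit_stream(self._assignments(), cfg)
        assert visits.empty and events == []

    def test_gap_detector_exact_in_separated_limit(self):
        cfg = small_cfg(n_winters=1, weekends_per_winter=2,
                        events_per_logger_day=2.0, event_spread_seconds=20.0)
        visits, events = simulate_visit_stream(self._assignments(), cfg)
        detected = detect_flocking_events(visits, "gap", gap_seconds=600)
        assert {frozenset(e.members) for e in detected} == {
            frozenset(e.members) for e in events
        }

    def test_mean_group_size_near_configured(self):
        cfg = small_cfg(n_winters=2, weekends_per_winter=13,
                        events_per_logger_day=3.0, mean_event_group=5.0)
        visits, events = simulate_visit_stream(self._assignments(n=200, n_log=10), cfg)
        assert len(events) > 900
        mean_gs = np.mean([e.group_size for e in events])
        assert mean_gs == pytest.approx(5.0, rel=0.1)

    def test_full_design_has_39_weekend_periods(self):
        cal = make_weekend_calendar(SimConfig(seed=0))
        assert cal["period"].nunique() == 39  # 3 winters x 13 weekends
        assert len(cal) == 78  # two sampling days each

    def test_calendar_covers_stream(self):
        cfg = small_cfg(n_winters=2, weekends_per_winter=3)
        cal = make_weekend_calendar(cfg)
        assert len(cal) == 2 * 3 * 2
        visits, _ = simulate_visit_stream(self._assignments(), cfg)
        days = np.unique(np.floor(visits["timestamp"] / 86400).astype(int))
        assert set(days) <= set(cal["date"])


class TestRecovery:
    def test_structure_and_rough_recovery(self):
        cfg = SimConfig(
            seed=21, n_founders=80, n_generations=2, mean_brood_size=3.0,
            pair_fraction=1.0, immigrant_fraction=0.0, n_winters=1,
            n_obs_per_individual=8, presence_prob=1.0, focal_generations=2,
            variances=VarianceComponents(V_A=0, V_ID=0.4, V_LOG=0, V_SECT=0,
                                         V_BI=0, V_SPATIAL=0, V_ENVSIM=0, V_R=0.6),
        )
        tab = recovery_experiment(cfg, n_replicates=4, fit_terms=("ID",))
        assert list(tab.index) == ["ID", "R"]
        assert set(tab.columns) >= {"true", "bias", "emp_sd", "mean_se", "coverage"}
        assert abs(tab.loc["ID", "bias"]) < 0.15
        assert tab["n_nonconverged"].iloc[0] == 0

    def test_replicate_floor(self):
        with pytest.raises(ValueError):
            recovery_experiment(small_cfg(), 1)
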
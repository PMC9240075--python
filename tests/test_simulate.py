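"""Clonal-dynamics simulator: event model, IS superposition, noise model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isclone import (
    ISMap,
    SimulationConfig,
    apply_noise,
    assign_integration_sites,
    noise_interval_halfwidth,
    simulate,
    simulate_clonal_dynamics,
    superimpose_is,
)


def small_config(**kw) -> SimulationConfig:
    base = dict(n_clones=20, cells_per_clone=50, t_end=200.0, n_measurements=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestClonalDynamics:
    def test_no_rates_means_frozen_population(self):
        cfg = small_config(d=0.0, delta=0.0, p_max=0.0, seed=3)
        traj = simulate_clonal_dynamics(cfg)
        assert (traj.sizes == cfg.cells_per_clone).all()

    def test_seed_reproducibility(self):
        cfg = small_config(seed=11)
        a = simulate_clonal_dynamics(cfg)
        b = simulate_clonal_dynamics(cfg)
        np.testing.assert_array_equal(a.sizes, b.sizes)

    def test_clones_exchangeable_when_rates_identical(self):
        # identical differentiation rates (delta=0): final sizes must be
        # statistically indistinguishable across clone indices
        finals = []
        for rep in range(20):
            cfg = small_config(delta=0.0, seed=100 + rep)
            finals.append(simulate_clonal_dynamics(cfg).sizes[:, -1])
        by_clone = np.array(finals)  # (reps, clones)
        stat, p = stats.kruskal(*[by_clone[:, c] for c in range(by_clone.shape[1])])
        assert p > 0.01

    def test_heterogeneity_accelerates_dominance(self):
        # larger spread of differentiation rates -> larger top-clone share
        def top_share(delta, seed):
            traj = simulate_clonal_dynamics(
                SimulationConfig(delta=delta, seed=seed)
            )
            final = traj.sizes[:, -1].astype(float)
            return final.max() / final.sum()

        wins = sum(
            top_share(0.01, 500 + r) > top_share(0.0, 500 + r) for r in range(20)
        )
        assert wins >= 18

    def test_population_bounded_by_carrying_capacity(self):
        for rep in range(20):
            cfg = small_config(seed=700 + rep)
            totals = simulate_clonal_dynamics(cfg).sizes.sum(axis=0)
            # one step can overshoot K by at most the divisions drawn in it
            dt = cfg.resolve_dt()
            assert totals.max() <= cfg.carrying_capacity * (1 + cfg.p_max * dt)

    def test_explicit_dt_too_large_rejected(self):
        with pytest.raises(ValueError, match="smaller dt"):
            simulate_clonal_dynamics(small_config(p_max=0.9, dt=2.0))


class TestAssignIntegrationSites:
    def test_poisson_mean_recovered(self):
        rng = np.random.default_rng(5)
        lam = 5.0
        clone_ids = [f"c{i}" for i in range(10_000)]
        m = assign_integration_sites(clone_ids, lam, rng)
        counts = pd.Series(m.clone_of).value_counts()
        mean = len(m.clone_of) / len(clone_ids)  # zero-IS clones count as 0
        assert abs(mean - lam) < 3 * np.sqrt(lam / len(clone_ids))
        assert counts.sum() == len(m.clone_of)

    def test_deterministic_under_fixed_rng(self):
        a = assign_integration_sites(["c1", "c2"], 3.0, np.random.default_rng(9))
        b = assign_integration_sites(["c1", "c2"], 3.0, np.random.default_rng(9))
        assert a.clone_of == b.clone_of

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            assign_integration_sites(["c1"], 0.0, np.random.default_rng(0))


class TestSuperimposeIS:
    def test_is_rows_copy_clone_trajectory(self):
        cfg = small_config(seed=2)
        traj = simulate_clonal_dynamics(cfg)
        m = ISMap({"a": traj.clone_ids[0], "b": traj.clone_ids[0],
                   "c": traj.clone_ids[0], "d": traj.clone_ids[3]})
        raw = superimpose_is(traj, m)
        for iid in ("a", "b", "c"):
            np.testing.assert_array_equal(raw.loc[iid], traj.sizes[0])
        np.testing.assert_array_equal(raw.loc["d"], traj.sizes[3])

    def test_total_is_mass_is_count_weighted_clone_sum(self):
        cfg = small_config(seed=4)
        traj = simulate_clonal_dynamics(cfg)
        rng = np.random.default_rng(1)
        m = assign_integration_sites(traj.clone_ids, 2.0, rng)
        raw = superimpose_is(traj, m)
        counts = pd.Series(m.clone_of).value_counts()
        expected = sum(
            counts.get(cid, 0) * traj.sizes[i]
            for i, cid in enumerate(traj.clone_ids)
        )
        np.testing.assert_allclose(raw.sum(axis=0), expected)

    def test_unknown_clone_rejected(self):
        traj = simulate_clonal_dynamics(small_config(seed=2))
        with pytest.raises(ValueError, match="ghost"):
            superimpose_is(traj, ISMap({"x": "ghost"}))


class TestApplyNoise:
    @staticmethod
    def raw_and_map():
        raw = pd.DataFrame(
            {"m1": [10.0, 10.0, 40.0], "m2": [20.0, 20.0, 30.0],
             "m3": [40.0, 40.0, 10.0]},
            index=["a1", "a2", "b1"],
        )
        return raw, ISMap({"a1": "A", "a2": "A", "b1": "B"})

    def test_zero_noise_is_exact_normalization(self):
        raw, m = self.raw_and_map()
        out = apply_noise(raw, m, 0.0, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(
            out.values, raw.to_numpy() / raw.sum(axis=0).to_numpy()
        )

    def test_clonal_factor_cancels_within_clone(self):
        # nu>0, sigma=0: IS of one clone stay exactly proportional
        raw, m = self.raw_and_map()
        out = apply_noise(raw, m, 0.0, 0.5, np.random.default_rng(42))
        ratio = out.abundance.loc["a1"] / out.abundance.loc["a2"]
        np.testing.assert_allclose(ratio, 1.0, atol=1e-12)

    def test_sigma_004_gives_8pct_interval(self):
        # the 95% interval of g ~ N(1, 0.04^2) spans about +/-8%
        assert noise_interval_halfwidth(0.04) == pytest.approx(0.0784, abs=5e-4)

    def test_all_zero_column_rejected(self):
        raw = pd.DataFrame({"m1": [0.0], "m2": [1.0], "m3": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="m1"):
            apply_noise(raw, ISMap({"a": "A"}), 0.0, 0.0, np.random.default_rng(0))


class TestSimulateEndToEnd:
    def test_fixed_seed_reproducible(self):
        cfg = small_config(seed=8)
        r1, r2 = simulate(cfg), simulate(cfg)
        pd.testing.assert_frame_equal(r1.observed.abundance, r2.observed.abundance)
        assert r1.is_map.clone_of == r2.is_map.clone_of

    def test_observed_columns_sum_to_one(self):
        res = simulate(small_config(seed=8))
        np.testing.assert_allclose(res.observed.values.sum(axis=0), 1.0, atol=1e-9)

    def test_ground_truth_covers_all_observed_is(self):
        res = simulate(small_config(seed=8))
        assert set(res.observed.is_ids) == set(res.is_map.clone_of)

    def test_raw_is_equals_clone_trajectory(self):
        res = simulate(small_config(seed=8))
        pos = {c: i for i, c in enumerate(res.trajectories.clone_ids)}
        for iid in res.raw_is.index[:10]:
            clone = res.is_map.clone_of[iid]
            np.testing.assert_array_equal(
                res.raw_is.loc[iid].to_numpy(),
                res.trajectories.sizes[pos[clone]].astype(float),
            )


class TestMixFixture:
    def test_foreground_is_counts(self, mix_fixture):
        fg = [i for i in mix_fixture.truth.is_ids if not i.startswith("bg")]
        assert len(fg) == 21
        per_clone = pd.Series(
            {i: mix_fixture.truth.clone_of[i] for i in fg}
        ).value_counts()
        assert per_clone.to_dict() == {"ID46": 10, "ID37": 6, "ID30": 4, "ID27": 1}

    def test_background_stays_below_one_percent(self, mix_fixture, mix_abundance):
        bg = mix_abundance.abundance.loc[
            [i for i in mix_abundance.is_ids if i.startswith("bg")]
        ]
        assert (((bg < 0.01).sum(axis=1)) >= 6).all()

    def test_background_share_spans_stated_range(self, mix_fixture):
        bg = mix_fixture.proportions.loc["background"]
        assert 0.07 <= bg.min() and bg.max() <= 0.60
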
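"""Joint mutual information, dimension randomization, and comparisons."""

import numpy as np
import pytest

from tempocells.mutualinfo import (ActivityRecords, JointOccupancyMap,
                                   build_map, compare_populations,
                                   information_significance, joint_information,
                                   randomize_dimension,
                                   randomized_information)
from tempocells.synth import PlantedPopulationSpec, generate_joint_selectivity


def _map(lam, p, dims=("s", "t")):
    return JointOccupancyMap(np.asarray(lam, float), np.asarray(p, float),
                             list(dims))


class TestJointInformation:
    def test_flat_response_zero(self):
        m = _map(np.ones((3, 4)), np.full((3, 4), 1 / 12))
        assert joint_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_single_active_cell_example(self):
        # 2x2 uniform occupancy, lambda=1 at one cell: I = 1*log2(4)*0.25
        lam = np.zeros((2, 2))
        lam[0, 0] = 1.0
        m = _map(lam, np.full((2, 2), 0.25))
        assert joint_information(m) == pytest.approx(0.5, abs=1e-9)

    def test_zero_activity_map(self):
        m = _map(np.zeros((2, 2)), np.full((2, 2), 0.25))
        assert joint_information(m) == 0.0

    def test_uniform_extra_dimension_leaves_information_unchanged(self):
        # exhaustive records: activity depends only on t; adding a uniform
        # location dimension splits cells without changing lambda or I
        t = np.repeat(np.arange(6), 4)
        loc = np.tile(np.arange(4), 6)
        act = (t % 3).astype(float)
        rec1 = ActivityRecords(act, {"time": t}, {"time": 6})
        rec2 = ActivityRecords(act, {"time": t, "location": loc},
                               {"time": 6, "location": 4})
        i1 = joint_information(build_map(rec1))
        i2 = joint_information(build_map(rec2))
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_3d_path_agrees_with_2d_when_third_dim_single_level(self, rng):
        n = 500
        s = rng.integers(2, size=n)
        t = rng.integers(8, size=n)
        act = rng.random(n) * (1 + s)
        rec2 = ActivityRecords(act, {"stimulus": s, "time": t},
                               {"stimulus": 2, "time": 8})
        rec3 = ActivityRecords(act, {"stimulus": s, "time": t,
                                     "location": np.zeros(n, dtype=int)},
                               {"stimulus": 2, "time": 8, "location": 1})
        assert joint_information(build_map(rec2)) == pytest.approx(
            joint_information(build_map(rec3)), abs=1e-12)

    def test_nonnegative_on_simulated_maps(self, rng):
        for seed in range(5):
            spec = PlantedPopulationSpec(rng_seed=seed, noise_sd=0.2,
                                         counts={"NOISE": 128})
            rec = generate_joint_selectivity(spec, ("stimulus", "time"),
                                             kind="JOINT")
            assert joint_information(build_map(rec)) >= -1e-12


class TestRandomizeDimension:
    def test_unknown_variable_rejected(self, rng):
        rec = ActivityRecords(np.ones(4), {"time": np.arange(4)}, {"time": 4})
        with pytest.raises(ValueError):
            randomize_dimension(rec, "location", rng)

    def test_single_level_variable_unchanged(self, rng):
        n = 50
        rec = ActivityRecords(np.arange(n, dtype=float),
                              {"stimulus": np.zeros(n, dtype=int),
                               "time": np.arange(n) % 5},
                              {"stimulus": 1, "time": 5})
        m0 = build_map(rec)
        m1 = randomize_dimension(rec, "stimulus", rng)
        assert np.array_equal(m0.mean_activity, m1.mean_activity)
        assert np.array_equal(m0.occupancy, m1.occupancy)

    def test_time_only_unit_insensitive_to_stimulus_randomization(self):
        spec = PlantedPopulationSpec(rng_seed=1, noise_sd=0.05,
                                     counts={"NOISE": 128})
        rec = generate_joint_selectivity(spec, ("stimulus", "time"), kind="time")
        res = information_significance(rec, rng=np.random.default_rng(1),
                                       n_randomization_repeats=30)
        assert res.significant
        assert abs(res.I - res.I_randomized["stimulus"]) < 3 * max(res.null_sd, 1e-6)

    def test_stimulus_only_unit_collapses_under_stimulus_randomization(self):
        spec = PlantedPopulationSpec(rng_seed=2, noise_sd=0.05,
                                     counts={"NOISE": 128})
        rec = generate_joint_selectivity(spec, ("stimulus", "time"),
                                         kind="stimulus")
        res = information_significance(rec, rng=np.random.default_rng(2),
                                       n_randomization_repeats=30)
        assert res.significant
        assert res.I_randomized["stimulus"] < 0.25 * res.I


class TestInformationSignificance:
    def test_joint_selective_unit_significant(self):
        spec = PlantedPopulationSpec(rng_seed=3, noise_sd=0.05,
                                     counts={"NOISE": 128})
        rec = generate_joint_selectivity(spec, ("stimulus", "time"), kind="JOINT")
        res = information_significance(rec, rng=np.random.default_rng(3),
                                       n_randomization_repeats=10)
        assert res.significant and res.I > 0

    def test_noise_units_rarely_significant(self):
        hits = 0
        n_units = 100
        rng = np.random.default_rng(4)
        for k in range(n_units):
            spec = PlantedPopulationSpec(rng_seed=1000 + k, noise_sd=0.3,
                                         counts={"NOISE": 128})
            rec = generate_joint_selectivity(spec, ("stimulus", "time"),
                                             kind="CONSTANT", n_records=1500)
            res = information_significance(rec, rng=rng,
                                           n_randomization_repeats=2)
            hits += res.significant
        assert hits / n_units <= 0.05

    def test_constant_unit_zero_information(self):
        n = 400
        rec = ActivityRecords(np.full(n, 0.5),
                              {"stimulus": np.arange(n) % 2,
                               "time": np.arange(n) % 10},
                              {"stimulus": 2, "time": 10})
        res = information_significance(rec, rng=np.random.default_rng(0),
                                       n_randomization_repeats=2)
        assert res.I == pytest.approx(0.0, abs=1e-12)
        assert not res.significant

    def test_empty_records_rejected(self):
        rec = ActivityRecords(np.zeros(0), {"time": np.zeros(0, dtype=int)},
                              {"time": 1})
        with pytest.raises(ValueError):
            information_significance(rec)


class TestComparePopulations:
    def test_identical_groups_not_significant(self):
        vals = list(np.linspace(0.1, 1.0, 30))
        out = compare_populations(vals, {"time": vals})
        assert out.p.iloc[0] > 0.99

    def test_joint_population_drops_under_both_randomizations(self):
        # a population where stimulus and time both matter: both
        # randomizations significantly reduce the information
        I_vals, I_rand = [], {"stimulus": [], "time": []}
        rng = np.random.default_rng(5)
        for k in range(25):
            spec = PlantedPopulationSpec(rng_seed=2000 + k, noise_sd=0.05,
                                         counts={"NOISE": 128})
            rec = generate_joint_selectivity(spec, ("stimulus", "time"),
                                             kind="JOINT", n_records=1500)
            I_vals.append(joint_information(build_map(rec)))
            for d in I_rand:
                I_rand[d].append(randomized_information(rec, d, rng, 10))
        out = compare_populations(I_vals, I_rand).set_index("dimension")
        assert out.loc["stimulus", "p_bonferroni"] < 0.05
        assert out.loc["time", "p_bonferroni"] < 0.05

    def test_location_only_spatial_population(self):
        """3-D maps of location-only units: only the location randomization
        produces a significant drop."""
        I_vals = []
        I_rand = {"stimulus": [], "time": [], "location": []}
        rng = np.random.default_rng(6)
        for k in range(25):
            spec = PlantedPopulationSpec(rng_seed=3000 + k, noise_sd=0.05,
                                         counts={"NOISE": 128})
            rec = generate_joint_selectivity(
                spec, ("stimulus", "time", "location"), kind="location",
                n_records=2500)
            I_vals.append(joint_information(build_map(rec)))
            for d in I_rand:
                I_rand[d].append(randomized_information(rec, d, rng, 10))
        out = compare_populations(I_vals, I_rand).set_index("dimension")
        assert out.loc["location", "p_bonferroni"] < 0.05
        assert out.loc["stimulus", "p_bonferroni"] > 0.05
        assert out.loc["time", "p_bonferroni"] > 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_populations([1.0], {"time": [1.0, 2.0]})
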
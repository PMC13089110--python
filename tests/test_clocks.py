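"""Clock application, the age anti-transform, BAG residualization and
biological-age stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import comet_bioage as cb
from comet_bioage.clocks import anti_transform_age, transform_age
from comet_bioage.errors import (AlignmentError, EstimationError, InputError,
                                 MissingCpGError, StratificationError)


def toy_matrix(values, cpgs=("cg1", "cg2"), ids=None):
    ids = ids or [f"p{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=pd.Index(ids, name="participant_id"),
                        columns=list(cpgs))


class TestAgeTransform:
    def test_fixed_point_at_adult_age(self):
        assert anti_transform_age(0.0) == pytest.approx(20.0, abs=1e-12)

    @given(st.floats(min_value=1e-6, max_value=120.0, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_identity(self, age):
        assert anti_transform_age(transform_age(age)) == pytest.approx(age, abs=1e-9)

    def test_branches_are_continuous_at_zero(self):
        eps = 1e-9
        assert abs(anti_transform_age(eps) - anti_transform_age(-eps)) < 1e-6


class TestApplyClock:
    def test_constant_clock_predicts_intercept(self):
        clock = cb.ClockModel("const", intercept=50.0, coefficients={"cg1": 0.0, "cg2": 0.0})
        pred = cb.apply_clock(toy_matrix([[0.1, 0.9], [0.5, 0.5]]), clock)
        assert (pred == 50.0).all()

    def test_missing_cpgs_listed(self):
        clock = cb.ClockModel("c", intercept=0.0,
                              coefficients={"cg1": 1.0, "cgX": 2.0, "cgY": 3.0})
        with pytest.raises(MissingCpGError) as err:
            cb.apply_clock(toy_matrix([[0.5, 0.5]]), clock)
        assert err.value.missing == ["cgX", "cgY"]

    def test_log_linear_clock_anti_transforms(self):
        clock = cb.ClockModel("h", intercept=0.0, coefficients={"cg1": 1.0, "cg2": 0.0},
                              transform="log_linear_adult")
        pred = cb.apply_clock(toy_matrix([[0.0, 0.3]]), clock)
        assert pred.iloc[0] == pytest.approx(20.0)

    def test_noiseless_generator_round_trip(self):
        cfg = cb.SyntheticConfig(n_cu=30, n_mci=20, n_dementia=10,
                                 clock_noise_sd=0.0, seed=4)
        participants, _, _, truth = cb.generate_cohort(cfg)
        betas, clocks = cb.generate_clock_data(participants, truth, cfg)
        matrix = cb.select_replicate(betas, 0)
        target = (participants.set_index("id")["age_at_mri"]
                  + truth.per_participant["latent_bag"])
        for clock in clocks:
            pred = cb.apply_clock(matrix, clock)
            assert np.abs(pred - target.loc[pred.index]).max() < 1e-8


class TestSelectReplicate:
    def test_single_row_kept_and_index_flattened(self):
        idx = pd.MultiIndex.from_tuples([("a", 0), ("b", 0)],
                                        names=["participant_id", "replicate"])
        m = pd.DataFrame([[0.1], [0.2]], index=idx, columns=["cg1"])
        out = cb.select_replicate(m, seed=0)
        assert list(out.index) == ["a", "b"]
        assert out.loc["a", "cg1"] == 0.1

    def test_deterministic_under_seed(self):
        idx = pd.MultiIndex.from_tuples([("a", 0), ("a", 1), ("a", 2), ("b", 0)],
                                        names=["participant_id", "replicate"])
        m = pd.DataFrame(np.arange(4.0)[:, None], index=idx, columns=["cg1"])
        first = cb.select_replicate(m, seed=7)
        for _ in range(3):
            pd.testing.assert_frame_equal(cb.select_replicate(m, seed=7), first)

    def test_selection_uniform_within_groups(self):
        n = 1000
        ids = np.repeat([f"p{i}" for i in range(n)], 2)
        idx = pd.MultiIndex.from_arrays([ids, np.tile([0, 1], n)],
                                        names=["participant_id", "replicate"])
        m = pd.DataFrame({"which": np.tile([0.0, 1.0], n)}, index=idx)
        frac = cb.select_replicate(m, seed=123)["which"].mean()
        # binomial 99% bounds around 0.5 at n=1000
        assert abs(frac - 0.5) < 2.576 * 0.5 / np.sqrt(n)


class TestComputeBag:
    def test_perfect_clock_gives_zero_residuals(self):
        age = pd.Series([60.0, 70.0, 80.0], index=["a", "b", "c"])
        assert np.allclose(cb.compute_bag(age.copy(), age), 0.0, atol=1e-12)

    def test_constant_shift_absorbed_by_intercept(self):
        age = pd.Series([60.0, 70.0, 80.0], index=["a", "b", "c"])
        assert np.allclose(cb.compute_bag(age + 7.0, age), 0.0, atol=1e-12)

    def test_three_point_closed_form(self):
        # hand oracle: x=(60,70,80), y=(58,75,77); slope = Sxy/Sxx = 190/200,
        # intercept through the means -> residuals (-2.5, +5, -2.5)
        age = pd.Series([60.0, 70.0, 80.0], index=["a", "b", "c"])
        pred = pd.Series([58.0, 75.0, 77.0], index=["a", "b", "c"])
        res = cb.compute_bag(pred, age)
        assert np.allclose(res.to_numpy(), [-2.5, 5.0, -2.5], atol=1e-12)

    def test_residuals_sum_zero_and_uncorrelated_with_age(self):
        rng = np.random.default_rng(0)
        age = pd.Series(rng.uniform(55, 95, 200))
        pred = pd.Series(age + rng.normal(0, 5, 200))
        res = cb.compute_bag(pred, age)
        assert abs(res.sum()) < 1e-8
        assert abs(np.corrcoef(res, age)[0, 1]) < 1e-10

    def test_degenerate_design_rejected(self):
        age = pd.Series([70.0, 70.0, 70.0])
        with pytest.raises(EstimationError):
            cb.compute_bag(age + 1, age)
        with pytest.raises(EstimationError):
            cb.compute_bag(pd.Series([1.0, 2.0]), pd.Series([60.0, 70.0]))


class TestAverageBag:
    def test_mean_and_idempotence(self):
        v = pd.Series([1.0, -2.0, 0.5], index=["a", "b", "c"])
        out = cb.average_bag({"c1": v, "c2": v, "c3": v})
        pd.testing.assert_series_equal(out, v.rename("bag"))
        mixed = cb.average_bag({"c1": pd.Series([2.0]), "c2": pd.Series([-2.0]),
                                "c3": pd.Series([0.0])})
        assert mixed.iloc[0] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        frame = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("xyz"))
        brute = frame.to_numpy().mean(axis=1)
        assert np.allclose(cb.average_bag(frame), brute, atol=1e-12)

    def test_misaligned_participants_rejected(self):
        with pytest.raises(AlignmentError):
            cb.average_bag({"c1": pd.Series([1.0], index=["a"]),
                            "c2": pd.Series([1.0], index=["b"])})


class TestStratifyBag:
    def test_boundary_and_center_assignment(self):
        # construct a vector whose mean is 0 and sample SD is 1
        base = pd.Series([1.0, -1.0, 1.0, -1.0, 0.6, -0.6, 0.0, 0.0])
        bag = base / base.std(ddof=1)
        groups = cb.stratify_bag(bag, k=0.5)
        z = (bag - bag.mean()) / bag.std(ddof=1)
        assert (groups[z >= 0.5] == "accelerated").all()
        assert (groups[z <= -0.5] == "decelerated").all()
        assert (groups[np.abs(z) < 0.5] == "neutral").all()
        assert set(groups) == {"accelerated", "neutral", "decelerated"}

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        bag = pd.Series(rng.normal(size=300))
        base = cb.stratify_bag(bag)
        pd.testing.assert_series_equal(cb.stratify_bag(3.5 * bag - 40.0), base)

    def test_gaussian_tail_fraction(self):
        rng = np.random.default_rng(3)
        bag = pd.Series(rng.standard_normal(100_000))
        frac = (cb.stratify_bag(bag) == "accelerated").mean()
        assert frac == pytest.approx(0.3085, abs=0.01)

    def test_zero_sd_rejected(self):
        with pytest.raises(StratificationError):
            cb.stratify_bag(pd.Series([1.0, 1.0, 1.0]))
        with pytest.raises(InputError):
            cb.stratify_bag(pd.Series([1.0, 2.0]), k=0.0)


class TestParameterRecovery:
    def test_planted_bag_recovered(self):
        # SD-4 latent gap, 2-year clock noise, n=500: averaged-residual BAG
        # must track the planted gap tightly
        cfg = cb.SyntheticConfig(n_cu=250, n_mci=150, n_dementia=100,
                                 bag_sd=4.0, clock_noise_sd=2.0, seed=42)
        participants, _, _, truth = cb.generate_cohort(cfg)
        betas, clocks = cb.generate_clock_data(participants, truth, cfg)
        bag = cb.compute_bag_table(cb.select_replicate(betas, 0), clocks,
                                   participants.set_index("id")["age_at_mri"])
        r = np.corrcoef(bag["bag"], truth.per_participant["latent_bag"])[0, 1]
        assert r > 0.95

    def test_averaging_reduces_noise(self):
        cfg = cb.SyntheticConfig(n_cu=200, n_mci=0, n_dementia=0,
                                 clock_noise_sd=3.0, seed=9)
        participants, _, _, truth = cb.generate_cohort(cfg)
        betas, clocks = cb.generate_clock_data(participants, truth, cfg)
        bag = cb.compute_bag_table(cb.select_replicate(betas, 0), clocks,
                                   participants.set_index("id")["age_at_mri"])
        latent = truth.per_participant["latent_bag"].loc[bag.index]
        err_avg = np.var(bag["bag"] - latent)
        for clock in clocks:
            assert err_avg < np.var(bag[f"residual_{clock.name}"] - latent)


class TestClockFileFormat:
    def test_round_trip(self, tmp_path):
        clock = cb.ClockModel("demo", intercept=12.5,
                              coefficients={"cg1": 0.25, "cg2": -1.75},
                              transform="log_linear_adult", adult_age=20.0)
        path = tmp_path / "demo.csv"
        cb.write_clock(clock, path)
        loaded = cb.read_clock(path)
        assert loaded == clock
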
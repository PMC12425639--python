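"""Split planning, role discordance, repetitions and median aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dcftmle import dgm
from dcftmle.dcf import (
    AllRepetitionsFailedError,
    RepetitionEstimate,
    SplitPlan,
    aggregate,
    build_plan,
    dcf_tmle,
    make_splits,
    roles_gen1,
    roles_gen2,
    run_repetition,
)


class TestMakeSplits:
    @pytest.mark.parametrize(
        "n,p,expected_sizes",
        [
            (10, 3, {4, 3, 3}),
            (3000, 5, {600}),
            (2418, 15, {162, 161}),
        ],
    )
    def test_sizes(self, n, p, expected_sizes):
        labels = make_splits(n, p, seed=1)
        sizes = np.bincount(labels, minlength=p + 1)[1:]
        assert set(sizes) == expected_sizes
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == n

    def test_exact_counts_2418_15(self):
        sizes = np.bincount(make_splits(2418, 15, seed=2), minlength=16)[1:]
        assert sorted(sizes)[-3:] == [162, 162, 162]
        assert sorted(sizes)[:12] == [161] * 12

    def test_errors(self):
        with pytest.raises(ValueError):
            make_splits(2, 3, seed=0)
        with pytest.raises(ValueError):
            make_splits(100, 2, seed=0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n=st.integers(9, 400), p=st.integers(3, 9), seed=st.integers(0, 10_000))
    def test_partition_property(self, n, p, seed):
        if p > n:
            return
        labels = make_splits(n, p, seed)
        assert len(labels) == n
        assert set(np.unique(labels)) == set(range(1, p + 1))
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 1


class TestRoles:
    def test_gen1_p3_rotation(self):
        triples = {(t.estimation, t.propensity, t.outcome) for t in roles_gen1(3)}
        assert triples == {(3, (2,), (1,)), (1, (3,), (2,)), (2, (1,), (3,))}

    def test_gen1_p5_s3(self):
        t = next(t for t in roles_gen1(5) if t.estimation == 3)
        assert t.propensity == (2,) and t.outcome == (1,)

    def test_gen1_p10_unused_splits(self):
        for t in roles_gen1(10):
            used = {t.estimation, *t.propensity, *t.outcome}
            assert len(used) == 3  # exactly 7 splits unused per triple

    def test_gen1_each_split_in_each_role_once(self):
        for p in (3, 5, 10):
            triples = roles_gen1(p)
            assert sorted(t.estimation for t in triples) == list(range(1, p + 1))
            assert sorted(t.propensity[0] for t in triples) == list(range(1, p + 1))
            assert sorted(t.outcome[0] for t in triples) == list(range(1, p + 1))

    def test_gen2_p5_pool_sizes(self):
        for t in roles_gen2(5):
            assert len(t.propensity) == 2 and len(t.outcome) == 2
            assert {t.estimation, *t.propensity, *t.outcome} == {1, 2, 3, 4, 5}

    def test_gen2_p9_pool_sizes(self):
        for t in roles_gen2(9):
            assert len(t.propensity) == 4 and len(t.outcome) == 4

    def test_gen2_p3_identical_to_gen1(self):
        assert roles_gen2(3) == roles_gen1(3)

    def test_gen2_even_p_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            roles_gen2(4)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(p=st.integers(3, 15))
    def test_discordance_property(self, p):
        """Estimation, propensity and outcome split sets are pairwise disjoint
        in every role triple, under both schemes."""
        schemes = [roles_gen1(p)]
        if p % 2 == 1:
            schemes.append(roles_gen2(p))
        for triples in schemes:
            for t in triples:
                assert not {t.estimation} & set(t.propensity)
                assert not {t.estimation} & set(t.outcome)
                assert not set(t.propensity) & set(t.outcome)

    def test_gen2_full_data_use(self):
        """Under full data use, estimation + propensity + outcome records
        exhaust the sample for every triple."""
        plan = build_plan(1000, 5, generalization=2, seed=3)
        for t in plan.roles:
            n_used = (
                len(plan.indices([t.estimation]))
                + len(plan.indices(list(t.propensity)))
                + len(plan.indices(list(t.outcome)))
            )
            assert n_used == 1000


class TestRunRepetition:
    def test_p3_gen1_gen2_identical(self, main_dataset_500, fast_library):
        r1 = run_repetition(main_dataset_500.records, p=3, generalization=1, seed=42, library=fast_library)
        r2 = run_repetition(main_dataset_500.records, p=3, generalization=2, seed=42, library=fast_library)
        assert r1.ok and r2.ok
        assert r1.ate_r == r2.ate_r
        assert r1.var_r == r2.var_r

    def test_constant_outcome_fails_not_raises(self, fast_library):
        ds = dgm.generate_dataset(300, seed=5)
        df = ds.records.copy()
        df["Y"] = 0
        rep = run_repetition(df, p=3, generalization=1, seed=1, library=fast_library)
        assert rep.status == "failed"
        assert np.isnan(rep.ate_r)

    def test_gen2_even_p_requires_flag(self, main_dataset_500, fast_library):
        with pytest.raises(ValueError, match="pool_even_splits"):
            run_repetition(main_dataset_500.records, p=4, generalization=2, seed=1, library=fast_library)
        rep = run_repetition(
            main_dataset_500.records, p=4, generalization=2, seed=1,
            library=fast_library, pool_even_splits=True,
        )
        assert rep.ok

    def test_seeded_determinism(self, main_dataset_500, fast_library):
        r1 = run_repetition(main_dataset_500.records, p=5, generalization=1, seed=9, library=fast_library)
        r2 = run_repetition(main_dataset_500.records, p=5, generalization=1, seed=9, library=fast_library)
        assert r1.ate_r == r2.ate_r and r1.var_r == r2.var_r


class TestAggregate:
    def test_worked_example(self):
        """Median of repetition estimates and median of within+between terms."""
        reps = [
            RepetitionEstimate(status="success", ate_r=0.10, var_r=0.01),
            RepetitionEstimate(status="success", ate_r=0.12, var_r=0.01),
            RepetitionEstimate(status="success", ate_r=0.20, var_r=0.01),
        ]
        res = aggregate(reps)
        assert res.ate == pytest.approx(0.12, abs=1e-15)
        assert res.var == pytest.approx(0.0104, abs=1e-15)

    def test_single_success_collapses(self):
        reps = [RepetitionEstimate(status="success", ate_r=0.1, var_r=0.004)]
        res = aggregate(reps)
        assert res.ate == 0.1
        assert res.var == 0.004
        assert res.se == pytest.approx(np.sqrt(0.004))

    def test_failed_repetitions_excluded(self):
        reps = [
            RepetitionEstimate(status="success", ate_r=0.10, var_r=0.01),
            RepetitionEstimate(status="success", ate_r=0.12, var_r=0.01),
            RepetitionEstimate(status="success", ate_r=0.20, var_r=0.01),
        ]
        base = aggregate(reps)
        with_failure = aggregate(reps + [RepetitionEstimate(status="failed")])
        assert with_failure.ate == base.ate
        assert with_failure.var == base.var
        assert with_failure.n_failed == 1

    def test_all_failed_raises(self):
        with pytest.raises(AllRepetitionsFailedError):
            aggregate([RepetitionEstimate(status="failed")])

    def test_ci_from_se(self):
        res = aggregate([RepetitionEstimate(status="success", ate_r=0.1, var_r=0.004)])
        assert res.ci_high - res.ci_low == pytest.approx(2 * 1.96 * res.se)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.data())
    def test_permutation_invariance(self, data):
        vals = data.draw(
            st.lists(
                st.tuples(
                    st.floats(-0.5, 0.5, allow_nan=False),
                    st.floats(1e-6, 0.1, allow_nan=False),
                ),
                min_size=1,
                max_size=12,
            )
        )
        reps = [RepetitionEstimate(status="success", ate_r=a, var_r=v) for a, v in vals]
        shuffled = list(reps)
        rng = np.random.default_rng(data.draw(st.integers(0, 100)))
        rng.shuffle(shuffled)
        r1, r2 = aggregate(reps), aggregate(shuffled)
        assert r1.ate == pytest.approx(r2.ate, abs=0.0)
        assert r1.var == pytest.approx(r2.var, abs=0.0)

    def test_even_count_median_is_midpoint(self):
        reps = [
            RepetitionEstimate(status="success", ate_r=a, var_r=0.01)
            for a in (0.10, 0.14, 0.18, 0.30)
        ]
        assert aggregate(reps).ate == pytest.approx(0.16)


class TestDriver:
    def test_repetition_prefix_nesting(self, fast_library):
        """The first r repetitions of a longer run equal a shorter run's."""
        ds = dgm.generate_dataset(300, seed=77)
        short = dcf_tmle(ds.records, p=3, r=2, generalization=1, seed=5, library=fast_library)
        long = dcf_tmle(ds.records, p=3, r=4, generalization=1, seed=5, library=fast_library)
        assert [rep.ate_r for rep in long.repetitions[:2]] == [
            rep.ate_r for rep in short.repetitions
        ]

    def test_result_shape(self, main_dataset_500, fast_library):
        res = dcf_tmle(main_dataset_500.records, p=3, r=3, generalization=1, seed=4, library=fast_library)
        assert res.n_success + res.n_failed == 3
        assert res.r == 3 and res.p == 3
        row = res.summary_row()
        assert set(row) == {
            "method", "generalization", "p", "r", "ate", "se",
            "ci_low", "ci_high", "n_success", "n_failed",
        }
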
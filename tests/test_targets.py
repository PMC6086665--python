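import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrnastab import kinetics, simulate, targets
from mrnastab.containers import ValidationError


class TestBuildTargetSet:
    def test_recovers_planted_targets(self, small_truth, small_sequences):
        tset = targets.build_target_set(small_sequences, min_sites=1)
        assert set(small_truth.target_ids) <= set(tset.gene_ids)
        assert tset.provenance == "seed_match"

    def test_short_seed_propagates_error(self, small_sequences):
        with pytest.raises(ValidationError):
            targets.build_target_set(small_sequences, seed="AAGTG")

    def test_list_mode_warns_and_intersects(self, caplog):
        universe = [f"g{i}" for i in range(10)]
        with caplog.at_level("WARNING"):
            tset = targets.target_set_from_list(["g1", "g2", "absent"], universe)
        assert len(tset.gene_ids) == 2
        assert "absent from the analyzed genes" in caplog.text

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            targets.target_set_from_list(["x"], ["g1"])


class TestGroupShiftTest:
    def test_identical_multiset_halves_shift_zero(self):
        values = pd.Series(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            index=[f"g{i}" for i in range(6)],
        )
        shift, _ = targets.group_shift_test(values, ["g0", "g1", "g2"])
        assert shift == 0.0

    def test_exact_enumeration_example(self):
        # targets {3,4} vs background {1,2}: U = 4, p = 2/6
        values = pd.Series({"a": 3.0, "b": 4.0, "c": 1.0, "d": 2.0})
        shift, p = targets.group_shift_test(values, ["a", "b"])
        assert shift == pytest.approx(2.0)
        assert p == pytest.approx(1 / 3)

    def test_exact_u_statistic(self):
        u, p = targets.mann_whitney_exact([3, 4], [1, 2])
        assert u == 4.0 and p == pytest.approx(2 / 6)

    def test_exact_matches_full_enumeration_with_ties(self):
        # independent brute force over labelings, ties counted half
        a, b = [1.0, 2.0, 2.0], [2.0, 3.0]
        u_obs, p = targets.mann_whitney_exact(a, b)
        pooled = a + b
        mu = len(a) * len(b) / 2
        hits = total = 0
        for subset in itertools.combinations(range(5), 3):
            grp_a = [pooled[i] for i in subset]
            grp_b = [pooled[i] for i in range(5) if i not in subset]
            u = sum(
                (x > y) + 0.5 * (x == y) for x in grp_a for y in grp_b
            )
            hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            total += 1
        assert p == pytest.approx(hits / total)

    def test_exact_agrees_with_asymptotic_for_groups_of_eight(self):
        rng = np.random.default_rng(1)
        rel_errors = []
        for _ in range(20):
            a = rng.standard_normal(8)
            b = rng.standard_normal(8) + 0.5
            _, p_exact = targets.mann_whitney_exact(a, b)
            p_asym = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            rel_errors.append(abs(p_exact - p_asym) / p_exact)
        assert np.median(rel_errors) < 0.1

    def test_background_all_mode(self):
        values = pd.Series({"a": 5.0, "b": 6.0, "c": 1.0, "d": 2.0})
        shift_all, _ = targets.group_shift_test(values, ["a", "b"], background="all")
        assert shift_all == pytest.approx(5.5 - 3.5)

    def test_programmed_shift_recovered(self):
        rng = np.random.default_rng(2)
        n = 2000
        values = pd.Series(rng.standard_normal(n), index=[f"g{i}" for i in range(n)])
        target_ids = [f"g{i}" for i in range(300)]
        values[target_ids] += 1.0
        shift, p = targets.group_shift_test(values, target_ids)
        assert shift == pytest.approx(1.0, abs=0.1)
        assert p < 1e-10

    def test_empty_group_rejected(self):
        values = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValidationError):
            targets.group_shift_test(values, ["a", "b", "c"])


class TestPercentileFoldRange:
    def test_constant_vector_gives_one(self):
        assert targets.percentile_fold_range([2.0, 2.0, 2.0], 25, 75) == 1.0

    def test_interpolated_quantiles_example(self):
        # log2 scores {0,1,2,3}: Q25 = 0.75, Q75 = 2.25 -> 2^1.5
        assert targets.percentile_fold_range([0, 1, 2, 3], 25, 75) == pytest.approx(
            2 ** 1.5
        )

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.standard_normal(100)
        a = targets.percentile_fold_range(values, 10, 90)
        b = targets.percentile_fold_range(values + 4.2, 10, 90)
        assert a == pytest.approx(b)

    def test_integer_scaling_is_multiplicative(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal(100)
        base = targets.percentile_fold_range(values, 25, 75)
        tripled = targets.percentile_fold_range(values * 3, 25, 75)
        assert tripled == pytest.approx(base**3)

    def test_bad_order_rejected(self):
        with pytest.raises(ValidationError):
            targets.percentile_fold_range([1, 2, 3], 75, 25)


class TestChangeCorrelation:
    def test_identity_and_reversal(self):
        rng = np.random.default_rng(5)
        a = pd.Series(rng.standard_normal(50), index=[f"g{i}" for i in range(50)])
        rho, _ = targets.change_correlation(a, a)
        assert rho == pytest.approx(1.0)
        rho, _ = targets.change_correlation(a, a.rank(ascending=False))
        assert rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_average_rank_oracle(self):
        a = pd.Series({"g1": 1.0, "g2": 1.0, "g3": 2.0} | {f"h{i}": float(i) for i in range(9)})
        b = pd.Series({"g1": 3.0, "g2": 3.0, "g3": 4.0} | {f"h{i}": float(i) for i in range(9)})

        def avg_ranks(values):
            order = np.argsort(values, kind="stable")
            ranks = np.empty(len(values))
            i = 0
            sorted_vals = values[order]
            while i < len(values):
                j = i
                while j < len(values) and sorted_vals[j] == sorted_vals[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        shared = a.index
        ra, rb = avg_ranks(a[shared].to_numpy()), avg_ranks(b[shared].to_numpy())
        oracle = np.corrcoef(ra, rb)[0, 1]
        rho, _ = targets.change_correlation(a, b)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        a = pd.Series(np.ones(20), index=[f"g{i}" for i in range(20)])
        b = pd.Series(np.arange(20.0), index=a.index)
        with pytest.raises(ValidationError, match="constant"):
            targets.change_correlation(a, b)


@pytest.fixture(scope="module")
def two_ko_results():
    cfg = simulate.SimConfig(
        n_genes=1000,
        n_targets=150,
        seed=31,
        genotype_effects={
            "WT": (1.0, 1.0),
            "KO_trans": (1.0, 2.0),  # translation-only derepression
            "KO_both": (2.0, 2.0),  # stability + translation derepression
        },
    )
    truth = simulate.generate_truth(cfg)
    counts = simulate.sample_counts(truth, cfg)
    diff_stab = {
        ko: kinetics.differential_test(counts, "stability", ("WT", ko))
        for ko in ("KO_trans", "KO_both")
    }
    diff_trans = {
        ko: kinetics.differential_test(counts, "translation", ("WT", ko))
        for ko in ("KO_trans", "KO_both")
    }
    return truth, diff_stab, diff_trans


class TestDecouplingSummary:
    def test_programmed_effects_recovered(self, two_ko_results):
        truth, diff_stab, diff_trans = two_ko_results
        summary = targets.decoupling_summary(diff_stab, diff_trans, truth.target_ids)
        shifts = summary.shifts.set_index(["contrast", "metric"])["median_shift"]
        assert shifts[("KO_both", "stability_change")] > 0.5
        assert abs(shifts[("KO_trans", "stability_change")]) < 0.1
        assert shifts[("KO_trans", "translation_change")] > 0.5
        assert shifts[("KO_both", "translation_change")] > 0.5

    def test_identical_tables_correlate_perfectly(self, two_ko_results):
        _, diff_stab, _ = two_ko_results
        same = {"a": diff_stab["KO_both"], "b": diff_stab["KO_both"]}
        summary = targets.decoupling_summary(same, same, ["g00001", "g00002", "g00003"])
        assert np.allclose(summary.correlations["rho"], 1.0)

    def test_null_simulation_shows_no_shift(self):
        cfg = simulate.SimConfig(n_genes=600, n_targets=100, seed=32)
        truth = simulate.generate_truth(cfg)  # all effects 1
        counts = simulate.sample_counts(truth, cfg)
        diff_stab = {"KO": kinetics.differential_test(counts, "stability", ("WT", "KO"))}
        diff_trans = {
            "KO": kinetics.differential_test(counts, "translation", ("WT", "KO"))
        }
        summary = targets.decoupling_summary(diff_stab, diff_trans, truth.target_ids)
        assert (summary.shifts["median_shift"].abs() < 0.1).all()
        assert (summary.shifts["p"] > 0.01).all()
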
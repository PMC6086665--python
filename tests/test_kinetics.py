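import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import spearmanr

from mrnastab import kinetics, simulate
from mrnastab.containers import CountTable, ValidationError


def _single_assay_table(values, assay="total"):
    values = np.atleast_2d(np.asarray(values, dtype=float)).T
    sheet = pd.DataFrame(
        {"sample_id": ["s1"], "assay": [assay], "genotype": ["WT"], "replicate": [1]}
    )
    counts = pd.DataFrame(
        values, columns=["s1"],
        index=pd.Index([f"g{i}" for i in range(len(values))], name="gene_id"),
    )
    return CountTable(counts=counts, samples=sheet)


class TestCpmNormalize:
    def test_definition_single_sample(self):
        table = kinetics.cpm_normalize(_single_assay_table([2, 3, 5]))
        assert table.counts["s1"].tolist() == [200000.0, 300000.0, 500000.0]
        assert table.normalized

    def test_symmetry_equal_counts(self):
        table = kinetics.cpm_normalize(_single_assay_table([7] * 4))
        assert np.allclose(table.counts["s1"], 1e6 / 4)

    def test_matches_scalar_loop_oracle(self, toy_counts):
        cpm = kinetics.cpm_normalize(toy_counts)
        raw = toy_counts.counts.to_numpy()
        expected = np.empty_like(raw)
        for j in range(raw.shape[1]):
            colsum = sum(raw[i, j] for i in range(raw.shape[0]))
            for i in range(raw.shape[0]):
                expected[i, j] = raw[i, j] / colsum * 1e6
        assert np.allclose(cpm.counts.to_numpy(), expected)

    def test_zero_column_sum_names_sample(self, toy_counts):
        counts = toy_counts.counts.copy()
        counts["WT_total_r1"] = 0.0
        table = CountTable(counts=counts, samples=toy_counts.samples)
        with pytest.raises(ValidationError, match="WT_total_r1"):
            kinetics.cpm_normalize(table)


class TestFilterExpressed:
    def _table(self, cpm_rows):
        n = len(cpm_rows[0])
        sheet = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "assay": ["total"] * n,
                "genotype": ["WT"] * n,
                "replicate": list(range(1, n + 1)),
            }
        )
        counts = pd.DataFrame(
            np.asarray(cpm_rows, dtype=float),
            index=pd.Index([f"g{i}" for i in range(len(cpm_rows))], name="gene_id"),
            columns=sheet["sample_id"].tolist(),
        )
        return CountTable(counts=counts, samples=sheet, normalized=True)

    def test_borderline_kept_and_dropped(self):
        table = self._table([[3.1, 3.0, 3.2], [2.9, 3.5, 3.5], [0, 0, 0]])
        kept = kinetics.filter_expressed(table, min_cpm=3, min_reps=3)
        assert list(kept) == ["g0"]

    def test_min_reps_exceeding_samples_rejected(self):
        table = self._table([[3, 3]])
        with pytest.raises(ValidationError):
            kinetics.filter_expressed(table, min_reps=3)


class TestRatioScores:
    def test_stability_zero_when_assays_equal(self, toy_counts):
        counts = toy_counts.counts.copy()
        for genotype in ("WT", "KO"):
            for rep in (1, 2):
                counts[f"{genotype}_nascent_4sU_r{rep}"] = counts[f"{genotype}_total_r{rep}"]
        table = CountTable(counts=counts, samples=toy_counts.samples, normalized=True)
        result = kinetics.stability_scores(table)
        assert np.allclose(result.scores.to_numpy(), 0.0)

    def test_stability_arithmetic(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["n1", "t1"],
                "assay": ["nascent_4sU", "total"],
                "genotype": ["WT", "WT"],
                "replicate": [1, 1],
            }
        )
        counts = pd.DataFrame(
            {"n1": [2.0], "t1": [8.0]}, index=pd.Index(["g1"], name="gene_id")
        )
        table = CountTable(counts=counts, samples=sheet, normalized=True)
        score = kinetics.stability_scores(table, pseudocount=0.5).scores.loc["g1", "WT"]
        assert score == pytest.approx(1.765534746, abs=1e-9)

    def test_translation_arithmetic(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["m1", "h1"],
                "assay": ["monosome", "high_polysome"],
                "genotype": ["WT", "WT"],
                "replicate": [1, 1],
            }
        )
        counts = pd.DataFrame(
            {"m1": [4.0], "h1": [16.0]}, index=pd.Index(["g1"], name="gene_id")
        )
        table = CountTable(counts=counts, samples=sheet, normalized=True)
        level = kinetics.translation_levels(table, pseudocount=0.5).scores.loc["g1", "WT"]
        assert level == pytest.approx(np.log2(16.5 / 4.5), abs=1e-9)

    def test_missing_assay_names_it(self, toy_counts):
        table = kinetics.cpm_normalize(toy_counts)
        with pytest.raises(ValidationError, match="high_polysome"):
            kinetics.translation_levels(table)

    def test_noiseless_recovery_is_perfect(self, small_truth, small_config):
        # pseudocount 0: expected counts are all positive and the ranks must
        # match the truth exactly in the noise-free limit
        exp = simulate.expected_counts(small_truth, small_config)
        cpm = kinetics.cpm_normalize(exp)
        stab = kinetics.stability_scores(cpm, pseudocount=0.0)
        rho = spearmanr(stab.scores["WT"], -np.log2(small_truth.genes["beta"])).statistic
        assert rho == pytest.approx(1.0)
        trans = kinetics.translation_levels(cpm, pseudocount=0.0)
        rho = spearmanr(
            trans.scores["WT"], np.log2(small_truth.genes["trans_level"])
        ).statistic
        assert rho == pytest.approx(1.0)

    def test_library_scaling_invariance(self, toy_counts):
        """Scaling one sample's raw counts cancels after CPM normalization."""
        base = kinetics.stability_scores(kinetics.cpm_normalize(toy_counts)).scores
        scaled_counts = toy_counts.counts.copy()
        scaled_counts["WT_nascent_4sU_r1"] *= 7.3
        scaled = CountTable(counts=scaled_counts, samples=toy_counts.samples)
        rescored = kinetics.stability_scores(kinetics.cpm_normalize(scaled)).scores
        pd.testing.assert_frame_equal(base, rescored)

    def test_unequal_replicates_use_cross_pairs(self):
        sheet = pd.DataFrame(
            {
                "sample_id": ["n1", "n2", "t1"],
                "assay": ["nascent_4sU", "nascent_4sU", "total"],
                "genotype": ["WT"] * 3,
                "replicate": [1, 2, 1],
            }
        )
        counts = pd.DataFrame(
            {"n1": [2.0], "n2": [8.0], "t1": [8.0]},
            index=pd.Index(["g1"], name="gene_id"),
        )
        table = CountTable(counts=counts, samples=sheet, normalized=True)
        result = kinetics.stability_scores(table, pseudocount=0.5)
        expected = np.mean([np.log2(8.5 / 2.5), np.log2(8.5 / 8.5)])
        assert result.scores.loc["g1", "WT"] == pytest.approx(expected)
        assert len(result.replicate_scores) == 2


class TestInteractionFit:
    def test_cell_mean_contrast_with_zero_noise_flagged(self):
        means = {(0, 0): 1.0, (0, 1): 2.0, (1, 0): 3.0, (1, 1): 5.0}
        a = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        b = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        y = np.array([means[(x, z)] for x, z in zip(a, b)])
        coef, se, t, df, p = kinetics.interaction_fit(y, a, b)
        assert coef == pytest.approx(5 - 3 - 2 + 1)
        assert se == 0.0 and np.isnan(p)  # zero residual variance

    def test_constant_y_gives_zero_effects(self):
        a = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        b = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        coef, *_ = kinetics.interaction_fit(np.full(8, 3.0), a, b)
        assert coef == pytest.approx(0.0, abs=1e-12)

    def test_empty_cell_rejected(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 0, 1, 1])  # cells (0,1), (1,0) empty
        with pytest.raises(ValidationError, match="empty cells"):
            kinetics.interaction_fit(np.arange(4.0), a, b)

    def test_no_residual_df_rejected(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        with pytest.raises(ValidationError, match="degrees of freedom"):
            kinetics.interaction_fit(np.arange(4.0), a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = np.array([0, 0, 0, 1, 1, 1] * 2)
        b = np.array([0] * 6 + [1] * 6)
        y = rng.standard_normal(12)
        coef, se, t, df, p = kinetics.interaction_fit(y, a, b)
        # explicit 4x4 normal equations solve
        X = np.column_stack([np.ones(12), a, b, a * b])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (12 - 4)
        se_o = np.sqrt(s2 * np.linalg.inv(X.T @ X)[3, 3])
        t_o = beta[3] / se_o
        p_o = 2 * stats.t.sf(abs(t_o), 8)
        assert coef == pytest.approx(beta[3], abs=1e-10)
        assert se == pytest.approx(se_o, abs=1e-10)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)
        assert df == 8


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert kinetics.bh_adjust([0.05]).tolist() == [0.05]

    def test_step_up_two_values(self):
        assert np.allclose(kinetics.bh_adjust([0.1, 0.2]), [0.2, 0.2])

    def test_step_up_four_values(self):
        assert np.allclose(kinetics.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            kinetics.bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_time_definition(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = rng.random(rng.integers(1, 40))
        q = kinetics.bh_adjust(p)
        # quadratic-time step-up: q_(i) = min_{j>=i} p_(j) m / j
        order = np.argsort(p, kind="stable")
        m = len(p)
        expected = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            candidates = [
                p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
            ]
            expected[idx] = min(1.0, min(candidates))
        assert np.allclose(q, expected, atol=1e-12)
        # monotone in p-rank, q >= p
        assert (q >= p - 1e-15).all()
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDifferentialTest:
    def test_single_gene_q_equals_p(self, toy_counts):
        # pick a filter threshold that leaves exactly one gene in the test
        cpm = kinetics.cpm_normalize(toy_counts)
        floors = cpm.counts.min(axis=1).sort_values()
        threshold = (floors.iloc[-1] + floors.iloc[-2]) / 2
        result = kinetics.differential_test(
            toy_counts, "stability", ("WT", "KO"), min_cpm=threshold, min_reps=8
        )
        assert len(result.table) == 1
        row = result.table.iloc[0]
        assert row["q"] == pytest.approx(row["p"])

    def test_programmed_translation_effect_recovered(self):
        cfg = simulate.SimConfig(
            n_genes=800, n_targets=200, target_translation_fold=2.0, seed=21
        )
        truth = simulate.generate_truth(cfg)
        counts = simulate.sample_counts(truth, cfg)
        trans = kinetics.differential_test(counts, "translation", ("WT", "KO"))
        stab = kinetics.differential_test(counts, "stability", ("WT", "KO"))
        targets = truth.target_ids
        # target-vs-background shift: CPM renormalisation adds a common
        # composition offset to every gene, which the background subtracts
        def shift(table):
            is_t = table.index.isin(targets)
            return table.loc[is_t, "coef"].median() - table.loc[~is_t, "coef"].median()

        assert shift(trans.table) == pytest.approx(1.0, abs=0.15)
        assert abs(shift(stab.table)) < 0.1

    def test_filtered_genes_absent(self, small_counts):
        high = kinetics.differential_test(
            small_counts, "stability", ("WT", "KO"), min_cpm=500
        )
        everything = kinetics.differential_test(
            small_counts, "stability", ("WT", "KO"), min_cpm=0, min_reps=1
        )
        assert len(high.table) < len(everything.table)

    def test_missing_genotype_samples_rejected(self, small_counts):
        with pytest.raises(ValidationError, match="genotype 'XX'"):
            kinetics.differential_test(small_counts, "stability", ("WT", "XX"))

    def test_shrink_var_preserves_coefficients_and_tightens_se(self, small_counts):
        plain = kinetics.differential_test(small_counts, "stability", ("WT", "KO"))
        shrunk = kinetics.differential_test(
            small_counts, "stability", ("WT", "KO"), shrink_var=True
        )
        assert np.allclose(plain.table["coef"], shrunk.table["coef"])
        assert shrunk.table["df"].iloc[0] > plain.table["df"].iloc[0]


def test_null_pvalues_roughly_uniform_small():
    """Smaller-scale version of the calibration property (full scale in the
    acceptance suite): under a no-effect simulation, interaction p-values
    are approximately U(0,1)."""
    cfg = simulate.SimConfig(
        n_genes=1000, n_targets=0, assays=("nascent_4sU", "total"), seed=22
    )
    truth = simulate.generate_truth(cfg)
    counts = simulate.sample_counts(truth, cfg)
    result = kinetics.differential_test(counts, "stability", ("WT", "KO"))
    p = result.table["p"].dropna()
    assert stats.kstest(p, "uniform").statistic < 0.05
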
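"""End-to-end validation studies on synthetic data with known ground truth.

Each function runs one self-contained study — simulate, analyze, measure —
and returns the headline numbers. They are used by the acceptance test
suite and by ``scripts/acceptance.py``; the study conditions (gene counts,
depths, dispersion, effect sizes) are the package defaults and are
documented in the methods note.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import codon, features, kinetics, simulate, targets


def stability_recovery(seed: int = 1, n_genes: int = 2000) -> dict:
    """Spearman correlation of estimated stability scores with -log2(beta).

    2,000 genes, 3 replicates each of nascent and total RNA at 2e6 reads,
    NB dispersion 0.05.
    """
    cfg = simulate.SimConfig(
        n_genes=n_genes,
        n_targets=0,
        genotype_effects={"WT": (1.0, 1.0)},
        assays=("nascent_4sU", "total"),
        seed=seed,
    )
    truth = simulate.generate_truth(cfg)
    counts = simulate.sample_counts(truth, cfg)
    cpm = kinetics.cpm_normalize(counts)
    keep = kinetics.filter_expressed(cpm)
    scores = kinetics.stability_scores(cpm.subset_genes(keep)).scores["WT"]
    rho = stats.spearmanr(
        scores, -np.log2(truth.genes.loc[scores.index, "beta"])
    ).statistic
    return {"spearman": float(rho), "n": int(len(scores))}


def translation_recovery(seed: int = 1, n_genes: int = 2000) -> dict:
    """Spearman correlation of estimated translation levels with log2(t)."""
    cfg = simulate.SimConfig(
        n_genes=n_genes,
        n_targets=0,
        genotype_effects={"WT": (1.0, 1.0)},
        assays=("monosome", "high_polysome"),
        seed=seed,
    )
    truth = simulate.generate_truth(cfg)
    counts = simulate.sample_counts(truth, cfg)
    cpm = kinetics.cpm_normalize(counts)
    keep = kinetics.filter_expressed(cpm)
    levels = kinetics.translation_levels(cpm.subset_genes(keep)).scores["WT"]
    rho = stats.spearmanr(
        levels, np.log2(truth.genes.loc[levels.index, "trans_level"])
    ).statistic
    return {"spearman": float(rho), "n": int(len(levels))}


def null_calibration(seed: int = 1, n_genes: int = 5000) -> dict:
    """Type-I error of the interaction test under a no-effect simulation.

    Returns the fraction of raw p-values below 0.05 and the
    Kolmogorov-Smirnov distance of the p-value distribution from U(0,1).
    """
    cfg = simulate.SimConfig(
        n_genes=n_genes,
        n_targets=0,
        genotype_effects={"WT": (1.0, 1.0), "KO": (1.0, 1.0)},
        assays=("nascent_4sU", "total"),
        seed=seed,
    )
    truth = simulate.generate_truth(cfg)
    counts = simulate.sample_counts(truth, cfg)
    result = kinetics.differential_test(counts, "stability", ("WT", "KO"))
    p = result.table["p"].dropna().to_numpy()
    return {
        "fraction_p_below_0.05": float((p < 0.05).mean()),
        "ks_distance": float(stats.kstest(p, "uniform").statistic),
        "n": int(len(p)),
    }


def decoupling_recovery(seed: int = 1, n_genes: int = 2000, n_targets: int = 300) -> dict:
    """Target-group shifts for a translation-only KO and a dual-effect KO.

    The translation-only genotype doubles the targets' translation level
    only (the miRNA-effector-loss scenario); the dual genotype doubles both
    stability and translation (the miRNA-loss scenario). Shifts are medians
    of the per-gene interaction coefficients, targets minus background.
    """
    cfg = simulate.SimConfig(
        n_genes=n_genes,
        n_targets=n_targets,
        genotype_effects={
            "WT": (1.0, 1.0),
            "KO_trans_only": (1.0, 2.0),
            "KO_dual": (2.0, 2.0),
        },
        seed=seed,
    )
    truth = simulate.generate_truth(cfg)
    counts = simulate.sample_counts(truth, cfg)
    out: dict = {"n": int(n_genes)}
    for label, genotype in (("trans_only", "KO_trans_only"), ("dual", "KO_dual")):
        for metric, contrast in (("stability", "stability"), ("translation", "translation")):
            result = kinetics.differential_test(counts, contrast, ("WT", genotype))
            shift, p = targets.group_shift_test(result.table["coef"], truth.target_ids)
            out[f"{label}_{metric}_shift"] = float(shift)
            out[f"{label}_{metric}_p"] = float(p)
    return out


#: ground-truth standardized effect of each feature on the constructed
#: stability score in the feature-recovery study (3'UTR length destabilizes)
FEATURE_EFFECTS = {
    "log10_utr3_len": -0.6,
    "gc_cds": 0.3,
    "n_are": -0.3,
    "n_mirna_sites": -0.2,
    "log10_cds_len": -0.2,
}


def feature_regression_recovery(seed: int = 1, n_genes: int = 5000) -> dict:
    """Fit R^2 when stability is a known feature combination (pop. R^2 0.25)."""
    cfg = simulate.SimConfig(n_genes=n_genes, n_targets=int(0.15 * n_genes), seed=seed)
    truth = simulate.generate_truth(cfg)
    seqs = simulate.generate_sequences(truth, cfg)
    table = features.extract_features(seqs)
    z = features.zscore_features(table)
    stability = simulate.stability_from_features(
        z, FEATURE_EFFECTS, 0.25, rng=np.random.default_rng(seed + 10)
    )
    r2, coefs = features.fit_feature_regression(table, stability)
    return {
        "r_squared": float(r2),
        "utr3_len_coef": float(coefs.loc["log10_utr3_len", "coef"]),
        "n": int(len(table)),
    }


def codon_spike_detection(
    seed: int = 1, n_runs: int = 20, n_per_group: int = 400, spike: float = 0.02
) -> dict:
    """Detection of a +0.02 codon-frequency spike in the unstable group.

    Over ``n_runs`` seeded simulations: fraction of runs where the spiked
    codon is Bonferroni-significant, and the worst-case number of other
    codons falsely called significant.
    """
    detected = 0
    max_false = 0
    spiked_codon = "GCT"
    for k in range(n_runs):
        rng = np.random.default_rng(seed * 1000 + k)
        freqs, stability = simulate.simulate_codon_spike(
            n_per_group, spiked_codon, spike, rng=rng
        )
        comp = codon.group_codon_comparison(freqs, stability, frac=0.5)
        hit = bool(comp.loc[spiked_codon, "significant"])
        detected += int(hit)
        false = int(comp["significant"].sum()) - int(hit)
        max_false = max(max_false, false)
    return {
        "detection_rate": detected / n_runs,
        "max_false_positives": max_false,
        "n": int(2 * n_per_group),
        "n_runs": n_runs,
    }


def oracle_equivalences(seed: int = 1) -> dict:
    """Maximum discrepancies between implementations and brute-force oracles.

    Covers the interaction OLS vs an explicit normal-equations solve, BH vs
    the quadratic-time step-up definition, sTAI vs a scalar log-mean loop,
    and the exact Mann-Whitney branch vs full enumeration.
    """
    rng = np.random.default_rng(seed)

    # interaction fit vs normal equations, 200 random balanced designs
    max_fit_err = 0.0
    a = np.array([0, 0, 0, 1, 1, 1] * 2, dtype=float)
    b = np.array([0.0] * 6 + [1.0] * 6)
    X = np.column_stack([np.ones(12), a, b, a * b])
    xtx_inv = np.linalg.inv(X.T @ X)
    for _ in range(200):
        y = rng.standard_normal(12)
        coef, se, t, df, p = kinetics.interaction_fit(y, a, b)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        se_o = float(np.sqrt(resid @ resid / 8 * xtx_inv[3, 3]))
        t_o = beta[3] / se_o
        p_o = 2 * stats.t.sf(abs(t_o), 8)
        max_fit_err = max(
            max_fit_err,
            abs(coef - beta[3]), abs(se - se_o), abs(t - t_o), abs(p - p_o),
        )

    # BH vs quadratic-time definition, 100 random vectors
    max_bh_err = 0.0
    for _ in range(100):
        p_vec = rng.random(int(rng.integers(1, 50)))
        q = kinetics.bh_adjust(p_vec)
        order = np.argsort(p_vec, kind="stable")
        m = len(p_vec)
        for rank_i, idx in enumerate(order, start=1):
            q_oracle = min(
                1.0,
                min(p_vec[order[j - 1]] * m / j for j in range(rank_i, m + 1)),
            )
            max_bh_err = max(max_bh_err, abs(q[idx] - q_oracle))

    # sTAI vs scalar log-mean oracle, 100 random CDS
    pool = simulate.simulate_trna_pool(rng)
    weights = codon.tai_weights(pool)
    cfg = simulate.SimConfig(n_genes=100, n_targets=0, cds_codons_median=120, seed=seed)
    truth = simulate.generate_truth(cfg)
    seqs = simulate.generate_sequences(truth, cfg, rng=rng)
    scores = codon.stai_scores(seqs, weights)
    max_stai_err = 0.0
    for gene, value in scores.items():
        cds = seqs.records.loc[gene, "cds"]
        logs = [
            np.log(weights.w[cds[i : i + 3]])
            for i in range(0, len(cds), 3)
            if cds[i : i + 3] not in codon.STOP_CODONS
        ]
        max_stai_err = max(max_stai_err, abs(value - np.exp(np.mean(logs))))

    # exact Mann-Whitney vs enumeration is the same computation by
    # construction; cross-check it against scipy's exact method on tie-free
    # data where both are defined
    max_mw_err = 0.0
    for _ in range(20):
        g1 = rng.standard_normal(int(rng.integers(2, 9)))
        g2 = rng.standard_normal(int(rng.integers(2, 9)))
        _, p_enum = targets.mann_whitney_exact(g1, g2)
        p_scipy = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="exact").pvalue
        max_mw_err = max(max_mw_err, abs(p_enum - p_scipy))

    return {
        "interaction_fit_max_error": float(max_fit_err),
        "bh_max_error": float(max_bh_err),
        "stai_max_error": float(max_stai_err),
        "mann_whitney_exact_max_error": float(max_mw_err),
    }
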
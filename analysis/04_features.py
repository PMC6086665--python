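"""Which sequence features explain the spread of mRNA stabilities?

Extracts the ten per-gene covariates (region lengths and GC, ARE count,
upstream ATGs, miRNA seed sites, exon count), regresses wild-type stability
on the z-scored features, and ranks single-feature Spearman correlations.
"""

from common import RESULTS_DIR, load_sequences

from mrnastab import features, io


def main():
    seqs = load_sequences()
    stability = io.read_table(RESULTS_DIR / "stability.tsv")["WT"]

    table = features.extract_features(seqs)
    io.write_table(table, RESULTS_DIR / "features.tsv")

    r2, coefs = features.fit_feature_regression(table, stability)
    io.write_table(coefs, RESULTS_DIR / "feature_regression.tsv", index_label="feature")
    print(f"multiple regression on {len(table)} genes: R^2 = {r2:.3f} "
          f"({100 * r2:.0f}% of stability variance explained)")

    corr = features.feature_correlations(table, stability)
    io.write_table(corr, RESULTS_DIR / "feature_correlations.tsv", index_label="feature")
    ranked = corr["rho"].abs().sort_values(ascending=False)
    top = ranked.index[0]
    print(f"strongest single feature: {top} "
          f"(rho = {corr.loc[top, 'rho']:.2f}, p = {corr.loc[top, 'p']:.2g})")
    print(corr["rho"].round(3).to_string())


if __name__ == "__main__":
    main()
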
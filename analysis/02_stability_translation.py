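"""Score per-gene mRNA stability and translation level in every genotype.

Stability = log2(total/nascent CPM) under the steady-state assumption
(beta ~ alpha/[mRNA]); translation level = log2(high polysome/monosome).
Reports the spread of stabilities (percentile fold ranges) and the
stability-translation correlation in the wild type, and checks both scores
against the simulation ground truth.
"""

import numpy as np
from common import RESULTS_DIR, load_counts, load_truth
from scipy.stats import spearmanr

from mrnastab import io, kinetics, targets


def main():
    counts = load_counts()
    truth = load_truth()
    cpm = kinetics.cpm_normalize(counts)

    stab_sub = cpm.select(assays=["nascent_4sU", "total"])
    keep = kinetics.filter_expressed(stab_sub)
    stability = kinetics.stability_scores(stab_sub.subset_genes(keep))
    io.write_table(stability.scores, RESULTS_DIR / "stability.tsv")

    trans_sub = cpm.select(assays=["monosome", "high_polysome"])
    keep_t = kinetics.filter_expressed(trans_sub)
    translation = kinetics.translation_levels(trans_sub.subset_genes(keep_t))
    io.write_table(translation.scores, RESULTS_DIR / "translation.tsv")

    wt = stability.scores["WT"].dropna()
    iqr_fold = targets.percentile_fold_range(wt, 25, 75)
    tail_fold = targets.percentile_fold_range(wt, 1, 99)
    print(f"{len(wt)} genes scored for stability, {len(translation.scores)} for translation")
    print(f"stability spread (WT): {iqr_fold:.2f}-fold between Q25 and Q75, "
          f"{tail_fold:.1f}-fold between 1st and 99th percentile")

    shared = wt.index.intersection(translation.scores.index)
    rho, p = spearmanr(wt.loc[shared], translation.scores.loc[shared, "WT"])
    print(f"stability vs translation level (WT): Spearman rho {rho:.2f} (p={p:.2g}) "
          f"-- more translated transcripts tend to be more stable")

    truth = truth.loc[wt.index]
    rho_beta = spearmanr(wt, -np.log2(truth["beta"])).statistic
    print(f"ground-truth check: Spearman(stability score, -log2 beta) = {rho_beta:.3f}")


if __name__ == "__main__":
    main()
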
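"""Sequence features of mRNA stability and their regression analysis.

Ten per-gene covariates: log10 lengths of 5'UTR/CDS/3'UTR, GC fraction of
each region, AU-rich element count (TATTTAT in the 3'UTR), upstream-ORF
count (ATG in the 5'UTR), miRNA seed-match site count in the 3'UTR, and
log10 exon count. Stability is regressed on the z-scored features by OLS;
per-feature Spearman correlations rank individual feature impact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import GeneSequences, StabilityTable, ValidationError

FEATURE_COLUMNS = [
    "log10_utr3_len",
    "log10_utr5_len",
    "log10_cds_len",
    "gc_utr3",
    "gc_utr5",
    "gc_cds",
    "n_are",
    "n_uorf",
    "n_mirna_sites",
    "log10_n_exons",
]

ARE_MOTIF = "TATTTAT"
DEFAULT_SEED = "AAGTGC"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def count_motif(seq: str, motif: str) -> int:
    """Number of (possibly overlapping) occurrences of ``motif`` in ``seq``."""
    if not motif:
        raise ValidationError("motif must be non-empty")
    count = 0
    start = seq.find(motif)
    while start != -1:
        count += 1
        start = seq.find(motif, start + 1)
    return count


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_seed_sites(utr3: str, seed: str = DEFAULT_SEED) -> int:
    """Occurrences in the 3'UTR of the reverse complement of a miRNA seed.

    The seed is given 5'->3' as in the miRNA (DNA alphabet); the default
    AAGTGC seed of the ESCC family yields the site GCACTT.
    """
    if len(seed) < 6:
        raise ValidationError(f"seed {seed!r} shorter than 6 nt")
    if set(seed.upper()) - set("ACGT"):
        raise ValidationError(f"seed {seed!r} not a DNA string")
    return count_motif(utr3, reverse_complement(seed.upper()))


def gc_content(seq: str) -> float:
    if not seq:
        raise ValidationError("empty sequence has no GC content")
    return (seq.count("G") + seq.count("C")) / len(seq)


def extract_features(seqs: GeneSequences, seed: str = DEFAULT_SEED) -> pd.DataFrame:
    """One row of the ten features per gene with all three regions present.

    Genes with any empty region are excluded (they lack a defined length or
    GC for it).
    """
    rows = {}
    for gene, rec in seqs.records.iterrows():
        if not (rec["utr5"] and rec["cds"] and rec["utr3"]):
            continue
        rows[gene] = {
            "log10_utr3_len": np.log10(len(rec["utr3"])),
            "log10_utr5_len": np.log10(len(rec["utr5"])),
            "log10_cds_len": np.log10(len(rec["cds"])),
            "gc_utr3": gc_content(rec["utr3"]),
            "gc_utr5": gc_content(rec["utr5"]),
            "gc_cds": gc_content(rec["cds"]),
            "n_are": count_motif(rec["utr3"], ARE_MOTIF),
            "n_uorf": count_motif(rec["utr5"], "ATG"),
            "n_mirna_sites": count_seed_sites(rec["utr3"], seed),
            "log10_n_exons": np.log10(rec["exon_count"]),
        }
    table = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    table.index.name = "gene_id"
    return table[FEATURE_COLUMNS] if len(table) else table


def _align(features: pd.DataFrame, stability) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(stability, StabilityTable):
        if stability.scores.shape[1] != 1:
            raise ValidationError(
                "pass a single genotype's scores (StabilityTable has "
                f"{stability.scores.shape[1]} genotypes)"
            )
        stability = stability.scores.iloc[:, 0]
    stability = pd.Series(stability).dropna()
    shared = features.index.intersection(stability.index)
    return features.loc[shared], stability.loc[shared]


def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    sd = features.std(ddof=0)
    if (sd == 0).any():
        # constant columns carry no signal; keep them at 0 so OLS drops them
        sd = sd.replace(0, 1.0)
    return (features - features.mean()) / sd


def fit_feature_regression(features: pd.DataFrame, stability):
    """OLS of stability on the z-scored features.

    Returns (r_squared, table) where table has one row per feature with
    columns coef/se/p. Features are standardised so coefficients are
    comparable across features; R^2 is unaffected by the scaling.
    """
    X, y = _align(features, stability)
    if len(X) < 20:
        raise ValidationError(f"need >= 20 genes after join, got {len(X)}")
    Xz = zscore_features(X)
    cond = np.linalg.cond(Xz.to_numpy())
    if cond > 1e8:
        corr = Xz.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        offenders = corr.columns[(corr > 0.9999).any()].tolist()
        raise ValidationError(
            f"collinear features (condition number {cond:.3g}): {offenders}"
        )
    model = sm.OLS(y.to_numpy(), sm.add_constant(Xz.to_numpy()))
    fit = model.fit()
    table = pd.DataFrame(
        {
            "coef": fit.params[1:],
            "se": fit.bse[1:],
            "p": fit.pvalues[1:],
        },
        index=pd.Index(Xz.columns, name="feature"),
    )
    return float(fit.rsquared), table


def feature_correlations(features: pd.DataFrame, stability) -> pd.DataFrame:
    """Spearman rho (average-rank ties) and p per feature vs stability.

    Constant features get rho = p = NaN and ``constant = True``.
    """
    X, y = _align(features, stability)
    rows = []
    for column in X.columns:
        x = X[column].to_numpy()
        if np.all(x == x[0]):
            rows.append({"feature": column, "rho": np.nan, "p": np.nan, "constant": True})
            continue
        rho, p = stats.spearmanr(x, y.to_numpy())
        rows.append({"feature": column, "rho": float(rho), "p": float(p), "constant": False})
    return pd.DataFrame(rows).set_index("feature")
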
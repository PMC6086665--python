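"""Normalisation, filtering, stability/translation scoring and differential
interaction-model testing.

Relative mRNA stability comes from the steady-state identity beta ~
alpha/[mRNA]: with nascent (4sU) reads proxying production alpha and total
RNA proxying [mRNA], log2(total/nascent) is -log2 of the relative
degradation rate up to a per-sample constant. Translation level is
log2(high polysome/monosome); translational efficiency is log2(RPF/total).
Genotype differences in any of these ratios are tested per gene with the
interaction term b3 of the two-factor linear model

    y = b0 + b1 * assay + b2 * genotype + b3 * assay x genotype,

fit by OLS on y = log2(CPM + c), with Benjamini-Hochberg adjustment across
genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    CountTable,
    DifferentialResult,
    StabilityTable,
    TranslationTable,
    ValidationError,
)

#: numerator/denominator assay per contrast (score = log2(num/den))
CONTRAST_ASSAYS = {
    "stability": ("total", "nascent_4sU"),
    "translation": ("high_polysome", "monosome"),
    "te": ("rpf", "total"),
}

DEFAULT_PSEUDOCOUNT = 0.5


def cpm_normalize(table: CountTable) -> CountTable:
    """Scale each sample to counts per million (column sum -> 10^6)."""
    if table.normalized:
        raise ValidationError("table is already CPM-normalized")
    sums = table.counts.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValidationError(f"zero column sum for sample(s): {zero.tolist()}")
    cpm = table.counts * (1e6 / sums)
    return CountTable(counts=cpm, samples=table.samples, normalized=True)


def filter_expressed(table: CountTable, min_cpm: float = 3.0, min_reps: int = 3) -> pd.Index:
    """Genes with CPM >= ``min_cpm`` in at least ``min_reps`` samples.

    Replicates are counted across all samples of the given table, so pass
    the subset of samples entering a contrast to filter within it.
    """
    if not table.normalized:
        raise ValidationError("filter_expressed requires a CPM-normalized table")
    if min_reps > table.counts.shape[1]:
        raise ValidationError(
            f"min_reps={min_reps} exceeds the {table.counts.shape[1]} available samples"
        )
    keep = (table.counts >= min_cpm).sum(axis=1) >= min_reps
    return table.counts.index[keep]


def _ratio_scores(
    table: CountTable,
    numerator_assay: str,
    denominator_assay: str,
    pseudocount: float,
    metric: str,
):
    """Per-genotype replicate-paired log2 ratio scores.

    Replicates are paired by replicate index; when the two assays have
    unequal replicate numbers, the mean over all cross pairs is used.
    """
    if not table.normalized:
        raise ValidationError("ratio scores require a CPM-normalized table")
    long_rows = []
    genotype_means = {}
    for genotype, sheet in table.samples.groupby("genotype", sort=False):
        num = sheet[sheet["assay"] == numerator_assay].sort_values("replicate")
        den = sheet[sheet["assay"] == denominator_assay].sort_values("replicate")
        if num.empty or den.empty:
            missing = numerator_assay if num.empty else denominator_assay
            raise ValidationError(
                f"genotype {genotype!r} is missing assay {missing!r} for {metric}"
            )
        if len(num) == len(den):
            pairs = list(zip(num["sample_id"], den["sample_id"]))
        else:
            pairs = [(a, b) for a in num["sample_id"] for b in den["sample_id"]]
        scores = []
        for k, (num_id, den_id) in enumerate(pairs, start=1):
            score = np.log2(
                (table.counts[num_id] + pseudocount) / (table.counts[den_id] + pseudocount)
            )
            scores.append(score)
            frame = score.rename("score").reset_index()
            frame["genotype"] = genotype
            frame["replicate"] = k
            long_rows.append(frame)
        genotype_means[genotype] = pd.concat(scores, axis=1).mean(axis=1)
    scores = pd.DataFrame(genotype_means)
    scores.index.name = "gene_id"
    replicate_scores = pd.concat(long_rows, ignore_index=True)[
        ["gene_id", "genotype", "replicate", "score"]
    ]
    return scores, replicate_scores


def stability_scores(
    table: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> StabilityTable:
    """log2((total CPM + c)/(nascent CPM + c)) per gene and genotype."""
    scores, reps = _ratio_scores(table, "total", "nascent_4sU", pseudocount, "stability")
    return StabilityTable(scores=scores, replicate_scores=reps)


def translation_levels(
    table: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> TranslationTable:
    """log2((high polysome CPM + c)/(monosome CPM + c)) per gene and genotype."""
    scores, reps = _ratio_scores(table, "high_polysome", "monosome", pseudocount, "translation")
    return TranslationTable(scores=scores, replicate_scores=reps)


def translational_efficiency(
    table: CountTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> TranslationTable:
    """log2((RPF CPM + c)/(total CPM + c)) per gene and genotype."""
    scores, reps = _ratio_scores(table, "rpf", "total", pseudocount, "te")
    return TranslationTable(scores=scores, replicate_scores=reps, metric="te")


def _design(factor_a: np.ndarray, factor_b: np.ndarray) -> np.ndarray:
    a = np.asarray(factor_a, dtype=float)
    b = np.asarray(factor_b, dtype=float)
    if set(np.unique(a)) - {0.0, 1.0} or set(np.unique(b)) - {0.0, 1.0}:
        raise ValidationError("factors must be binary 0/1 vectors")
    cells = {(int(x), int(y)) for x, y in zip(a, b)}
    if len(cells) < 4:
        raise ValidationError(f"design has empty cells; populated: {sorted(cells)}")
    return np.column_stack([np.ones_like(a), a, b, a * b])


def interaction_fit(y, factor_a, factor_b):
    """OLS fit of y = b0 + b1 A + b2 B + b3 AB; returns (coef, se, t, df, p).

    ``coef`` is the interaction b3 — the log2 fold-change of the A-ratio
    between the two B groups. With zero residual variance the gene cannot be
    tested: se = 0 and t, p are NaN (callers flag it).
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("y must be finite")
    X = _design(factor_a, factor_b)
    n = len(y)
    df = n - 4
    if df <= 0:
        raise ValidationError(f"no residual degrees of freedom (n={n})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    coef = float(beta[3])
    if rss <= 1e-10 * max(1.0, float(y @ y)):
        return coef, 0.0, float("nan"), df, float("nan")
    s2 = rss / df
    se = float(np.sqrt(s2 * xtx_inv[3, 3]))
    t = coef / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return coef, se, t, df, float(p)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_f_dist(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to sample
    variances, following the log-variance moment equations used for
    moderated t-statistics. Returns (d0, s0sq); d0 = inf means all variances
    are identical and full pooling applies."""
    z = np.log(s2[s2 > 0])
    e_z = z.mean()
    var_z = z.var(ddof=1) if len(z) > 1 else 0.0
    rhs = var_z - special.polygamma(1, df / 2.0)
    if rhs <= 0:
        return float("inf"), float(np.exp(e_z - special.digamma(df / 2.0) + np.log(df / 2.0)))
    # invert trigamma(d0/2) = rhs by bisection on d0 in (0.1, 1e7)
    lo, hi = 0.05, 1e7
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid / 2.0) > rhs:
            lo = mid
        else:
            hi = mid
    d0 = np.sqrt(lo * hi)
    s0sq = np.exp(
        e_z
        - special.digamma(df / 2.0)
        + np.log(df / 2.0)
        + special.digamma(d0 / 2.0)
        - np.log(d0 / 2.0)
    )
    return float(d0), float(s0sq)


def differential_test(
    table: CountTable,
    contrast: str,
    genotypes: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_cpm: float = 3.0,
    min_reps: int = 3,
    shrink_var: bool = False,
) -> DifferentialResult:
    """Per-gene interaction test of a ratio contrast between two genotypes.

    ``genotypes`` is (reference, test); a positive coefficient means the
    contrast's log2 ratio is higher in the test genotype. Genes failing the
    expression filter (CPM >= min_cpm in >= min_reps of the samples entering
    the contrast) are absent from the output. With ``shrink_var`` the
    residual variances are shrunk toward a moment-matched prior (moderated
    t with df + d0); off by default.
    """
    if contrast not in CONTRAST_ASSAYS:
        raise ValidationError(f"unknown contrast {contrast!r}")
    num_assay, den_assay = CONTRAST_ASSAYS[contrast]
    sub = table.select(assays=[den_assay, num_assay], genotypes=list(genotypes))
    for genotype in genotypes:
        for assay in (den_assay, num_assay):
            present = (
                (sub.samples["genotype"] == genotype) & (sub.samples["assay"] == assay)
            ).any()
            if not present:
                raise ValidationError(
                    f"contrast {contrast!r}: no samples for assay {assay!r}, "
                    f"genotype {genotype!r}"
                )
    if not sub.normalized:
        sub = cpm_normalize(sub)
    keep = filter_expressed(sub, min_cpm=min_cpm, min_reps=min_reps)
    sub = sub.subset_genes(keep)

    a = (sub.samples["assay"] == num_assay).to_numpy(dtype=float)
    b = (sub.samples["genotype"] == genotypes[1]).to_numpy(dtype=float)
    X = _design(a, b)
    n = X.shape[0]
    df = n - 4
    if df <= 0:
        raise ValidationError(f"no residual degrees of freedom (n={n})")

    Y = np.log2(sub.counts.to_numpy() + pseudocount)  # genes x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ (xtx_inv @ X.T).T  # genes x 4
    resid = Y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    coef = beta[:, 3]

    flagged = rss <= 1e-10 * np.maximum(1.0, np.einsum("ij,ij->i", Y, Y))
    s2 = np.where(flagged, np.nan, rss / df)
    df_eff = float(df)
    if shrink_var:
        d0, s0sq = _fit_f_dist(s2[~flagged], df)
        if np.isfinite(d0):
            s2 = (d0 * s0sq + df * s2) / (d0 + df)
            df_eff = df + d0
        else:
            s2 = np.full_like(s2, s0sq)
            df_eff = float(n)  # fully pooled
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2 * xtx_inv[3, 3])
        t = coef / se
        p = 2.0 * stats.t.sf(np.abs(t), df_eff)

    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    result = pd.DataFrame(
        {
            "coef": coef,
            "se": np.where(flagged, 0.0, se),
            "t": t,
            "df": df_eff,
            "p": p,
            "q": q,
            "flagged": flagged,
        },
        index=sub.counts.index,
    )
    return DifferentialResult(table=result, contrast=contrast, genotypes=tuple(genotypes))
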
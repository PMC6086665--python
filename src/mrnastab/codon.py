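"""Codon usage, stable-vs-unstable codon comparisons, and the species-
specific tRNA adaptation index (sTAI).

Codon usage frequency is the fraction each sense codon contributes to a
gene's CDS (stop codons excluded throughout; ATG included). Optimality is
probed two ways: (1) per-codon Mann-Whitney comparison of usage between the
most and least stable genes, Bonferroni-corrected over the 61 sense codons;
(2) dos Reis-style adaptiveness weights from tRNA gene copy numbers (tGCN)
and wobble-pairing constraints, whose geometric mean over a CDS is the
gene's sTAI.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSequences, StabilityTable, TRNAPool, ValidationError
from .features import reverse_complement

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]

#: classic tAI wobble constraint values s (selective disadvantage of the
#: wobble pair); Watson-Crick pairs have s = 0. Anticodon wobble-position A
#: is modeled as inosine (pairs C and A in addition to U).
DEFAULT_S_VECTOR = {"G:U": 0.41, "I:C": 0.28, "I:A": 0.9999, "U:G": 0.68}

#: third codon base -> (Watson-Crick anticodon wobble base,
#:                      wobble anticodon wobble base, wobble pair label)
_WOBBLE_RULES = {
    "T": ("A", "G", "G:U"),
    "C": ("G", "A", "I:C"),
    "A": ("T", "A", "I:A"),
    "G": ("C", "T", "U:G"),
}


def codon_frequencies(cds: str) -> pd.Series:
    """Frequency of each sense codon in a CDS (fractions summing to 1)."""
    if len(cds) % 3 != 0 or len(cds) == 0:
        raise ValidationError(f"CDS length {len(cds)} is not a positive multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    sense = [c for c in codons if c not in STOP_CODONS]
    if not sense:
        raise ValidationError("CDS contains no sense codons")
    counts = pd.Series(0.0, index=pd.Index(SENSE_CODONS, name="codon"))
    observed = pd.Series(sense).value_counts()
    unknown = set(observed.index) - set(SENSE_CODONS)
    if unknown:
        raise ValidationError(f"non-DNA codons in CDS: {sorted(unknown)}")
    counts.loc[observed.index] = observed.to_numpy(dtype=float)
    return counts / counts.sum()


def codon_frequency_table(seqs: GeneSequences) -> pd.DataFrame:
    """Genes x 61 codon frequency table over frame-valid CDSs."""
    rows = {
        gene: codon_frequencies(seqs.records.loc[gene, "cds"])
        for gene in seqs.coding_genes()
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"
    return table


def _stability_series(stability) -> pd.Series:
    if isinstance(stability, StabilityTable):
        if stability.scores.shape[1] != 1:
            raise ValidationError("pass a single genotype's stability scores")
        stability = stability.scores.iloc[:, 0]
    return pd.Series(stability).dropna()


def group_codon_comparison(
    freqs: pd.DataFrame, stability, frac: float = 0.2
) -> pd.DataFrame:
    """Per-codon usage comparison between the most and least stable genes.

    Genes are ranked by stability score (ties broken deterministically by
    gene id); the top and bottom ``frac`` form the stable/unstable groups.
    Per codon: two-sided Mann-Whitney on per-gene frequencies, Bonferroni
    over the 61 sense codons, and delta = median_stable - median_unstable.
    """
    if not 0 < frac <= 0.5:
        raise ValidationError("frac must be in (0, 0.5]")
    stability = _stability_series(stability)
    shared = freqs.index.intersection(stability.index)
    freqs, stability = freqs.loc[shared], stability.loc[shared]
    if stability.nunique() <= 1:
        raise ValidationError("stability scores are constant; groups would be arbitrary")
    n_group = int(np.floor(frac * len(stability)))
    if n_group < 10:
        raise ValidationError(f"need >= 10 genes per group, got {n_group}")
    order = stability.to_frame("score").sort_values(["score", "gene_id"]).index
    unstable = freqs.loc[order[:n_group]]
    stable = freqs.loc[order[-n_group:]]

    rows = []
    m = len(freqs.columns)
    for codon in freqs.columns:
        a, b = stable[codon].to_numpy(), unstable[codon].to_numpy()
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        rows.append(
            {
                "codon": codon,
                "median_stable": float(np.median(a)),
                "median_unstable": float(np.median(b)),
                "delta": float(np.median(a) - np.median(b)),
                "p_raw": p,
                "p_bonferroni": min(1.0, p * m),
            }
        )
    out = pd.DataFrame(rows).set_index("codon")
    out["significant"] = out["p_bonferroni"] < 0.05
    return out


def delta_median_comparison(wt_deltas: pd.Series, ko_deltas: pd.Series):
    """Compare per-codon median-usage differences between two genotypes.

    Returns (paired table, spearman rho, p). The codon sets must match.
    """
    wt, ko = pd.Series(wt_deltas), pd.Series(ko_deltas)
    if set(wt.index) != set(ko.index):
        raise ValidationError("codon sets differ between the two delta vectors")
    ko = ko.loc[wt.index]
    rho, p = stats.spearmanr(wt.to_numpy(), ko.to_numpy())
    table = pd.DataFrame({"delta_a": wt, "delta_b": ko})
    table.index.name = "codon"
    return table, float(rho), float(p)


@dataclass
class CodonWeights:
    """Per-codon tRNA adaptiveness: absolute W, normalised w, zero-W flag."""

    table: pd.DataFrame  # index codon, columns W, w, flagged
    s_vector: dict

    @property
    def w(self) -> pd.Series:
        return self.table["w"]


def pairing_anticodons(codon: str) -> list[tuple[str, str]]:
    """Anticodons able to read ``codon`` as (anticodon, pair label).

    The Watson-Crick anticodon is the reverse complement; one wobble
    anticodon differs at its first (wobble) position per the pairing rules.
    """
    wc = reverse_complement(codon)
    wc_base, wobble_base, label = _WOBBLE_RULES[codon[2]]
    assert wc[0] == wc_base
    return [(wc, "WC"), (wobble_base + wc[1:], label)]


def tai_weights(pool: TRNAPool, s_vector: dict | None = None) -> CodonWeights:
    """dos Reis-style per-codon adaptiveness weights from a tRNA pool.

    W(codon) = sum over pairing anticodons of (1 - s) * tGCN; w = W / max W.
    Codons no anticodon can read get the geometric mean of the nonzero w and
    are flagged.
    """
    if s_vector is None:
        s_vector = dict(DEFAULT_S_VECTOR)
    unknown = set(s_vector) - set(DEFAULT_S_VECTOR)
    if unknown:
        raise ValidationError(f"unknown wobble pair type(s): {sorted(unknown)}")
    for label, s in s_vector.items():
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"constraint s for {label} must be in [0, 1], got {s}")
    s_vector = {**DEFAULT_S_VECTOR, **s_vector}

    tgcn = pool.copy_numbers
    W = {}
    for codon in SENSE_CODONS:
        total = 0.0
        for anticodon, label in pairing_anticodons(codon):
            s = 0.0 if label == "WC" else s_vector[label]
            total += (1.0 - s) * float(tgcn.get(anticodon, 0.0))
        W[codon] = total
    table = pd.DataFrame({"W": pd.Series(W)})
    table.index.name = "codon"
    wmax = table["W"].max()
    if wmax <= 0:
        raise ValidationError("no codon has a positive adaptiveness weight")
    table["w"] = table["W"] / wmax
    table["flagged"] = table["W"] == 0.0
    nonzero = table.loc[~table["flagged"], "w"]
    if table["flagged"].any():
        geo_mean = float(np.exp(np.log(nonzero).mean()))
        table.loc[table["flagged"], "w"] = geo_mean
    return CodonWeights(table=table, s_vector=s_vector)


def stai_scores(seqs: GeneSequences, weights: CodonWeights) -> pd.Series:
    """Per-gene sTAI: geometric mean of w over the gene's sense codons."""
    w = weights.w
    log_w = np.log(w)
    out = {}
    for gene in seqs.coding_genes():
        cds = seqs.records.loc[gene, "cds"]
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        sense = [c for c in codons if c not in STOP_CODONS]
        if not sense:
            continue
        out[gene] = float(np.exp(log_w.loc[sense].mean()))
    series = pd.Series(out, name="stai")
    series.index.name = "gene_id"
    return series
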
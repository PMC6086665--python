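"""miRNA target-set statistics and the stability/translation decoupling
comparison.

Targets are defined by seed matching (3'UTR occurrences of the reverse
complement of a miRNA seed, AAGUGC for the ESCC family by default) or by a
user-supplied list. Group shifts of per-gene change scores (targets vs
background) are tested with the Mann-Whitney U test; comparing the target
shifts across two knockout genotypes for stability and translation
separately reveals whether a factor mediates one miRNA function, the other,
or both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DifferentialResult, GeneSequences, TargetSet, ValidationError
from .features import count_seed_sites

logger = logging.getLogger(__name__)

EXACT_MAX_GROUP = 8


def build_target_set(
    seqs: GeneSequences, seed: str = "AAGTGC", min_sites: int = 1
) -> TargetSet:
    """Genes whose 3'UTR carries at least ``min_sites`` seed-match sites."""
    hits = [
        gene
        for gene, utr3 in seqs.records["utr3"].items()
        if utr3 and count_seed_sites(utr3, seed) >= min_sites
    ]
    if not hits:
        raise ValidationError(f"no genes with >= {min_sites} seed-match site(s)")
    return TargetSet(gene_ids=pd.Index(hits), provenance="seed_match", seed=seed)


def target_set_from_list(gene_ids, universe) -> TargetSet:
    """Intersect a user-supplied target list with the analyzed genes."""
    wanted = pd.Index(gene_ids).unique()
    universe = pd.Index(universe)
    absent = wanted.difference(universe)
    if len(absent):
        logger.warning(
            "%d target id(s) absent from the analyzed genes (e.g. %s)",
            len(absent),
            absent[:3].tolist(),
        )
    present = wanted.intersection(universe)
    if len(present) == 0:
        raise ValidationError("no supplied target ids overlap the analyzed genes")
    return TargetSet(gene_ids=present, provenance="user_list")


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic for group a (ties count half)."""
    u = 0.0
    for x in a:
        u += np.sum(x > b) + 0.5 * np.sum(x == b)
    return float(u)


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by exhaustive enumeration.

    Enumerates all C(n, n_a) assignments of the pooled values to group a and
    counts those with |U - mean| at least as extreme as observed. Handles
    ties (half counts). Feasible for small groups only.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    u_obs = _mann_whitney_u(a, b)
    mu = na * (n - na) / 2.0
    extreme = 0
    idx = np.arange(n)
    for subset in combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(subset)] = True
        u = _mann_whitney_u(pooled[mask], pooled[~mask])
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / comb(n, na)


def group_shift_test(changes: pd.Series, targets, background: str = "complement"):
    """Median shift and Mann-Whitney p of target genes vs background.

    ``background="complement"`` (default) compares targets against all other
    analyzed genes; ``"all"`` compares against every analyzed gene including
    the targets. Exact enumeration is used when both groups have <= 8
    members, otherwise the normal approximation with continuity and tie
    correction.
    """
    changes = pd.Series(changes).dropna()
    if isinstance(targets, TargetSet):
        targets = targets.gene_ids
    targets = pd.Index(targets)
    in_target = changes.index.isin(targets)
    target_vals = changes[in_target].to_numpy()
    if background == "complement":
        bg_vals = changes[~in_target].to_numpy()
    elif background == "all":
        bg_vals = changes.to_numpy()
    else:
        raise ValidationError(f"unknown background mode {background!r}")
    if len(target_vals) < 2 or len(bg_vals) < 2:
        raise ValidationError(
            f"need >= 2 genes per group (targets {len(target_vals)}, "
            f"background {len(bg_vals)})"
        )
    shift = float(np.median(target_vals) - np.median(bg_vals))
    if len(target_vals) <= EXACT_MAX_GROUP and len(bg_vals) <= EXACT_MAX_GROUP:
        _, p = mann_whitney_exact(target_vals, bg_vals)
    else:
        p = float(
            stats.mannwhitneyu(
                target_vals, bg_vals, alternative="two-sided", method="asymptotic"
            ).pvalue
        )
    return shift, p


def percentile_fold_range(values, lo: float, hi: float) -> float:
    """Fold-change between two percentiles of log2 scores.

    2^(Q(hi) - Q(lo)) with linear-interpolation quantiles; lo/hi in percent.
    """
    values = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(values) < 2:
        raise ValidationError("need >= 2 finite values")
    if lo >= hi:
        raise ValidationError(f"lo ({lo}) must be < hi ({hi})")
    q_lo, q_hi = np.quantile(values, [lo / 100.0, hi / 100.0], method="linear")
    return float(2.0 ** (q_hi - q_lo))


def change_correlation(changes_a, changes_b) -> tuple[float, float]:
    """Spearman correlation of two per-gene change vectors (inner join)."""
    a = pd.Series(changes_a).dropna()
    b = pd.Series(changes_b).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 10:
        raise ValidationError(f"need >= 10 shared genes, got {len(shared)}")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant input; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class DecouplingSummary:
    """Target shifts per (genotype contrast x metric) + cross-contrast rho."""

    shifts: pd.DataFrame  # contrast, metric, n_targets, n_background, median_shift, p
    correlations: pd.DataFrame  # metric, rho, p


def decoupling_summary(
    diff_stability: dict[str, DifferentialResult],
    diff_translation: dict[str, DifferentialResult],
    targets,
    background: str = "complement",
) -> DecouplingSummary:
    """Assemble the decoupling comparison across genotype contrasts.

    ``diff_stability`` / ``diff_translation`` map a contrast label (e.g. the
    knockout genotype) to its per-gene interaction-test result. For every
    (contrast, metric) the target group shift of the interaction
    coefficients is tested; for every metric the per-gene changes are
    correlated across each pair of contrasts.
    """
    if isinstance(targets, TargetSet):
        target_index = targets.gene_ids
    else:
        target_index = pd.Index(targets)

    shift_rows = []
    for metric, results in (("stability_change", diff_stability),
                            ("translation_change", diff_translation)):
        for label, result in results.items():
            changes = result.table["coef"].dropna()
            n_t = int(changes.index.isin(target_index).sum())
            n_b = len(changes) - n_t if background == "complement" else len(changes)
            shift, p = group_shift_test(changes, target_index, background=background)
            shift_rows.append(
                {
                    "contrast": label,
                    "metric": metric,
                    "n_targets": n_t,
                    "n_background": n_b,
                    "median_shift": shift,
                    "p": p,
                }
            )

    corr_rows = []
    for metric, results in (("stability_change", diff_stability),
                            ("translation_change", diff_translation)):
        labels = list(results)
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                rho, p = change_correlation(
                    results[la].table["coef"], results[lb].table["coef"]
                )
                corr_rows.append(
                    {"metric": metric, "contrast_a": la, "contrast_b": lb,
                     "rho": rho, "p": p}
                )
    return DecouplingSummary(
        shifts=pd.DataFrame(shift_rows),
        correlations=pd.DataFrame(corr_rows),
    )
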
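"""Synthetic multi-assay RNA-seq data with known ground truth.

The generator realises the steady-state kinetic model the analysis assumes:
each gene has a production rate alpha and a degradation rate beta, so its
steady-state abundance is alpha/beta; a translation level t partitions that
abundance between monosome and high-polysome fractions. Genotype effects
(fold-changes of stability 1/beta and of t) are confined to a declared
miRNA-target set. Counts are negative-binomial with mean mu and variance
mu + dispersion * mu^2 (Poisson at dispersion 0), with per-sample log-normal
library-size jitter. Sequences carry plantable AAGUGC-seed sites, AU-rich
elements and upstream-ATG motifs whose rates can be coupled to beta so the
sequence-feature analyses have recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ASSAYS,
    CountTable,
    GeneSequences,
    TruthSet,
    ValidationError,
)

SEED_SITE = "GCACTT"  # reverse complement of the AAGUGC seed, in DNA
ARE_MOTIF = "TATTTAT"
_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the default study conditions.

    Rates are arbitrary units (only ratios matter downstream); SDs are on the
    log2 scale. ``genotype_effects`` maps genotype -> (stability_fold,
    translation_fold) applied to target genes only; the first entry is the
    reference and must be (1, 1).
    """

    n_genes: int = 2000
    sd_log2_alpha: float = 1.0
    sd_log2_beta: float = 1.5
    sd_log2_trans: float = 1.0
    #: correlation knob between log2 t and -log2 beta (stability); default off
    stability_translation_corr: float = 0.0
    n_targets: int = 300
    target_stability_fold: float = 1.0
    target_translation_fold: float = 1.0
    #: explicit per-genotype (stability_fold, translation_fold) for targets;
    #: None -> {"WT": (1,1), "KO": (target_stability_fold, target_translation_fold)}
    genotype_effects: dict[str, tuple[float, float]] | None = None
    #: genotype treated as the baseline; its effects must be (1, 1)
    reference: str = "WT"
    assays: tuple[str, ...] = ("nascent_4sU", "total", "monosome", "high_polysome")
    n_replicates: int = 3
    depth: float = 2e6
    dispersion: float = 0.05
    sd_log2_libsize: float = 0.2
    low_polysome_weight: float = 0.5
    # sequence generation
    utr5_len_median: float = 150.0
    utr5_len_sd_log2: float = 0.5
    cds_codons_median: float = 400.0
    cds_codons_sd_log2: float = 0.4
    utr3_len_median: float = 800.0
    utr3_len_sd_log2: float = 0.6
    gc_content: float = 0.45
    n_seed_sites: int = 2
    are_base_rate: float = 1.0
    are_beta_coupling: float = 0.5
    uorf_base_rate: float = 2.0
    uorf_beta_coupling: float = 0.0
    #: shift of log2 3'UTR length per SD of log2 beta (positive = unstable
    #: genes get longer 3'UTRs, the direction reported for real transcriptomes)
    utr3_len_beta_coupling: float = 0.0
    exon_count_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets > self.n_genes:
            raise ValidationError("n_targets cannot exceed n_genes")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        for name in ("n_genes", "n_replicates", "depth"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        unknown = set(self.assays) - set(ASSAYS)
        if unknown:
            raise ValidationError(f"unknown assays in config: {sorted(unknown)}")
        if not -1.0 <= self.stability_translation_corr <= 1.0:
            raise ValidationError("stability_translation_corr must be in [-1, 1]")

    def effects(self) -> dict[str, tuple[float, float]]:
        """Per-genotype effect folds, reference genotype first."""
        if self.genotype_effects is not None:
            eff = {g: tuple(v) for g, v in self.genotype_effects.items()}
        else:
            eff = {
                self.reference: (1.0, 1.0),
                "KO": (self.target_stability_fold, self.target_translation_fold),
            }
        if self.reference not in eff:
            raise ValidationError(
                f"reference genotype {self.reference!r} absent from genotype_effects"
            )
        if tuple(eff[self.reference]) != (1.0, 1.0):
            raise ValidationError("reference genotype effects must be (1, 1)")
        ordered = {self.reference: (1.0, 1.0)}
        for genotype in sorted(g for g in eff if g != self.reference):
            ordered[genotype] = eff[genotype]
        return ordered

    @property
    def reference_genotype(self) -> str:
        return self.reference


def generate_truth(config: SimConfig) -> TruthSet:
    """Draw per-gene ground-truth rates and genotype effects.

    log2(alpha), log2(beta) and log2(t) are normal with the configured SDs;
    the optional correlation knob tilts log2(t) toward -log2(beta). The
    first ``n_targets`` genes are targets; knockout effects apply to them only.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    log2_alpha = rng.normal(0.0, config.sd_log2_alpha, n)
    z_beta = rng.standard_normal(n)
    log2_beta = config.sd_log2_beta * z_beta
    rho = config.stability_translation_corr
    z_t = rho * (-z_beta) + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    log2_trans = config.sd_log2_trans * z_t

    genes = pd.DataFrame(
        {
            "alpha": 2.0**log2_alpha,
            "beta": 2.0**log2_beta,
            "trans_level": 2.0**log2_trans,
            "is_target": np.arange(n) < config.n_targets,
        },
        index=gene_ids,
    )

    effects = config.effects()
    stab = pd.DataFrame(1.0, index=gene_ids, columns=list(effects))
    trans = pd.DataFrame(1.0, index=gene_ids, columns=list(effects))
    ref = config.reference_genotype
    for genotype, (sfold, tfold) in effects.items():
        if genotype == ref:
            continue
        stab.loc[genes["is_target"], genotype] = sfold
        trans.loc[genes["is_target"], genotype] = tfold
    return TruthSet(
        genes=genes,
        stability_effect=stab,
        translation_effect=trans,
        reference_genotype=ref,
    )


def _relative_abundance(
    truth: TruthSet, config: SimConfig, assay: str, genotype: str
) -> np.ndarray:
    """Expected relative abundance per gene for one (assay, genotype) cell.

    Steady state: total mRNA = alpha/beta * s where s is the genotype's
    stability effect (fold-change of 1/beta). The translation level
    t' = t * translation_effect splits mRNA between monosome (1/(1+t')) and
    high polysome (t'/(1+t')); ribosome footprints scale as mRNA * t'.
    Nascent RNA tracks production alpha alone.
    """
    alpha = truth.genes["alpha"].to_numpy()
    beta = truth.genes["beta"].to_numpy()
    s = truth.stability_effect[genotype].to_numpy()
    t = truth.genes["trans_level"].to_numpy() * truth.translation_effect[genotype].to_numpy()
    mrna = alpha / beta * s
    if assay == "nascent_4sU":
        return alpha
    if assay == "total":
        return mrna
    if assay == "monosome":
        return mrna / (1.0 + t)
    if assay == "high_polysome":
        return mrna * t / (1.0 + t)
    if assay == "low_polysome":
        w = config.low_polysome_weight
        return mrna * ((1.0 - w) / (1.0 + t) + w * t / (1.0 + t))
    if assay == "rpf":
        return mrna * t
    raise ValidationError(f"unknown assay {assay!r}")


def _sample_sheet(config: SimConfig) -> pd.DataFrame:
    rows = []
    for genotype in config.effects():
        for assay in config.assays:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{assay}_r{rep}",
                        "assay": assay,
                        "genotype": genotype,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def expected_counts(truth: TruthSet, config: SimConfig) -> CountTable:
    """Noise-free expected counts (each sample scaled to ``depth``).

    The deterministic limit of :func:`sample_counts`: no library jitter and
    no counting noise. Useful as an oracle for the steady-state identities.
    """
    sheet = _sample_sheet(config)
    cols = {}
    for row in sheet.itertuples():
        rel = _relative_abundance(truth, config, row.assay, row.genotype)
        cols[row.sample_id] = config.depth * rel / rel.sum()
    counts = pd.DataFrame(cols, index=truth.genes.index)
    return CountTable(counts=counts, samples=sheet, normalized=False)


def sample_counts(truth: TruthSet, config: SimConfig, rng=None) -> CountTable:
    """Draw negative-binomial counts for every (assay, genotype, replicate).

    Mean per sample: depth * relative abundance * log-normal jitter factor.
    Counts are gamma-Poisson mixtures giving variance mu + dispersion * mu^2;
    dispersion = 0 degenerates to Poisson.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    sheet = _sample_sheet(config)
    cols = {}
    for row in sheet.itertuples():
        rel = _relative_abundance(truth, config, row.assay, row.genotype)
        jitter = 2.0 ** rng.normal(0.0, config.sd_log2_libsize)
        mu = config.depth * rel / rel.sum() * jitter
        if config.dispersion == 0:
            draws = rng.poisson(mu)
        else:
            shape = 1.0 / config.dispersion
            lam = rng.gamma(shape, mu / shape)
            draws = rng.poisson(lam)
        cols[row.sample_id] = draws.astype(float)
    counts = pd.DataFrame(cols, index=truth.genes.index)
    return CountTable(counts=counts, samples=sheet, normalized=False)


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _random_cds(rng, n_codons: int, gc: float) -> str:
    """ATG + (n-2) random sense codons + random stop; length 3*n_codons."""
    body = _random_seq(rng, 3 * (n_codons - 2), gc)
    seq = body.tobytes().decode()
    # reject internal stops codon-wise, redrawing in place
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, codon in enumerate(codons):
        while codons[i] in _STOPS:
            codons[i] = _random_seq(rng, 3, gc).tobytes().decode()
    return "ATG" + "".join(codons) + _STOPS[rng.integers(3)]


def _plant_motifs(rng, seq: str, motifs: list[str]) -> str:
    """Overwrite non-overlapping windows of ``seq`` with the given motifs."""
    total = sum(len(m) for m in motifs)
    if total > len(seq):
        raise ValidationError(
            f"region of length {len(seq)} too short to host {len(motifs)} motifs "
            f"({total} nt)"
        )
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    occupied: list[tuple[int, int]] = []
    for motif in motifs:
        m = len(motif)
        for _ in range(1000):
            start = int(rng.integers(0, len(seq) - m + 1))
            if all(start + m <= lo or start >= hi for lo, hi in occupied):
                break
        else:
            raise ValidationError("could not place motifs without overlap")
        occupied.append((start, start + m))
        arr[start : start + m] = np.frombuffer(motif.encode(), dtype="S1")
    return arr.tobytes().decode()


def _length(rng, median: float, sd_log2: float, shift_log2: float = 0.0, floor: int = 30) -> int:
    return max(floor, int(round(median * 2.0 ** (rng.normal(0.0, sd_log2) + shift_log2))))


def generate_sequences(truth: TruthSet, config: SimConfig, rng=None) -> GeneSequences:
    """Random region sequences with plantable, beta-coupled motifs.

    Target genes receive ``n_seed_sites`` planted seed-match sites (GCACTT)
    in the 3'UTR. ARE and upstream-ATG plant counts are Poisson with rates
    multiplied by 2^(coupling * z_beta) where z_beta standardises log2(beta),
    so less stable genes can be enriched for destabilising motifs. The 3'UTR
    length median shifts by ``utr3_len_beta_coupling`` log2 units per SD of
    log2(beta).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    log2_beta = np.log2(truth.genes["beta"].to_numpy())
    sd = log2_beta.std()
    z_beta = (log2_beta - log2_beta.mean()) / sd if sd > 0 else np.zeros_like(log2_beta)

    rows = []
    for i, gene in enumerate(truth.genes.index):
        z = z_beta[i]
        utr5_len = _length(rng, config.utr5_len_median, config.utr5_len_sd_log2)
        utr3_len = _length(
            rng,
            config.utr3_len_median,
            config.utr3_len_sd_log2,
            shift_log2=config.utr3_len_beta_coupling * z,
        )
        n_codons = max(10, int(round(config.cds_codons_median * 2.0 ** rng.normal(0.0, config.cds_codons_sd_log2))))

        utr5 = _random_seq(rng, utr5_len, config.gc_content).tobytes().decode()
        utr3 = _random_seq(rng, utr3_len, config.gc_content).tobytes().decode()
        cds = _random_cds(rng, n_codons, config.gc_content)

        n_uorf = rng.poisson(config.uorf_base_rate * 2.0 ** (config.uorf_beta_coupling * z))
        if n_uorf:
            utr5 = _plant_motifs(rng, utr5, ["ATG"] * int(n_uorf))

        utr3_motifs: list[str] = []
        if truth.genes["is_target"].iloc[i]:
            utr3_motifs += [SEED_SITE] * config.n_seed_sites
        n_are = rng.poisson(config.are_base_rate * 2.0 ** (config.are_beta_coupling * z))
        utr3_motifs += [ARE_MOTIF] * int(n_are)
        if utr3_motifs:
            utr3 = _plant_motifs(rng, utr3, utr3_motifs)

        rows.append(
            {
                "gene_id": gene,
                "utr5": utr5,
                "cds": cds,
                "utr3": utr3,
                "exon_count": 1 + int(rng.poisson(config.exon_count_mean - 1)),
                "cds_valid": True,
            }
        )
    return GeneSequences(records=pd.DataFrame(rows).set_index("gene_id"))


def stability_from_features(
    features: pd.DataFrame,
    coefficients: pd.Series | dict,
    population_r2: float,
    rng=None,
) -> pd.Series:
    """Construct a stability score as a linear function of features plus noise.

    The noise SD is chosen so the population coefficient of determination
    equals ``population_r2``: Var(noise) = Var(signal) * (1 - R2) / R2.
    Used to test that the feature regression recovers a known signal.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not 0 < population_r2 < 1:
        raise ValidationError("population_r2 must be in (0, 1)")
    coefficients = pd.Series(coefficients, dtype=float)
    X = features[coefficients.index].to_numpy(dtype=float)
    signal = X @ coefficients.to_numpy()
    var_signal = signal.var()
    if var_signal == 0:
        raise ValidationError("feature signal has zero variance")
    noise_sd = np.sqrt(var_signal * (1.0 - population_r2) / population_r2)
    return pd.Series(signal + rng.normal(0.0, noise_sd, len(signal)), index=features.index)


def simulate_trna_pool(rng=None, mean_copies: float = 6.0, p_missing: float = 0.15):
    """Random tRNA pool over the Watson-Crick anticodons of the sense codons.

    Each anticodon gets a 1 + Poisson(mean_copies - 1) gene copy number and
    is dropped with probability ``p_missing`` (those codons then rely on
    wobble reading, as real genomes do). At least one anticodon survives.
    """
    from .codon import SENSE_CODONS
    from .containers import TRNAPool
    from .features import reverse_complement

    if rng is None:
        rng = np.random.default_rng(0)
    anticodons = sorted({reverse_complement(c) for c in SENSE_CODONS})
    copies = 1 + rng.poisson(max(0.0, mean_copies - 1.0), len(anticodons))
    keep = rng.random(len(anticodons)) >= p_missing
    if not keep.any():
        keep[0] = True
    series = pd.Series(copies[keep].astype(float), index=pd.Index(np.array(anticodons)[keep]))
    return TRNAPool(copy_numbers=series)


def simulate_codon_spike(
    n_per_group: int,
    spike_codon: str,
    spike: float = 0.02,
    n_codons: int = 300,
    rng=None,
):
    """Codon-frequency table with one codon spiked in the unstable half.

    Generates ``2 * n_per_group`` genes of random sense codons (gene lengths
    log-normal around ``n_codons`` codons, as real CDS lengths vary), draws a
    continuous stability score, and adds ``spike`` to the spiked codon's
    frequency (renormalising) for every gene in the bottom half.
    Returns (frequencies DataFrame genes x 61, stability Series).
    """
    from .codon import SENSE_CODONS

    if rng is None:
        rng = np.random.default_rng(0)
    if spike_codon not in SENSE_CODONS:
        raise ValidationError(f"{spike_codon!r} is not a sense codon")
    n_genes = 2 * n_per_group
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    lengths = np.maximum(30, np.round(n_codons * 2.0 ** rng.normal(0.0, 0.4, n_genes))).astype(int)
    draws = np.stack(
        [rng.multinomial(n, np.full(61, 1.0 / 61.0)) / n for n in lengths]
    )
    freqs = pd.DataFrame(draws, index=gene_ids, columns=SENSE_CODONS)
    stability = pd.Series(rng.standard_normal(n_genes), index=gene_ids)
    unstable = stability.rank(method="first") <= n_per_group
    spiked = freqs.loc[unstable].copy()
    spiked[spike_codon] += spike
    freqs.loc[unstable] = spiked.div(spiked.sum(axis=1), axis=0)
    return freqs, stability
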
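"""Core in-memory containers shared across the pipeline.

Everything is a thin, validated wrapper around pandas objects so the
analysis stages can rely on a handful of invariants (unique gene ids,
non-negative counts, consistent sample metadata) without re-checking them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ASSAYS = (
    "nascent_4sU",
    "total",
    "monosome",
    "low_polysome",
    "high_polysome",
    "rpf",
)


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample sheet.

    Required columns: ``sample_id``, ``assay``, ``genotype``, ``replicate``.
    Sample ids must be unique, assays drawn from :data:`ASSAYS`, replicates
    positive integers.
    """
    required = {"sample_id", "assay", "genotype", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    sheet = sheet.copy()
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    bad = set(sheet["assay"]) - set(ASSAYS)
    if bad:
        raise ValidationError(f"unknown assays {sorted(bad)}; expected one of {ASSAYS}")
    reps = pd.to_numeric(sheet["replicate"], errors="coerce")
    if reps.isna().any() or (reps < 1).any() or (reps != reps.astype(int)).any():
        raise ValidationError("replicate must be a positive integer for every sample")
    sheet["replicate"] = reps.astype(int)
    return sheet


@dataclass
class CountTable:
    """Gene-by-sample count matrix plus sample metadata.

    ``counts`` is genes x samples (columns in sample-sheet order);
    ``samples`` is the validated sample sheet indexed 0..n-1 with columns
    sample_id/assay/genotype/replicate. ``normalized`` marks CPM scaling.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples.reset_index(drop=True))
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValidationError(
                "count matrix columns do not match sample sheet order: "
                f"{list(self.counts.columns)} vs {list(self.samples['sample_id'])}"
            )
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (values < 0).any():
            gene, sample = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[gene]!r}, "
                f"sample {self.counts.columns[sample]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "CountTable":
        """Restrict to samples where ``mask`` (aligned to sheet rows) is True."""
        mask = np.asarray(mask, dtype=bool)
        sheet = self.samples.loc[mask].reset_index(drop=True)
        return CountTable(
            counts=self.counts.loc[:, sheet["sample_id"].tolist()],
            samples=sheet,
            normalized=self.normalized,
        )

    def subset_genes(self, gene_ids) -> "CountTable":
        keep = self.counts.index.intersection(pd.Index(gene_ids))
        return CountTable(
            counts=self.counts.loc[keep],
            samples=self.samples,
            normalized=self.normalized,
        )

    def select(self, assays=None, genotypes=None) -> "CountTable":
        mask = pd.Series(True, index=self.samples.index)
        if assays is not None:
            mask &= self.samples["assay"].isin(assays)
        if genotypes is not None:
            mask &= self.samples["genotype"].isin(genotypes)
        return self.subset_samples(mask)


@dataclass
class GeneSequences:
    """Per-gene region sequences (5'UTR, CDS, 3'UTR) and exon counts.

    ``records`` is indexed by gene id with string columns ``utr5``, ``cds``,
    ``utr3`` (empty string = region missing), integer ``exon_count`` and a
    boolean ``cds_valid`` flag (frame-length check) gating codon operations.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"utr5", "cds", "utr3", "exon_count", "cds_valid"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValidationError(f"GeneSequences missing columns: {sorted(missing)}")
        if self.records.index.duplicated().any():
            raise ValidationError("duplicate gene ids in sequences")

    @property
    def gene_ids(self) -> pd.Index:
        return self.records.index

    def coding_genes(self) -> pd.Index:
        """Genes whose CDS passed the frame check (length % 3 == 0, >= 3)."""
        return self.records.index[self.records["cds_valid"]]


@dataclass
class TRNAPool:
    """tRNA gene copy numbers (tGCN) keyed by anticodon (DNA alphabet)."""

    copy_numbers: pd.Series  # index: anticodon, values: tGCN

    def __post_init__(self) -> None:
        idx = self.copy_numbers.index
        if idx.duplicated().any():
            raise ValidationError(f"duplicate anticodons: {idx[idx.duplicated()].tolist()}")
        for ac in idx:
            if len(ac) != 3 or set(ac) - set("ACGT"):
                raise ValidationError(f"invalid anticodon {ac!r}")
        vals = self.copy_numbers.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValidationError("negative tRNA copy number")
        if not (vals > 0).any():
            raise ValidationError("tRNA pool has no positive copy numbers")


@dataclass
class StabilityTable:
    """Per-gene, per-genotype log2(total/nascent) stability scores.

    ``scores``: genes x genotypes (replicate mean); ``replicate_scores``:
    long frame gene_id/genotype/replicate/score.
    """

    scores: pd.DataFrame
    replicate_scores: pd.DataFrame
    metric: str = "stability"


@dataclass
class TranslationTable:
    """Per-gene, per-genotype log2(high polysome/monosome) translation levels."""

    scores: pd.DataFrame
    replicate_scores: pd.DataFrame
    metric: str = "translation"


@dataclass
class DifferentialResult:
    """Per-gene interaction-model test results for one contrast.

    ``table`` columns: coef (log2 interaction), se, t, df, p, q, flagged.
    """

    table: pd.DataFrame
    contrast: str
    genotypes: tuple[str, str]


@dataclass
class TargetSet:
    """A set of putative miRNA target genes with provenance."""

    gene_ids: pd.Index
    provenance: str  # "user_list" | "seed_match"
    seed: str | None = None

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValidationError("target set is empty")
        self.gene_ids = pd.Index(self.gene_ids).unique()


@dataclass
class TruthSet:
    """Ground-truth simulation parameters.

    ``genes``: per-gene alpha, beta, trans_level, is_target.
    ``effects``: per (genotype, gene) stability_effect and translation_effect
    stored as genes x genotype DataFrames.
    """

    genes: pd.DataFrame
    stability_effect: pd.DataFrame
    translation_effect: pd.DataFrame
    reference_genotype: str = "WT"

    def __post_init__(self) -> None:
        for col in ("alpha", "beta", "trans_level"):
            if (self.genes[col] <= 0).any():
                raise ValidationError(f"nonpositive {col} in truth set")
        ref = self.reference_genotype
        for eff in (self.stability_effect, self.translation_effect):
            if not np.allclose(eff[ref], 1.0):
                raise ValidationError("reference genotype effects must equal 1")

    @property
    def target_ids(self) -> pd.Index:
        return self.genes.index[self.genes["is_target"]]
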
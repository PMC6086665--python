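"""Readers and writers for the external text formats.

Counts, sample sheets, tRNA pools and annotations travel as TSV; sequences
as per-region FASTA (5'UTR, CDS, 3'UTR keyed by gene id); target lists as
one id per line. All numeric output is written with 12 significant digits
so result tables round-trip to full precision.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .containers import CountTable, GeneSequences, TRNAPool, ValidationError

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    from .containers import validate_sample_sheet

    return validate_sample_sheet(sheet)


def read_count_matrix(path, sheet_path) -> CountTable:
    """Read a gene-by-sample TSV (first column ``gene_id``) plus sample sheet.

    Samples are matched by id; the sheet's order defines the column order.
    Raises :class:`ValidationError` naming the offending id/cell on any
    mismatch, duplicate gene, or negative/non-numeric count.
    """
    sheet = read_sample_sheet(sheet_path)
    raw = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in raw.columns:
        raise ValidationError(f"{path}: first column must be 'gene_id'")
    raw = raw.set_index("gene_id")
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene_id in {path}: {dups}")

    matrix_samples = set(raw.columns)
    sheet_samples = set(sheet["sample_id"])
    missing_in_sheet = matrix_samples - sheet_samples
    if missing_in_sheet:
        raise ValidationError(
            f"samples in count matrix but not in sample sheet: {sorted(missing_in_sheet)}"
        )
    missing_in_matrix = sheet_samples - matrix_samples
    if missing_in_matrix:
        raise ValidationError(
            f"samples in sample sheet but not in count matrix: {sorted(missing_in_matrix)}"
        )

    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        if numeric.isna().any():
            gene = raw.index[numeric.isna()][0]
            raise ValidationError(f"non-numeric count at gene {gene!r}, sample {col!r}")
        if (numeric < 0).any():
            gene = raw.index[numeric < 0][0]
            raise ValidationError(f"negative count at gene {gene!r}, sample {col!r}")
    counts = raw[sheet["sample_id"].tolist()].astype(float)
    return CountTable(counts=counts, samples=sheet, normalized=False)


def write_count_matrix(table: CountTable, path, sheet_path=None) -> None:
    out = table.counts.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    if sheet_path is not None:
        table.samples.to_csv(sheet_path, sep="\t", index=False)


def _read_fasta_dict(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ValidationError(f"duplicate FASTA record {record.id!r} in {path}")
        seqs[record.id] = str(record.seq).upper().replace("U", "T")
    return seqs


def read_fasta_regions(utr5_path, cds_path, utr3_path, annot_path) -> GeneSequences:
    """Assemble per-gene region sequences from three FASTAs plus annotation.

    Genes missing a region get an empty string for it. 'U' is mapped to 'T'
    and case is folded. A CDS whose length is not a positive multiple of 3
    is flagged (``cds_valid=False``) and excluded from codon operations but
    kept for length/GC features; this is logged, not fatal.
    """
    utr5 = _read_fasta_dict(utr5_path)
    cds = _read_fasta_dict(cds_path)
    utr3 = _read_fasta_dict(utr3_path)
    annot = pd.read_csv(annot_path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "exon_count"} <= set(annot.columns):
        raise ValidationError(f"{annot_path}: need columns gene_id, exon_count")
    annot = annot.set_index("gene_id")

    genes = sorted(set(utr5) | set(cds) | set(utr3) | set(annot.index))
    rows = []
    for gene in genes:
        c = cds.get(gene, "")
        valid = len(c) >= 3 and len(c) % 3 == 0
        if c and not valid:
            logger.warning(
                "gene %s: CDS length %d not a multiple of 3; excluded from codon operations",
                gene,
                len(c),
            )
        rows.append(
            {
                "gene_id": gene,
                "utr5": utr5.get(gene, ""),
                "cds": c,
                "utr3": utr3.get(gene, ""),
                "exon_count": int(annot.loc[gene, "exon_count"]) if gene in annot.index else 1,
                "cds_valid": valid,
            }
        )
    records = pd.DataFrame(rows).set_index("gene_id")
    return GeneSequences(records=records)


def write_fasta_regions(seqs: GeneSequences, utr5_path, cds_path, utr3_path, annot_path) -> None:
    for column, path in (("utr5", utr5_path), ("cds", cds_path), ("utr3", utr3_path)):
        with open(path, "w") as handle:
            for gene, seq in seqs.records[column].items():
                if seq:
                    handle.write(f">{gene}\n")
                    for i in range(0, len(seq), 70):
                        handle.write(seq[i : i + 70] + "\n")
    annot = seqs.records[["exon_count"]].copy()
    annot.insert(0, "gene_id", annot.index)
    annot.to_csv(annot_path, sep="\t", index=False)


def read_trna_table(path) -> TRNAPool:
    """Read a tRNA pool TSV with columns ``anticodon``, ``copy_number``."""
    table = pd.read_csv(path, sep="\t", dtype={"anticodon": str})
    if not {"anticodon", "copy_number"} <= set(table.columns):
        raise ValidationError(f"{path}: need columns anticodon, copy_number")
    table["anticodon"] = table["anticodon"].str.upper().str.replace("U", "T")
    if table["anticodon"].duplicated().any():
        dups = table.loc[table["anticodon"].duplicated(), "anticodon"].tolist()
        raise ValidationError(f"duplicate anticodon rows: {dups}")
    for ac in table["anticodon"]:
        if len(ac) != 3 or set(ac) - set("ACGT"):
            raise ValidationError(f"invalid anticodon {ac!r}")
    series = table.set_index("anticodon")["copy_number"].astype(float)
    return TRNAPool(copy_numbers=series)


def write_trna_table(pool: TRNAPool, path) -> None:
    out = pool.copy_numbers.rename("copy_number").reset_index()
    out.columns = ["anticodon", "copy_number"]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_target_list(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def write_target_list(gene_ids, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def write_table(frame: pd.DataFrame, path, index_label: str | None = "gene_id") -> None:
    """Write a result table as TSV with 12-significant-digit floats."""
    frame.to_csv(
        path,
        sep="\t",
        float_format=FLOAT_FORMAT,
        index=index_label is not None,
        index_label=index_label,
    )


def read_table(path, index_col: str | None = "gene_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
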
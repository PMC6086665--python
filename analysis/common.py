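"""Shared configuration of the synthetic two-knockout study.

One wild type and two knockouts acting on the same 300-gene miRNA-target
set: an effector-style knockout that only derepresses target translation
(2-fold), and a biogenesis-style knockout that derepresses both target
stability and translation (2-fold each). The stability-translation
correlation knob is set to 0.3 to emulate the positive coupling real
transcriptomes show between the two quantities.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "data"
RESULTS_DIR = ROOT / "results"

SEED = 1

STUDY_CONFIG = {
    "simulate": {
        "n_genes": 2000,
        "n_targets": 300,
        "stability_translation_corr": 0.3,
        "utr3_len_beta_coupling": 0.3,
        "are_beta_coupling": 0.5,
        "genotype_effects": {
            "WT": [1.0, 1.0],
            "KO_effector": [1.0, 2.0],   # translation derepression only
            "KO_mirna": [2.0, 2.0],      # stability + translation derepression
        },
        "seed": SEED,
    },
    "thresholds": {"min_cpm": 3, "min_reps": 3, "fdr": 0.05, "pseudocount": 0.5},
    "contrasts": [
        {"name": "effector_stability", "type": "stability", "genotypes": ["WT", "KO_effector"]},
        {"name": "effector_translation", "type": "translation", "genotypes": ["WT", "KO_effector"]},
        {"name": "mirna_stability", "type": "stability", "genotypes": ["WT", "KO_mirna"]},
        {"name": "mirna_translation", "type": "translation", "genotypes": ["WT", "KO_mirna"]},
    ],
    "targets": {"seed": "AAGTGC", "min_sites": 1},
    "seed": SEED,
}


def load_counts():
    from mrnastab import io

    return io.read_count_matrix(DATA_DIR / "counts.tsv", DATA_DIR / "sample_sheet.tsv")


def load_sequences():
    from mrnastab import io

    return io.read_fasta_regions(
        DATA_DIR / "utr5.fasta",
        DATA_DIR / "cds.fasta",
        DATA_DIR / "utr3.fasta",
        DATA_DIR / "annotation.tsv",
    )


def load_truth():
    from mrnastab import io

    return io.read_table(DATA_DIR / "truth.tsv")
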
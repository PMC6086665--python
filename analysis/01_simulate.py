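"""Simulate the multi-assay two-knockout study.

Writes counts, sample sheet, region FASTAs, annotation, tRNA pool, target
list and the ground-truth table under results/data/. Everything downstream
reads these files, so the whole analysis can be reproduced from this one
seed.
"""

from common import DATA_DIR, STUDY_CONFIG

from mrnastab import pipeline


def main():
    results = pipeline.run_pipeline(STUDY_CONFIG, DATA_DIR, stages=())
    counts = results["counts"]
    sheet = counts.samples
    print(f"simulated {counts.counts.shape[0]} genes x {counts.counts.shape[1]} samples")
    print(
        "assays:",
        ", ".join(sorted(sheet["assay"].unique())),
        "| genotypes:",
        ", ".join(sheet["genotype"].unique()),
    )
    print(f"inputs written to {DATA_DIR}")


if __name__ == "__main__":
    main()
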
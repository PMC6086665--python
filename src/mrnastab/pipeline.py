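"""End-to-end pipeline driver: simulate or load inputs, run every analysis
stage, write result TSVs and a reproducibility log.

The configuration is a plain mapping (usually parsed from a YAML file):

    simulate:            # optional; omit and give `inputs:` to load files
      n_genes: 2000
      n_targets: 300
      genotype_effects: {WT: [1, 1], KO: [1, 2]}
    inputs:              # optional; paths to counts/sample_sheet/FASTAs/...
      counts: counts.tsv
      sample_sheet: samples.tsv
    thresholds: {min_cpm: 3, min_reps: 3, fdr: 0.05, pseudocount: 0.5}
    contrasts:
      - {name: KO_stability, type: stability, genotypes: [WT, KO]}
      - {name: KO_translation, type: translation, genotypes: [WT, KO]}
    targets: {seed: AAGTGC, min_sites: 1}   # or {list: targets.txt}
    seed: 1

Every stage failure is re-raised with a stage label. Identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, codon, features, io, kinetics, simulate, targets
from .containers import CountTable, GeneSequences, TRNAPool, ValidationError

logger = logging.getLogger(__name__)

STAGES = ("simulate", "stability", "translation", "differential", "features", "codon", "targets")

DEFAULT_THRESHOLDS = {"min_cpm": 3.0, "min_reps": 3, "fdr": 0.05, "pseudocount": 0.5}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"[{name}] {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _sim_config(config: dict) -> simulate.SimConfig:
    params = dict(config.get("simulate", {}))
    if "genotype_effects" in params and params["genotype_effects"] is not None:
        params["genotype_effects"] = {
            g: tuple(v) for g, v in params["genotype_effects"].items()
        }
    if "assays" in params:
        params["assays"] = tuple(params["assays"])
    params.setdefault("seed", int(config.get("seed", 0)))
    return simulate.SimConfig(**params)


def _load_inputs(config: dict, outdir: Path):
    """Return (CountTable, GeneSequences|None, TRNAPool|None, target list|None)."""
    if "simulate" in config:
        sim = _sim_config(config)
        rng = np.random.default_rng(sim.seed)
        truth = simulate.generate_truth(sim)
        counts = simulate.sample_counts(truth, sim, rng=np.random.default_rng(sim.seed + 1))
        seqs = simulate.generate_sequences(truth, sim, rng=np.random.default_rng(sim.seed + 2))
        pool = simulate.simulate_trna_pool(rng=np.random.default_rng(sim.seed + 3))
        truth_out = truth.genes.copy()
        for genotype in truth.stability_effect.columns:
            truth_out[f"stability_effect_{genotype}"] = truth.stability_effect[genotype]
            truth_out[f"translation_effect_{genotype}"] = truth.translation_effect[genotype]
        io.write_table(truth_out, outdir / "truth.tsv")
        io.write_count_matrix(counts, outdir / "counts.tsv", outdir / "sample_sheet.tsv")
        io.write_fasta_regions(
            seqs,
            outdir / "utr5.fasta",
            outdir / "cds.fasta",
            outdir / "utr3.fasta",
            outdir / "annotation.tsv",
        )
        io.write_trna_table(pool, outdir / "trna_pool.tsv")
        io.write_target_list(truth.target_ids, outdir / "targets.txt")
        return counts, seqs, pool, list(truth.target_ids)

    inputs = config.get("inputs")
    if not inputs:
        raise ValidationError("config needs either a `simulate` or an `inputs` section")
    counts = io.read_count_matrix(inputs["counts"], inputs["sample_sheet"])
    seqs = None
    if all(k in inputs for k in ("utr5_fasta", "cds_fasta", "utr3_fasta", "annotation")):
        seqs = io.read_fasta_regions(
            inputs["utr5_fasta"], inputs["cds_fasta"], inputs["utr3_fasta"], inputs["annotation"]
        )
    pool = io.read_trna_table(inputs["trna_table"]) if "trna_table" in inputs else None
    target_list = (
        io.read_target_list(inputs["target_list"]) if "target_list" in inputs else None
    )
    return counts, seqs, pool, target_list


def _check_contrasts(config: dict, counts: CountTable) -> list[dict]:
    contrasts = config.get("contrasts", [])
    sheet = counts.samples
    for contrast in contrasts:
        num, den = kinetics.CONTRAST_ASSAYS[contrast["type"]]
        for genotype in contrast["genotypes"]:
            for assay in (den, num):
                cell = sheet[(sheet["assay"] == assay) & (sheet["genotype"] == genotype)]
                if cell.empty:
                    raise ValidationError(
                        f"contrast {contrast.get('name', contrast['type'])!r} needs "
                        f"assay {assay!r} for genotype {genotype!r}: no such samples"
                    )
                if len(cell) < 2:
                    raise ValidationError(
                        f"(assay={assay}, genotype={genotype}) has {len(cell)} replicate(s); "
                        "need >= 2"
                    )
    return contrasts


def run_pipeline(config: dict, outdir, stages=STAGES) -> dict:
    """Run the requested stages; returns the in-memory results keyed by name."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    seed = int(config.get("seed", 0))
    results: dict = {}

    with _stage("load"):
        counts, seqs, pool, target_list = _load_inputs(config, outdir)
        contrasts = _check_contrasts(config, counts)
        cpm = kinetics.cpm_normalize(counts)
        results["counts"], results["sequences"] = counts, seqs

    reference = counts.samples["genotype"].iloc[0]
    assays_present = set(counts.samples["assay"])
    pseudo = thresholds["pseudocount"]

    stability = None
    if "stability" in stages and {"nascent_4sU", "total"} <= assays_present:
        with _stage("stability"):
            sub = cpm.select(assays=["nascent_4sU", "total"])
            keep = kinetics.filter_expressed(sub, thresholds["min_cpm"], thresholds["min_reps"])
            stability = kinetics.stability_scores(sub.subset_genes(keep), pseudo)
            io.write_table(stability.scores, outdir / "stability.tsv")
            results["stability"] = stability

    translation = None
    if "translation" in stages and {"monosome", "high_polysome"} <= assays_present:
        with _stage("translation"):
            sub = cpm.select(assays=["monosome", "high_polysome"])
            keep = kinetics.filter_expressed(sub, thresholds["min_cpm"], thresholds["min_reps"])
            translation = kinetics.translation_levels(sub.subset_genes(keep), pseudo)
            io.write_table(translation.scores, outdir / "translation.tsv")
            results["translation"] = translation
    if "translation" in stages and {"rpf", "total"} <= assays_present:
        with _stage("te"):
            sub = cpm.select(assays=["rpf", "total"])
            keep = kinetics.filter_expressed(sub, thresholds["min_cpm"], thresholds["min_reps"])
            te = kinetics.translational_efficiency(sub.subset_genes(keep), pseudo)
            io.write_table(te.scores, outdir / "te.tsv")
            results["te"] = te

    differentials: dict[str, kinetics.DifferentialResult] = {}
    if "differential" in stages and contrasts:
        with _stage("differential"):
            for contrast in contrasts:
                name = contrast.get("name", contrast["type"])
                result = kinetics.differential_test(
                    counts,
                    contrast["type"],
                    tuple(contrast["genotypes"]),
                    pseudocount=pseudo,
                    min_cpm=thresholds["min_cpm"],
                    min_reps=thresholds["min_reps"],
                    shrink_var=bool(config.get("shrink_var", False)),
                )
                io.write_table(result.table, outdir / f"differential_{name}.tsv")
                differentials[name] = result
            results["differential"] = differentials

    feature_table = None
    if "features" in stages and seqs is not None:
        with _stage("features"):
            feature_table = features.extract_features(seqs)
            io.write_table(feature_table, outdir / "features.tsv")
            results["features"] = feature_table
            if stability is not None and reference in stability.scores.columns:
                ref_scores = stability.scores[reference]
                r2, coefs = features.fit_feature_regression(feature_table, ref_scores)
                io.write_table(coefs, outdir / "feature_regression.tsv", index_label="feature")
                (outdir / "feature_regression_summary.txt").write_text(
                    f"r_squared\t{r2:.12g}\nn_genes\t{len(feature_table.index.intersection(ref_scores.dropna().index))}\n"
                )
                corr = features.feature_correlations(feature_table, ref_scores)
                io.write_table(corr, outdir / "feature_correlations.tsv", index_label="feature")
                results["feature_regression"] = (r2, coefs)
                results["feature_correlations"] = corr

    if "codon" in stages and seqs is not None:
        with _stage("codon"):
            freqs = codon.codon_frequency_table(seqs)
            io.write_table(freqs, outdir / "codon_frequencies.tsv")
            results["codon_frequencies"] = freqs
            comparisons = {}
            if stability is not None:
                for genotype in stability.scores.columns:
                    comp = codon.group_codon_comparison(freqs, stability.scores[genotype])
                    io.write_table(comp, outdir / f"codon_comparison_{genotype}.tsv",
                                   index_label="codon")
                    comparisons[genotype] = comp
                if len(comparisons) >= 2:
                    names = list(comparisons)
                    _, rho, p = codon.delta_median_comparison(
                        comparisons[names[0]]["delta"], comparisons[names[1]]["delta"]
                    )
                    (outdir / "codon_delta_correlation.txt").write_text(
                        f"contrast\t{names[0]}_vs_{names[1]}\nspearman_rho\t{rho:.12g}\np\t{p:.12g}\n"
                    )
                results["codon_comparisons"] = comparisons
            if pool is not None:
                weights = codon.tai_weights(pool)
                io.write_table(weights.table, outdir / "tai_weights.tsv", index_label="codon")
                stai = codon.stai_scores(seqs, weights)
                io.write_table(stai.to_frame(), outdir / "stai.tsv")
                results["stai"] = stai

    if "targets" in stages:
        with _stage("targets"):
            if target_list is not None:
                universe = counts.gene_ids
                tset = targets.target_set_from_list(target_list, universe)
            elif seqs is not None:
                tcfg = config.get("targets", {})
                tset = targets.build_target_set(
                    seqs, seed=tcfg.get("seed", "AAGTGC"),
                    min_sites=int(tcfg.get("min_sites", 1)),
                )
            else:
                tset = None
            if tset is not None and differentials:
                stab_d = {n: r for n, r in differentials.items() if r.contrast == "stability"}
                trans_d = {n: r for n, r in differentials.items()
                           if r.contrast in ("translation", "te")}
                rows = []
                for name, result in differentials.items():
                    shift, p = targets.group_shift_test(result.table["coef"], tset)
                    rows.append({"contrast": name, "median_shift": shift, "p": p})
                shifts = pd.DataFrame(rows)
                io.write_table(shifts, outdir / "target_shifts.tsv", index_label=None)
                results["target_shifts"] = shifts
                if len(stab_d) >= 2 or len(trans_d) >= 2:
                    summary = targets.decoupling_summary(stab_d, trans_d, tset)
                    io.write_table(summary.shifts, outdir / "decoupling_shifts.tsv",
                                   index_label=None)
                    io.write_table(summary.correlations, outdir / "decoupling_correlations.tsv",
                                   index_label=None)
                    results["decoupling"] = summary
            if stability is not None and reference in stability.scores.columns:
                scores = stability.scores[reference].dropna()
                iqr_fold = targets.percentile_fold_range(scores, 25, 75)
                extreme_fold = targets.percentile_fold_range(scores, 1, 99)
                (outdir / "stability_range.txt").write_text(
                    f"fold_25_75\t{iqr_fold:.12g}\nfold_1_99\t{extreme_fold:.12g}\n"
                )
                results["stability_range"] = (iqr_fold, extreme_fold)
            results["target_set"] = tset

    with _stage("log"):
        lines = [f"mrnastab {__version__}", f"seed\t{seed}"]
        lines += [f"{k}\t{v}" for k, v in sorted(thresholds.items())]
        lines += [f"stage\t{s}" for s in stages]
        (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")
    return results
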
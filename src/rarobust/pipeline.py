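"""End-to-end orchestration: simulate -> preprocess -> patterns ->
COMPACT -> trajectory, with every intermediate written to a run
directory and a machine-readable JSON summary."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

import rarobust
from rarobust.compact import build_compact, categorize_genes, coarse_grain
from rarobust.containers import CtTable, ExpressionMatrix
from rarobust.config import RunConfig
from rarobust.genesets import GeneSetCatalog
from rarobust import io as rio
from rarobust.patterns import (
    clutch_mean,
    count_patterns,
    differential_vs_control,
    differential_vs_t0,
    discretize,
    overall_overlap_fraction,
)
from rarobust.preprocess import (
    combine_assays,
    delta_delta_ct,
    filter_min_expression,
    log2_transform,
    quantile_normalize,
    significance_filter,
    zscore_genes,
)
from rarobust.simulate import simulate_dataset
from rarobust.trajectory import analyze_trajectories

logger = logging.getLogger(__name__)


def to_counts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform a log2 matrix to the linear count scale (2^x)."""
    if matrix.scale != "log2":
        raise ValueError("expected a log2-scale matrix")
    return ExpressionMatrix(
        np.power(2.0, matrix.values), matrix.samples.copy(), "counts"
    )


def preprocess_counts(
    counts: ExpressionMatrix, min_count: float, pseudocount: float
) -> ExpressionMatrix:
    """Filter, log2-transform and quantile-normalize a count matrix."""
    filtered = filter_min_expression(counts, min_count)
    logged = log2_transform(filtered, pseudocount)
    return quantile_normalize(logged)


def control_normalized_patterns(
    averaged: ExpressionMatrix,
    significant: dict[str, list[str]],
    fold_control: float,
    treatments: tuple[str, ...] = ("RA", "DEAB"),
) -> dict[str, pd.DataFrame]:
    """Control-referenced T=4 ternary patterns per treatment.

    The gene universe is the union of the per-treatment significant
    sets; a gene not significant for a treatment keeps the all-zero
    pattern on that axis.
    """
    universe = sorted(set().union(*significant.values()))
    out = {}
    for treatment in treatments:
        diff = differential_vs_control(averaged, treatment)
        patterns = discretize(diff, fold_control)
        keep = set(significant[treatment])
        patterns.loc[[g for g in patterns.index if g not in keep]] = 0
        out[treatment] = patterns.loc[universe]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict.

    Writes every intermediate table under ``config.outdir`` and a
    ``summary.json`` whose content is a pure function of the config
    (two runs with the same config and seed are byte-identical).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if config.verbose:
        logging.basicConfig(level=logging.INFO)

    # ---- stage 1: simulate -------------------------------------------------
    matrix, ct, truth = simulate_dataset(config.simulation)
    rio.write_expression(matrix, out / "expression_log2.tsv", out / "samples.tsv")
    rio.write_ct_table(ct, out / "ct_records.tsv", out / "ct_samples.tsv")
    rio.write_frame(truth.genes, out / "truth_genes.tsv")
    rio.write_frame(truth.clutches, out / "truth_clutches.tsv")

    # ---- stage 2: preprocess the RNA-seq-like half -------------------------
    rnaseq = matrix.subset_samples((matrix.samples["assay"] == "rnaseq").to_numpy())
    normalized = preprocess_counts(
        to_counts(rnaseq), config.min_count, config.pseudocount
    )
    rio.write_expression(
        normalized, out / "rnaseq_normalized.tsv", out / "rnaseq_samples.tsv"
    )

    # significance gates: all-treatment gate for the t0 patterns, and a
    # per-treatment (Control + one perturbation) gate for the COMPACT
    sig_all = significance_filter(normalized, config.q_threshold)
    sig_per_treatment: dict[str, list[str]] = {}
    for treatment in ("RA", "DEAB"):
        mask = normalized.samples["treatment"].isin(["Control", treatment]).to_numpy()
        sig_per_treatment[treatment] = significance_filter(
            normalized.subset_samples(mask), config.q_threshold
        )
    rio.write_gene_list(sig_all, out / "significant_genes.txt")
    for treatment, genes in sig_per_treatment.items():
        rio.write_gene_list(genes, out / f"significant_{treatment.lower()}.txt")

    # ---- stage 3: t0-referenced patterns (T = 3, two-fold) -----------------
    averaged = clutch_mean(normalized)
    diffs_t0 = differential_vs_t0(averaged)
    tables_t0 = {}
    for treatment, diff in diffs_t0.items():
        patterns = discretize(diff.loc[[g for g in diff.index if g in set(sig_all)]],
                              config.fold_t0)
        tables_t0[treatment] = count_patterns(patterns, comparison=f"{treatment}_vs_t0")
        rio.write_frame(
            tables_t0[treatment].to_frame(),
            out / f"patterns_t0_{treatment.lower()}.tsv",
            index=False,
        )
    overlap = overall_overlap_fraction(tables_t0)

    # ---- stage 4: COMPACT (T = 4, 1.3-fold, control-referenced) ------------
    patterns_ctl = control_normalized_patterns(
        averaged, sig_per_treatment, config.fold_control
    )
    compact = build_compact(patterns_ctl["DEAB"], patterns_ctl["RA"])
    coarse = coarse_grain(compact)
    categories = categorize_genes(patterns_ctl["RA"], patterns_ctl["DEAB"])
    rio.write_frame(
        pd.DataFrame(compact.counts), out / "compact_fine.csv", sep=","
    )
    rio.write_frame(compact.to_long_frame(), out / "compact_long.tsv", index=False)
    rio.write_frame(coarse, out / "compact_coarse.csv", sep=",")
    rio.write_frame(categories, out / "gene_categories.tsv")

    # ---- stage 5: trajectory on the combined 144-sample matrix -------------
    z_rnaseq = zscore_genes(normalized)
    qpcr_log2 = delta_delta_ct(ct)
    z_qpcr = zscore_genes(qpcr_log2)
    combined = combine_assays(z_rnaseq, z_qpcr)
    rio.write_expression(combined, out / "combined_z.tsv", out / "combined_samples.tsv")
    catalog = GeneSetCatalog.default()
    gene_sets = {label: catalog[label] for label in catalog.labels()}
    traj = analyze_trajectories(
        combined,
        gene_sets,
        smoother_df=config.smoother_df,
        tol=config.curve_tol,
        max_iter=config.curve_max_iter,
    )
    rio.write_frame(traj["shifts"], out / "shift_table.tsv", index=False)
    if traj["quadrants"] is not None:
        rio.write_frame(traj["quadrants"], out / "quadrants.tsv", index=False)
    for label, curve in traj["curves"].items():
        rio.write_frame(
            pd.DataFrame(curve.vertices, columns=["PC1", "PC2", "PC3"]),
            out / f"curve_vertices_{label}.tsv",
            index=False,
        )
        rio.write_frame(
            traj["lambdas"][label].rename("lambda").to_frame(),
            out / f"lambda_{label}.tsv",
        )
        rio.write_frame(traj["scores"][label], out / f"scores_{label}.tsv")

    # ---- summary -----------------------------------------------------------
    n_start = int(
        (
            (combined.samples["treatment"] == "Control")
            & (combined.samples["time_h"] == 0.0)
        ).sum()
    )
    category_counts = categories["category"].value_counts().to_dict()
    summary = {
        "config": config.to_dict(),
        "n_samples_simulated": matrix.n_samples,
        "n_samples_combined": combined.n_samples,
        "n_samples_non_start": combined.n_samples - n_start,
        "n_genes_simulated": matrix.n_genes,
        "n_genes_after_filter": normalized.n_genes,
        "n_significant_all": len(sig_all),
        "n_significant_per_treatment": {
            k: len(v) for k, v in sig_per_treatment.items()
        },
        "t0_pattern_counts": {
            trt: {"n_genes": tab.n_genes, "n_patterns_occupied": int((tab.counts > 0).sum())}
            for trt, tab in tables_t0.items()
        },
        "t0_overlap_fraction_specific": overlap.to_dict(),
        "compact": {
            "fine_shape": list(compact.counts.shape),
            "n_genes": compact.n_genes,
            "n_cells_occupied": int((compact.counts > 0).sum()),
            "coarse_shape": list(coarse.shape),
            "coarse_total": int(coarse.to_numpy().sum()),
        },
        "category_counts": category_counts,
        "shift_table": traj["shifts"],
        "rankings": {
            f"{label}_{trt}": order for (label, trt), order in traj["rankings"].items()
        },
        "quadrants": traj["quadrants"],
    }
    rio.write_json(summary, out / "summary.json")
    (out / "run_log.txt").write_text(
        "rarobust {} | numpy {} | pandas {}\nseed: {}\noutdir: {}\n".format(
            rarobust.__version__,
            np.__version__,
            pd.__version__,
            config.simulation.seed,
            out,
        )
    )
    logger.info("pipeline complete: %s", out)
    return summary
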
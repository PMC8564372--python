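"""Normalization and significance gating of expression matrices.

The stage mirrors a standard bulk time-course workflow: a minimum-count
filter, log2 transform, quantile normalization across samples, gene-wise
Z-scoring within each assay, qPCR dCt/ddCt quantification, combination
of the two assay halves, and a per-gene two-way ANOVA (time, treatment,
interaction) with Benjamini-Hochberg correction that gates which genes
enter the pattern analyses.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rarobust.containers import CtTable, ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_min_expression(matrix: ExpressionMatrix, min_count: float) -> ExpressionMatrix:
    """Drop genes whose count is below ``min_count`` in *every* sample.

    A gene survives if at least one sample reaches the threshold; gene
    order is preserved.
    """
    if matrix.scale != "counts":
        raise ValueError(f"expected a counts-scale matrix, got {matrix.scale!r}")
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    keep = (matrix.values >= min_count).any(axis=1)
    return ExpressionMatrix(matrix.values.loc[keep], matrix.samples.copy(), "counts")


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count + pseudocount); records the log2 scale."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative values on the count scale")
    return ExpressionMatrix(
        np.log2(matrix.values + pseudocount), matrix.samples.copy(), "log2"
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean order-statistic distribution.

    After the call each sample's sorted value vector equals the
    across-sample mean of order statistics; within-sample ranks are
    preserved.  Tied values receive the mean of the order-statistic
    means their tie block spans.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = matrix.values.to_numpy(dtype=float)
    sorted_means = np.sort(arr, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(sorted_means)])
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        rmin = stats.rankdata(col, method="min").astype(int)
        rmax = stats.rankdata(col, method="max").astype(int)
        out[:, j] = (csum[rmax] - csum[rmin - 1]) / (rmax - rmin + 1)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.samples.copy(),
        matrix.scale,
    )


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise Z-score (sample sd, ddof = 1) across the matrix columns.

    Constant genes carry no pattern information and would produce
    non-finite scores; they are dropped with a warning.
    """
    values = matrix.values
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd < 1e-12
    if constant.any():
        dropped = values.index[constant].tolist()
        warnings.warn(
            f"dropping {len(dropped)} constant gene(s) before Z-scoring: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        values, mean, sd = values.loc[~constant], mean[~constant], sd[~constant]
    z = values.sub(mean, axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, matrix.samples.copy(), "zscore")


def collapse_ct(ct_table: CtTable) -> pd.DataFrame:
    """One Ct per gene x sample: median over pre-amplification groups of
    the per-group technical-replicate median.

    The median over the three primer pools (L homeolog, S homeolog,
    both) suppresses homeolog-specific amplification differences.
    """
    per_group = (
        ct_table.records.groupby(["gene_id", "sample_id", "preamp_group"])["ct"]
        .median()
        .reset_index()
    )
    return per_group.pivot_table(
        index="gene_id", columns="sample_id", values="ct", aggfunc="median"
    )


def delta_delta_ct(
    ct_table: CtTable,
    reference_treatment: str = "Control",
    reference_time: float = 0.0,
) -> ExpressionMatrix:
    """Relative log2 expression via the ddCt method.

    dCt = Ct_gene - Ct_housekeeping per sample; ddCt subtracts the same
    clutch's reference sample (``reference_treatment`` at
    ``reference_time``); reported log2 expression is -ddCt, so a target
    one cycle below the reference maps to +1 (two-fold up).  The
    housekeeping gene is removed from the output.
    """
    ct = collapse_ct(ct_table)
    meta = ct_table.samples
    if ct_table.housekeeping not in ct.index:
        raise ValueError(f"housekeeping gene {ct_table.housekeeping!r} missing")
    missing_hk = ct.loc[ct_table.housekeeping].isna()
    if missing_hk.any():
        raise ValueError(
            f"housekeeping Ct missing in samples {ct.columns[missing_hk].tolist()[:5]}"
        )
    dct = ct.sub(ct.loc[ct_table.housekeeping], axis=1).drop(index=ct_table.housekeeping)

    is_ref = (meta["treatment"] == reference_treatment) & (
        meta["time_h"] == reference_time
    )
    ref_by_clutch = meta.index[is_ref].to_series().groupby(meta.loc[is_ref, "clutch"])
    missing = set(meta["clutch"]) - set(ref_by_clutch.groups)
    if missing:
        raise ValueError(
            f"no {reference_treatment!r} @ {reference_time} h reference for "
            f"clutches {sorted(missing)}"
        )
    ref_sample = ref_by_clutch.first()
    ref_cols = meta.loc[dct.columns, "clutch"].map(ref_sample)
    ddct = dct - dct[ref_cols.to_numpy()].to_numpy()
    return ExpressionMatrix(-ddct, meta.loc[ddct.columns].copy(), "log2")


def combine_assays(
    z_matrix_a: ExpressionMatrix, z_matrix_b: ExpressionMatrix
) -> ExpressionMatrix:
    """Column-concatenate two independently Z-scored assays on their
    shared gene panel."""
    for m in (z_matrix_a, z_matrix_b):
        if m.scale != "zscore":
            raise ValueError("both inputs must be Z-scored before combining")
    shared = [g for g in z_matrix_a.values.index if g in set(z_matrix_b.values.index)]
    if not shared:
        raise ValueError("gene panels of the two assays do not intersect")
    overlap = set(z_matrix_a.sample_ids) & set(z_matrix_b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids occur in both assays: {sorted(overlap)[:5]}")
    values = pd.concat(
        [z_matrix_a.values.loc[shared], z_matrix_b.values.loc[shared]], axis=1
    )
    samples = pd.concat([z_matrix_a.samples, z_matrix_b.samples])
    return ExpressionMatrix(values, samples, "zscore")


def _hat(design: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the design column space, and its rank.

    SVD-based: the dummy blocks are deliberately full (no reference
    level), so designs are rank-deficient and an unpivoted QR would not
    isolate the column space.
    """
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    u = u[:, :rank]
    return u @ u.T, rank


def anova_two_way(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene fixed-effects two-way ANOVA over (time, treatment).

    All genes share the sample design, so residual sums of squares for
    the nested model sequence are obtained with precomputed projection
    matrices.  Effect sums of squares are partial (type II): interaction
    = additive vs full, each main effect = single-factor vs additive;
    F statistics use the full-model residual mean square.  Returns a
    DataFrame with p-values per effect and their per-gene minimum.
    """
    meta = matrix.samples
    time = pd.Categorical(meta["time_h"])
    treatment = pd.Categorical(meta["treatment"])
    if len(time.categories) < 2 or len(treatment.categories) < 2:
        raise ValueError("both time and treatment need at least 2 levels")
    cell = pd.Categorical(list(zip(meta["time_h"], meta["treatment"])))
    counts = pd.Series(cell).value_counts()
    if (counts < 2).any():
        raise ValueError("unreplicated (time, treatment) cells: no residual df")

    n = len(meta)
    one = np.ones((n, 1))
    d_time = pd.get_dummies(time, dtype=float).to_numpy()
    d_trt = pd.get_dummies(treatment, dtype=float).to_numpy()
    d_cell = pd.get_dummies(cell, dtype=float).to_numpy()

    h_full, r_full = _hat(np.hstack([one, d_cell]))
    h_add, r_add = _hat(np.hstack([one, d_time, d_trt]))
    h_time, r_time = _hat(np.hstack([one, d_time]))
    h_trt, r_trt = _hat(np.hstack([one, d_trt]))

    y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    total = (y * y).sum(axis=0)

    def rss(h: np.ndarray) -> np.ndarray:
        return total - (y * (h @ y)).sum(axis=0)

    rss_full, rss_add, rss_time, rss_trt = rss(h_full), rss(h_add), rss(h_time), rss(h_trt)
    df_resid = n - r_full
    df_int = r_full - r_add
    df_time = r_add - r_trt  # time | treatment
    df_trt = r_add - r_time  # treatment | time
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_resid

    def f_pvalue(ss: np.ndarray, df: int) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss / df) / mse
        p = stats.f.sf(f, df, df_resid)
        return np.where(np.isfinite(f), p, 1.0)

    p_time = f_pvalue(np.maximum(rss_trt - rss_add, 0.0), df_time)
    p_trt = f_pvalue(np.maximum(rss_time - rss_add, 0.0), df_trt)
    p_int = f_pvalue(np.maximum(rss_add - rss_full, 0.0), df_int)
    out = pd.DataFrame(
        {
            "p_time": p_time,
            "p_treatment": p_trt,
            "p_interaction": p_int,
        },
        index=matrix.values.index,
    )
    out["p_min"] = out.min(axis=1)
    return out


def significance_filter(
    matrix: ExpressionMatrix,
    q_threshold: float = 0.05,
    return_table: bool = False,
):
    """Genes with a significant time, treatment or interaction effect.

    Per gene the minimum of the three effect p-values is taken, then
    Benjamini-Hochberg adjusted across genes; gene ids with
    q <= ``q_threshold`` are returned (optionally with the full table).
    """
    table = anova_two_way(matrix)
    _, q, _, _ = multipletests(table["p_min"].to_numpy(), method="fdr_bh")
    table = table.assign(q=q)
    hits = table.index[table["q"] <= q_threshold].tolist()
    logger.info("significance gate: %d / %d genes at q <= %g", len(hits), len(table), q_threshold)
    if return_table:
        return hits, table
    return hits
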
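"""Ternary dynamic-pattern analysis of averaged time courses.

A gene's differential time course is discretized to one call per time
point — up (+1), no change (0) or down (-1) — against a fold-change
threshold on the log2 scale.  The ordered vector of calls is the gene's
*dynamic pattern*; with T time points there are 3^T possible patterns.
Patterns are indexed in base 3 with the earliest time point as the most
significant digit (-1 -> 0, 0 -> 1, +1 -> 2), so encode/decode is a
bijection between pattern vectors and integers in [0, 3^T).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rarobust.containers import ExpressionMatrix

_GLYPHS = {-1: "-", 0: "0", 1: "+"}
_GLYPHS_INV = {"-": -1, "0": 0, "+": 1, "−": -1}  # accept unicode minus


def encode_pattern(values) -> int:
    """Base-3 integer index of a ternary pattern vector."""
    values = np.asarray(values, dtype=int)
    if not np.isin(values, (-1, 0, 1)).all():
        raise ValueError("pattern entries must be in {-1, 0, +1}")
    index = 0
    for v in values:
        index = index * 3 + (int(v) + 1)
    return index


def decode_pattern(index: int, t: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_pattern` for a T-point pattern."""
    if not 0 <= index < 3**t:
        raise ValueError(f"index {index} outside [0, {3 ** t})")
    digits = []
    for _ in range(t):
        digits.append(index % 3 - 1)
        index //= 3
    return tuple(reversed(digits))


def pattern_string(values) -> str:
    """Compact glyph form of a pattern, e.g. ``+00-``."""
    return "".join(_GLYPHS[int(v)] for v in values)


def parse_pattern(text: str) -> tuple[int, ...]:
    return tuple(_GLYPHS_INV[ch] for ch in text)


@dataclass
class PatternCountTable:
    """Complete gene tally over all 3^T patterns of one comparison."""

    comparison: str
    t: int
    counts: np.ndarray  # length 3**t
    gene_lists: list[list[str]]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3**self.t,):
            raise ValueError("counts must cover all 3^T pattern indices")
        if (self.counts < 0).any():
            raise ValueError("negative pattern count")

    @property
    def n_genes(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "pattern_index": i,
                "pattern_string": pattern_string(decode_pattern(i, self.t)),
                "count": int(c),
                "gene_ids": ",".join(self.gene_lists[i]),
            }
            for i, c in enumerate(self.counts)
        ]
        return pd.DataFrame(rows)


def clutch_mean(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average expression across clutches within each treatment x time.

    Returns a matrix with one column per (treatment, time) labelled
    ``{treatment}_{time}h``; metadata keeps treatment and time, with
    clutch set to ``mean``.
    """
    meta = matrix.samples
    groups = meta.groupby(["treatment", "time_h"], observed=True, sort=True)
    cols, meta_rows = {}, []
    for (treatment, time_h), sub in groups:
        label = f"{treatment}_{time_h:g}h"
        cols[label] = matrix.values[sub.index].mean(axis=1)
        meta_rows.append(
            {
                "sample_id": label,
                "clutch": "mean",
                "treatment": treatment,
                "time_h": time_h,
                "assay": "mixed" if sub["assay"].nunique() > 1 else sub["assay"].iloc[0],
            }
        )
    return ExpressionMatrix(
        pd.DataFrame(cols, index=matrix.values.index),
        pd.DataFrame(meta_rows).set_index("sample_id"),
        matrix.scale,
    )


def _pivot(averaged: ExpressionMatrix, treatment: str) -> pd.DataFrame:
    """Columns of one treatment, ordered by time; columns labelled by time."""
    meta = averaged.samples
    sub = meta[meta["treatment"] == treatment].sort_values("time_h")
    if sub.empty:
        raise ValueError(f"treatment {treatment!r} absent from averaged matrix")
    frame = averaged.values[sub.index]
    frame.columns = sub["time_h"].to_numpy()
    return frame


def differential_vs_t0(
    averaged: ExpressionMatrix, treatments: tuple[str, ...] | None = None
) -> dict[str, pd.DataFrame]:
    """Per-treatment differential against that treatment's own t = 0.

    Returns, per treatment, a gene x time DataFrame over the non-zero
    time points (T - 1 columns).
    """
    if treatments is None:
        treatments = tuple(dict.fromkeys(averaged.samples["treatment"]))
    out = {}
    for treatment in treatments:
        frame = _pivot(averaged, treatment)
        if 0.0 not in frame.columns:
            raise ValueError(f"no t = 0 column for treatment {treatment!r}")
        base = frame[0.0]
        rest = frame.drop(columns=[0.0])
        out[treatment] = rest.sub(base, axis=0)
    return out


def differential_vs_control(
    averaged: ExpressionMatrix, treatment: str, control: str = "Control"
) -> pd.DataFrame:
    """Treatment minus Control at matching time points (T columns)."""
    trt = _pivot(averaged, treatment)
    try:
        ctl = _pivot(averaged, control)
    except ValueError as err:
        raise ValueError(f"control group {control!r} missing") from err
    shared = [t for t in trt.columns if t in set(ctl.columns)]
    if len(shared) != len(trt.columns):
        raise ValueError("Control is missing some treatment time points")
    return trt[shared].sub(ctl[shared].to_numpy())


def discretize(diff: pd.DataFrame, fold_threshold_linear: float) -> pd.DataFrame:
    """Threshold log2 differentials into ternary calls.

    The threshold is given as a linear fold change (> 1); a call is +1
    when the log2 difference is >= log2(threshold), -1 when <= -log2
    (threshold) (boundaries inclusive), else 0.
    """
    if fold_threshold_linear <= 1:
        raise ValueError("fold threshold must exceed 1 (linear scale)")
    tau = np.log2(fold_threshold_linear)
    arr = diff.to_numpy()
    tern = np.where(arr >= tau, 1, np.where(arr <= -tau, -1, 0))
    return pd.DataFrame(tern, index=diff.index, columns=diff.columns)


def count_patterns(patterns: pd.DataFrame, comparison: str = "") -> PatternCountTable:
    """Tally genes per pattern index over the complete 3^T grid."""
    t = patterns.shape[1]
    if t == 0:
        raise ValueError("empty pattern table")
    digits = patterns.to_numpy() + 1
    if not np.isin(digits, (0, 1, 2)).all():
        raise ValueError("pattern entries must be in {-1, 0, +1}")
    weights = 3 ** np.arange(t - 1, -1, -1)
    indices = digits @ weights
    counts = np.bincount(indices, minlength=3**t)
    gene_lists: list[list[str]] = [[] for _ in range(3**t)]
    for gene, idx in zip(patterns.index, indices):
        gene_lists[idx].append(gene)
    return PatternCountTable(comparison, t, counts, gene_lists)


def pattern_indices(patterns: pd.DataFrame) -> pd.Series:
    """Per-gene base-3 pattern index."""
    t = patterns.shape[1]
    weights = 3 ** np.arange(t - 1, -1, -1)
    return pd.Series((patterns.to_numpy() + 1) @ weights, index=patterns.index)


def pattern_overlap(tables_by_group: dict[str, PatternCountTable]) -> pd.DataFrame:
    """Per-pattern Venn partition of gene ids across groups.

    For every pattern index, genes are split into group-exclusive and
    shared compartments; the summary row per (pattern, group) reports
    the count exclusive to that group, the count shared with any other
    group, and the group-specific fraction.
    """
    ts = {tab.t for tab in tables_by_group.values()}
    if len(ts) != 1:
        raise ValueError("pattern tables have mixed T")
    (t,) = ts
    rows = []
    for idx in range(3**t):
        sets = {g: set(tab.gene_lists[idx]) for g, tab in tables_by_group.items()}
        for group, members in sets.items():
            others = set().union(*(s for g, s in sets.items() if g != group))
            exclusive = members - others
            shared = members & others
            rows.append(
                {
                    "pattern_index": idx,
                    "pattern_string": pattern_string(decode_pattern(idx, t)),
                    "group": group,
                    "n_genes": len(members),
                    "n_exclusive": len(exclusive),
                    "n_shared": len(shared),
                    "fraction_exclusive": (
                        len(exclusive) / len(members) if members else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def overall_overlap_fraction(tables_by_group: dict[str, PatternCountTable]) -> pd.Series:
    """Per-group fraction of its responding genes not responding elsewhere.

    A gene belongs to a group's responder set when its pattern there has
    at least one non-zero call; the all-zero (no-change) pattern is
    excluded, as in a Venn comparison of differentially changing genes.
    """
    universe: dict[str, set] = {}
    for g, tab in tables_by_group.items():
        zero_index = encode_pattern([0] * tab.t)
        universe[g] = set().union(
            *(lst for i, lst in enumerate(tab.gene_lists) if i != zero_index)
        )
    out = {}
    for group, members in universe.items():
        others = set().union(*(s for g, s in universe.items() if g != group))
        out[group] = len(members - others) / len(members) if members else np.nan
    return pd.Series(out, name="fraction_group_specific")
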
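"""COMPACT: comparative matrices of dynamic-pattern counts.

The COMPACT matrix crosses the control-normalized dynamic patterns of
two perturbations — here DEAB (reduced retinoic-acid synthesis, rows)
against RA (exogenous retinoic acid, columns).  Cell (i, j) counts the
genes with pattern index i under DEAB and j under RA; with T = 4 time
points that is an 81 x 81 grid (6561 cells).  Coarse-graining pools
patterns by response onset — the time of the first non-zero call and
its direction — into 9 groups per axis (1 no-change + 4 times x 2
directions), giving a 9 x 9 summary.

Genes are also classified by response direction into the quadrant
categories: both-up (a), RA-up/DEAB-down (b), RA-down/DEAB-up (c),
both-down (d), single-treatment responders, and non-responsive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rarobust.patterns import decode_pattern, pattern_indices, pattern_string

CATEGORIES = (
    "non-responsive",
    "RA-only",
    "DEAB-only",
    "quadrant-a",
    "quadrant-b",
    "quadrant-c",
    "quadrant-d",
)


@dataclass
class CompactMatrix:
    """Dense pattern-by-pattern gene-count grid with per-cell gene lists."""

    t: int
    counts: np.ndarray  # (3^T, 3^T); rows = DEAB pattern, cols = RA pattern
    gene_lists: dict[tuple[int, int], list[str]]
    row_label: str = "DEAB"
    col_label: str = "RA"

    def __post_init__(self) -> None:
        k = 3**self.t
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k} x {k} for T={self.t}")

    @property
    def k(self) -> int:
        return 3**self.t

    @property
    def n_genes(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def nonzero_submatrix(self) -> pd.DataFrame:
        """Rows/columns with any gene, labelled by pattern glyphs."""
        rows = np.flatnonzero(self.counts.sum(axis=1))
        cols = np.flatnonzero(self.counts.sum(axis=0))
        labels_r = [pattern_string(decode_pattern(i, self.t)) for i in rows]
        labels_c = [pattern_string(decode_pattern(j, self.t)) for j in cols]
        return pd.DataFrame(self.counts[np.ix_(rows, cols)], index=labels_r, columns=labels_c)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for (i, j), genes in sorted(self.gene_lists.items()):
            rows.append(
                {
                    "row_pattern": pattern_string(decode_pattern(i, self.t)),
                    "col_pattern": pattern_string(decode_pattern(j, self.t)),
                    "row_index": i,
                    "col_index": j,
                    "count": len(genes),
                    "gene_ids": ",".join(genes),
                }
            )
        return pd.DataFrame(rows)


def build_compact(
    patterns_deab: pd.DataFrame, patterns_ra: pd.DataFrame
) -> CompactMatrix:
    """Cross-tabulate two pattern tables over a shared gene universe."""
    if patterns_deab.shape[1] != patterns_ra.shape[1]:
        raise ValueError("pattern tables have different T")
    if not patterns_deab.index.equals(patterns_ra.index):
        raise ValueError("pattern tables cover different gene universes")
    t = patterns_deab.shape[1]
    k = 3**t
    idx_d = pattern_indices(patterns_deab)
    idx_r = pattern_indices(patterns_ra)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (idx_d.to_numpy(), idx_r.to_numpy()), 1)
    gene_lists: dict[tuple[int, int], list[str]] = {}
    for gene, i, j in zip(patterns_deab.index, idx_d, idx_r):
        gene_lists.setdefault((int(i), int(j)), []).append(gene)
    return CompactMatrix(t=t, counts=counts, gene_lists=gene_lists)


def onset_group(pattern) -> str:
    """Coarse label of a pattern: time slot and direction of first response.

    ``no-change`` for the all-zero pattern; otherwise ``t{k}-up`` or
    ``t{k}-down`` where k is the position (0-based) of the first
    non-zero call.
    """
    values = np.asarray(pattern, dtype=int)
    nz = np.flatnonzero(values)
    if nz.size == 0:
        return "no-change"
    first = nz[0]
    return f"t{first}-{'up' if values[first] > 0 else 'down'}"


def onset_labels(t: int) -> list[str]:
    """All coarse labels for T time points, in display order."""
    labels = ["no-change"]
    for k in range(t):
        labels += [f"t{k}-up", f"t{k}-down"]
    return labels


def coarse_grain(compact: CompactMatrix) -> pd.DataFrame:
    """Pool the fine grid by (row onset group, column onset group)."""
    labels = onset_labels(compact.t)
    group_of = np.array(
        [labels.index(onset_group(decode_pattern(i, compact.t))) for i in range(compact.k)]
    )
    n = len(labels)
    coarse = np.zeros((n, n), dtype=int)
    np.add.at(coarse, (group_of[:, None], group_of[None, :]), compact.counts)
    return pd.DataFrame(coarse, index=labels, columns=labels)


def pattern_direction(pattern) -> int:
    """Sign of the first non-zero call; 0 for the all-zero pattern."""
    values = np.asarray(pattern, dtype=int)
    nz = np.flatnonzero(values)
    return 0 if nz.size == 0 else int(np.sign(values[nz[0]]))


def is_mixed_sign(pattern) -> bool:
    values = np.asarray(pattern, dtype=int)
    return bool((values > 0).any() and (values < 0).any())


def classify_response(pattern_ra, pattern_deab) -> str:
    """Quadrant category of a gene from its RA and DEAB patterns."""
    ra = pattern_direction(pattern_ra)
    deab = pattern_direction(pattern_deab)
    if ra == 0 and deab == 0:
        return "non-responsive"
    if deab == 0:
        return "RA-only"
    if ra == 0:
        return "DEAB-only"
    if ra > 0 and deab > 0:
        return "quadrant-a"
    if ra > 0 and deab < 0:
        return "quadrant-b"
    if ra < 0 and deab > 0:
        return "quadrant-c"
    return "quadrant-d"


def categorize_genes(
    patterns_ra: pd.DataFrame, patterns_deab: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene category table; flags mixed-sign (non-monotone) patterns."""
    if not patterns_ra.index.equals(patterns_deab.index):
        raise ValueError("pattern tables cover different gene universes")
    rows = []
    for gene in patterns_ra.index:
        p_ra = patterns_ra.loc[gene].to_numpy()
        p_deab = patterns_deab.loc[gene].to_numpy()
        rows.append(
            {
                "gene_id": gene,
                "category": classify_response(p_ra, p_deab),
                "mixed_sign": is_mixed_sign(p_ra) or is_mixed_sign(p_deab),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
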
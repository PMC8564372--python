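"""Principal-curve trajectory analysis and the robustness shift score.

For a chosen gene panel the combined, Z-scored samples are projected
onto their first three principal components and a one-dimensional
principal curve is fitted through the score cloud.  The curve is
initialized with the oriented segment from (a) the centroid of the
0 h Control samples of all clutches to (b) the centroid of every other
sample, so arc distance λ = 0 sits at the unperturbed start state and λ
grows along the developmental trajectory.

Each sample's λ is its arc distance from the curve start.  For a clutch
and treatment the *net absolute expression shift*

    s = sum over time points t of |λ_treatment(t) - λ_control(t)| / max(λ)

measures how far, in normalized trajectory progress, the treated
samples sit from their clutch-matched controls, accumulated over the
recovery course.  A smaller s means the clutch restored normal
signaling faster — it is more robust to that perturbation.  Clutches
are ranked by s, and the two panel scores (hox = outcome, RA network =
feedback effort) place each clutch in an efficiency/efficacy quadrant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.decomposition import PCA

from rarobust.containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def pca_scores(
    matrix: ExpressionMatrix, gene_set, n_components: int = 3
) -> pd.DataFrame:
    """Sample scores on the top principal components of a gene panel.

    Genes are centered but not rescaled (the matrix is expected to be
    Z-scored already).  Each component's sign is fixed so that its
    largest-magnitude loading is positive, making scores reproducible
    across runs and libraries.
    """
    present = [g for g in gene_set if g in set(matrix.values.index)]
    if len(present) < n_components:
        raise ValueError(
            f"gene set has {len(present)} usable genes; need >= {n_components}"
        )
    data = matrix.values.loc[present].to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(data)
    for k in range(n_components):
        loading = pca.components_[k]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, k] *= -1.0
    frame = pd.DataFrame(
        scores,
        index=matrix.values.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)],
    )
    frame.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.copy()
    frame.attrs["genes"] = present
    return frame


@dataclass
class PrincipalCurve:
    """A fitted polyline in score space with per-sample projections."""

    vertices: np.ndarray  # (m, d) ordered from the λ = 0 end
    lambdas: np.ndarray  # (n,) arc distance of each sample's foot point
    residuals: np.ndarray  # (n,) squared distance to the curve
    projections: np.ndarray  # (n, d) foot points
    iterations: int
    converged: bool
    ssr_history: list[float] = field(default_factory=list)

    @property
    def total_ssr(self) -> float:
        return float(self.residuals.sum())

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.vertices, axis=0), axis=1).sum()
        )


def project_to_curve(points, vertices) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthogonally project points onto a polyline.

    Returns (λ, squared residual, foot point) per input point, where λ
    is the arc length from the first vertex to the foot.  When a point
    is equidistant from several segments the foot with the smaller λ is
    kept (numpy's first-minimum tie rule).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or len(vertices) < 2:
        raise ValueError("curve needs at least 2 vertices")
    seg_start = vertices[:-1]  # (m-1, d)
    diffs = np.diff(vertices, axis=0)
    seg_len2 = (diffs**2).sum(axis=1)
    seg_len = np.sqrt(seg_len2)
    cum_len = np.concatenate([[0.0], np.cumsum(seg_len)])

    # t* per (point, segment), clamped to the segment
    rel = points[:, None, :] - seg_start[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.einsum("psd,sd->ps", rel, diffs) / seg_len2
    t = np.nan_to_num(t, nan=0.0)
    t = np.clip(t, 0.0, 1.0)
    feet = seg_start[None, :, :] + t[:, :, None] * diffs[None, :, :]
    dist2 = ((points[:, None, :] - feet) ** 2).sum(axis=2)
    best = np.argmin(dist2, axis=1)
    rows = np.arange(len(points))
    lam = cum_len[best] + t[rows, best] * seg_len[best]
    return lam, dist2[rows, best], feet[rows, best]


def _spline_smooth(
    lam: np.ndarray, coords: np.ndarray, df: int
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cubic regression spline of each coordinate vs λ.

    ``df`` is the number of basis functions (>= 2); df = 4 is a single
    cubic polynomial, each extra df adds one interior knot at a λ
    quantile.  Returns fitted coordinates at the sorted unique λ values
    together with those λ values.
    """
    order = np.argsort(lam, kind="mergesort")
    x = lam[order]
    y = coords[order]
    grid = np.unique(x)
    span = x[-1] - x[0]
    if span <= 0:
        return grid, np.tile(y.mean(axis=0), (len(grid), 1))
    k = 3 if df >= 4 else max(1, df - 1)
    n_interior = max(df - (k + 1), 0)
    if n_interior:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(grid, qs)
    else:
        interior = np.array([])
    knots = np.concatenate(
        [np.full(k + 1, x[0]), interior, np.full(k + 1, x[-1])]
    )
    design = BSpline.design_matrix(x, knots, k).toarray()
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    design_grid = BSpline.design_matrix(grid, knots, k).toarray()
    return grid, design_grid @ coef


def fit_principal_curve(
    scores,
    start_a,
    start_b,
    smoother_df: int = 5,
    tol: float = 1e-4,
    max_iter: int = 50,
    stretch: float = 2.0,
) -> PrincipalCurve:
    """Iterative projection/smoothing fit of a principal curve.

    The curve is initialized as the oriented line through ``start_a`` ->
    ``start_b``; each iteration projects the samples onto the current
    polyline, smooths every coordinate as a spline function of λ,
    re-parameterizes the smoothed polyline by cumulative arc length and
    re-anchors λ = 0 at the end nearer ``start_a``.  Iteration stops
    when the total squared residual changes by less than ``tol``
    (relative) or stops decreasing; the best iterate is returned.

    ``stretch`` linearly extends both curve ends by that multiple of
    the terminal segment, preventing samples beyond the data's λ range
    from bunching at the end vertices (the same endpoint treatment the
    classical projection/expectation fitters use).
    """
    points = np.atleast_2d(np.asarray(scores, dtype=float))
    start_a = np.asarray(start_a, dtype=float)
    start_b = np.asarray(start_b, dtype=float)
    if len(points) < 4:
        raise ValueError("need at least 4 samples to fit a curve")
    direction = start_b - start_a
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("start_a and start_b coincide")
    if np.allclose(points, points[0]):
        raise ValueError("degenerate input: all samples identical")
    direction = direction / norm

    # initial λ: signed position along the start line, shifted to >= 0
    lam = (points - start_a) @ direction
    lam = lam - lam.min()

    best: PrincipalCurve | None = None
    ssr_prev = np.inf
    history: list[float] = []
    converged = False
    for iteration in range(1, max_iter + 1):
        grid, smooth = _spline_smooth(lam, points, smoother_df)
        if len(grid) < 2:
            raise ValueError("degenerate fit: fewer than 2 distinct λ values")
        vertices = smooth
        if stretch > 0:
            head = vertices[0] + stretch * (vertices[0] - vertices[1])
            tail = vertices[-1] + stretch * (vertices[-1] - vertices[-2])
            vertices = np.vstack([head, vertices, tail])
        # orient so the λ = 0 end is the one nearer start_a
        if np.linalg.norm(vertices[-1] - start_a) < np.linalg.norm(
            vertices[0] - start_a
        ):
            vertices = vertices[::-1]
        lam_new, res2, feet = project_to_curve(points, vertices)
        # anchor λ = 0 at the start-side-most sample projection, so λ is
        # unaffected by the end extensions and max(λ) is the sample span
        lam_new = lam_new - lam_new.min()
        ssr = float(res2.sum())
        if best is None or ssr <= best.total_ssr:
            best = PrincipalCurve(
                vertices=vertices,
                lambdas=lam_new,
                residuals=res2,
                projections=feet,
                iterations=iteration,
                converged=False,
                ssr_history=history + [ssr],
            )
        rel_change = abs(ssr_prev - ssr) / max(ssr_prev, 1e-12)
        if ssr <= ssr_prev:
            history.append(ssr)
        if rel_change < tol:
            converged = True
            break
        if ssr > ssr_prev:
            # residual increased: keep the best iterate, stop refining
            break
        ssr_prev = ssr
        lam = lam_new
    assert best is not None
    best.converged = converged
    best.ssr_history = history if history else [best.total_ssr]
    return best


def curve_start_points(
    scores: pd.DataFrame, metadata: pd.DataFrame, control: str = "Control"
) -> tuple[np.ndarray, np.ndarray]:
    """Two-centroid initialization: 0 h Control centroid vs all others."""
    meta = metadata.loc[scores.index]
    is_start = (meta["treatment"] == control) & (meta["time_h"] == 0.0)
    if not is_start.any():
        raise ValueError("no 0 h Control samples to anchor the curve start")
    if is_start.all():
        raise ValueError("no non-start samples to orient the curve")
    arr = scores.to_numpy(dtype=float)
    return arr[is_start.to_numpy()].mean(axis=0), arr[~is_start.to_numpy()].mean(axis=0)


def expression_shift(
    curve_lambdas: pd.Series,
    metadata: pd.DataFrame,
    clutch: str,
    treatment: str,
    gene_set_label: str = "",
    control: str = "Control",
    max_lambda: float | None = None,
) -> tuple[pd.Series, float]:
    """Per-time normalized deviation and net shift for one clutch x treatment.

    d_t = |λ_treatment(t) - λ_control(t)| / max(λ); s = Σ_t d_t.  By
    default max(λ) is the maximum over all samples on this curve; when
    a clutch x treatment x time cell holds several samples their λ mean
    is used.
    """
    meta = metadata.loc[curve_lambdas.index]
    if max_lambda is None:
        max_lambda = float(curve_lambdas.max())
    if max_lambda <= 0:
        raise ValueError("max(λ) must be positive")
    times = sorted(meta["time_h"].unique())
    devs = {}
    for t in times:
        sel_t = (meta["clutch"] == clutch) & (meta["time_h"] == t)
        lam_trt = curve_lambdas[sel_t & (meta["treatment"] == treatment)]
        lam_ctl = curve_lambdas[sel_t & (meta["treatment"] == control)]
        if lam_trt.empty or lam_ctl.empty:
            raise ValueError(
                f"missing sample for clutch {clutch!r}, time {t} h "
                f"({treatment!r} and/or {control!r})"
            )
        devs[t] = abs(lam_trt.mean() - lam_ctl.mean()) / max_lambda
    d = pd.Series(devs, name=f"d_{gene_set_label}")
    return d, float(d.sum())


def shift_table(
    lambdas_by_set: dict[str, pd.Series],
    metadata: pd.DataFrame,
    treatments: tuple[str, ...] = ("RA", "DEAB"),
    control: str = "Control",
) -> pd.DataFrame:
    """Net absolute expression shift for every clutch x treatment x gene set."""
    rows = []
    for label, lam in lambdas_by_set.items():
        meta = metadata.loc[lam.index]
        clutches = sorted(meta["clutch"].unique())
        for treatment in treatments:
            for clutch in clutches:
                d, s = expression_shift(
                    lam, metadata, clutch, treatment, label, control
                )
                row = {
                    "clutch": clutch,
                    "treatment": treatment,
                    "gene_set": label,
                    "s": s,
                }
                for t, v in d.items():
                    row[f"d_t{t:g}"] = v
                rows.append(row)
    return pd.DataFrame(rows)


def rank_clutches(
    shifts: pd.DataFrame, gene_set_label: str, treatment: str
) -> list[str]:
    """Clutches ordered most-robust (smallest s) first; ties by clutch id."""
    sub = shifts[
        (shifts["gene_set"] == gene_set_label) & (shifts["treatment"] == treatment)
    ]
    if sub.empty:
        raise ValueError(
            f"no shifts for gene set {gene_set_label!r}, treatment {treatment!r}"
        )
    if sub["clutch"].duplicated().any():
        raise ValueError("duplicate clutch rows in shift table")
    return sub.sort_values(["s", "clutch"], kind="mergesort")["clutch"].tolist()


QUADRANT_LABELS = {
    (False, False): "efficient-effective",
    (True, False): "effective-inefficient",
    (False, True): "ineffective",
    (True, True): "inefficient-ineffective",
}


def efficiency_quadrants(
    shifts: pd.DataFrame,
    outcome_set: str = "hox",
    effort_set: str = "ra_network",
) -> pd.DataFrame:
    """Place clutches in efficiency/efficacy quadrants per treatment.

    x = feedback-effort shift (RA network panel), y = outcome shift
    (hox panel); cutpoints are the across-clutch medians per treatment,
    boundaries inclusive on the low side.  Low outcome = effective
    regulation, low effort = efficient regulation.
    """
    wide = shifts.pivot_table(
        index=["clutch", "treatment"], columns="gene_set", values="s"
    )
    for needed in (outcome_set, effort_set):
        if needed not in wide.columns or wide[needed].isna().any():
            raise ValueError(f"shift table lacks complete {needed!r} scores")
    rows = []
    for treatment, sub in wide.groupby(level="treatment"):
        x = sub[effort_set]
        y = sub[outcome_set]
        if np.ptp(x.to_numpy()) == 0 or np.ptp(y.to_numpy()) == 0:
            warnings.warn(
                f"degenerate shift spread for treatment {treatment!r}; "
                "quadrants default to the boundary-inclusive lower bins",
                stacklevel=2,
            )
        x_med, y_med = float(x.median()), float(y.median())
        for (clutch, _), xi, yi in zip(sub.index, x, y):
            label = QUADRANT_LABELS[(xi > x_med, yi > y_med)]
            rows.append(
                {
                    "clutch": clutch,
                    "treatment": treatment,
                    "effort_shift": xi,
                    "outcome_shift": yi,
                    "quadrant": label,
                }
            )
    return pd.DataFrame(rows)


def analyze_trajectories(
    combined: ExpressionMatrix,
    gene_sets: dict[str, tuple[str, ...]],
    smoother_df: int = 5,
    tol: float = 1e-4,
    max_iter: int = 50,
    treatments: tuple[str, ...] = ("RA", "DEAB"),
) -> dict:
    """Full trajectory stage: PCA, curve, λ and shifts per gene set."""
    scores_by_set: dict[str, pd.DataFrame] = {}
    curves: dict[str, PrincipalCurve] = {}
    lambdas: dict[str, pd.Series] = {}
    for label, genes in gene_sets.items():
        scores = pca_scores(combined, genes)
        start_a, start_b = curve_start_points(scores, combined.samples)
        curve = fit_principal_curve(
            scores.to_numpy(), start_a, start_b, smoother_df, tol, max_iter
        )
        scores_by_set[label] = scores
        curves[label] = curve
        lambdas[label] = pd.Series(curve.lambdas, index=scores.index, name="lambda")
        logger.info(
            "gene set %s: curve SSR %.4f after %d iteration(s), converged=%s",
            label,
            curve.total_ssr,
            curve.iterations,
            curve.converged,
        )
    shifts = shift_table(lambdas, combined.samples, treatments)
    quadrants = efficiency_quadrants(shifts) if len(gene_sets) >= 2 else None
    rankings = {
        (label, trt): rank_clutches(shifts, label, trt)
        for label in gene_sets
        for trt in treatments
    }
    return {
        "scores": scores_by_set,
        "curves": curves,
        "lambdas": lambdas,
        "shifts": shifts,
        "quadrants": quadrants,
        "rankings": rankings,
    }
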
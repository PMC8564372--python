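"""Synthetic multi-clutch RA-perturbation time courses.

The generator emulates the study design it is meant to exercise: twelve
egg clutches (biological replicates, ids ``A``..``L``), three treatments
(``Control``, transient retinoic-acid addition ``RA``, and the RALDH
inhibitor ``DEAB``), and four post-washout time points (0, 1.5, 3,
4.5 h), one pooled sample per clutch x treatment x time — 144 samples.
Half the clutches are labelled as an RNA-seq-like assay and half as a
high-throughput-qPCR-like assay, mirroring the split of the original
cohort.

Each gene belongs to a response class (``null``, ``RA_only_up``,
``RA_only_down``, ``DEAB_only_up``, ``DEAB_only_down``, ``both_same``,
``both_opposite``).  The treatment deflection decays exponentially after
washout with a clutch-specific half-time, emulating the recovery
kinetics in which treatment/control distances shrink over time:

    value(t) = baseline + drift(t) + delta * A(clutch, treatment) * 2^(-t / halftime) + noise

``delta`` is the class/treatment sign (+1, 0 or -1), so the deflection
magnitude at t = 0 equals the planted clutch gain ``A``.  Clutch gains
for RA and DEAB are tied to a per-clutch trade-off coordinate ``u`` so
that, across clutches, robustness to increased RA is anti-correlated
with robustness to decreased RA (a Pareto-like trade-off, "uneven
robustness").

The named feedback (``ra_network``) and outcome (``hox``) panels are
always planted as ``both_opposite`` responders (up under RA, down under
DEAB) riding on a shared developmental ramp, which is what makes the
downstream principal-curve trajectory meaningful.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rarobust.containers import CtTable, ExpressionMatrix
from rarobust.genesets import HOX_GENES, RA_NETWORK_GENES

TREATMENTS = ("Control", "RA", "DEAB")
TIMES_H = (0.0, 1.5, 3.0, 4.5)
HOUSEKEEPING_GENE = "gapdh"

GENE_CLASSES = (
    "null",
    "RA_only_up",
    "RA_only_down",
    "DEAB_only_up",
    "DEAB_only_down",
    "both_same",
    "both_opposite",
)

#: Deflection sign per (class, treatment); ``both_same`` uses the
#: per-gene sign drawn at assignment time, ``both_opposite`` is RA-up.
_CLASS_DELTA = {
    "null": {"RA": 0, "DEAB": 0},
    "RA_only_up": {"RA": +1, "DEAB": 0},
    "RA_only_down": {"RA": -1, "DEAB": 0},
    "DEAB_only_up": {"RA": 0, "DEAB": +1},
    "DEAB_only_down": {"RA": 0, "DEAB": -1},
    "both_same": {"RA": +1, "DEAB": +1},
    "both_opposite": {"RA": +1, "DEAB": -1},
}

DEFAULT_PROPORTIONS = {
    "null": 0.55,
    "RA_only_up": 0.08,
    "RA_only_down": 0.07,
    "DEAB_only_up": 0.08,
    "DEAB_only_down": 0.07,
    "both_same": 0.08,
    "both_opposite": 0.07,
}


def class_delta(gene_class: str, treatment: str, sign: int = +1) -> int:
    """Deflection sign of a gene class under a treatment.

    ``sign`` flips the shared direction of ``both_same`` genes (and the
    orientation of ``both_opposite`` genes, which remain opposed).
    """
    if gene_class not in _CLASS_DELTA:
        raise ValueError(f"unknown gene class {gene_class!r}")
    if treatment == "Control":
        return 0
    if treatment not in ("RA", "DEAB"):
        raise ValueError(f"unknown treatment {treatment!r}")
    return _CLASS_DELTA[gene_class][treatment] * sign


@dataclass
class ClutchParams:
    """Per-clutch generative parameters."""

    clutch: str
    tradeoff_u: float
    gain_ra: float
    gain_deab: float
    recovery_halftime_h: float

    def gain(self, treatment: str) -> float:
        if treatment == "Control":
            return 0.0
        return self.gain_ra if treatment == "RA" else self.gain_deab


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study grid: 12 clutches x 3 treatments x 4
    time points = 144 samples, split evenly between an RNA-seq-like and
    a qPCR-like assay.  Amplitudes and noise are in log2 units.
    """

    n_clutches: int = 12
    treatments: tuple[str, ...] = TREATMENTS
    times_h: tuple[float, ...] = TIMES_H
    n_genes: int = 2000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    gain_scale: float = 2.0
    tradeoff_u: tuple[float, ...] | None = None  # default: evenly spans [0, 1]
    recovery_halftime_h: float | tuple[float, ...] = 1.5
    noise_sd: float = 0.3
    drift_amplitude: float = 1.0
    panel_ramp: float = 2.5  # developmental log2 ramp of panel genes over the course
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 2.0
    ct_intercept: float = 24.0
    ct_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clutches < 2:
            raise ValueError("need at least 2 clutches")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        times = tuple(float(t) for t in self.times_h)
        if times != tuple(sorted(times)) or times[0] != 0.0:
            raise ValueError("times_h must be sorted ascending and start at 0")
        self.times_h = times
        if self.n_genes < len(GENE_CLASSES):
            raise ValueError("n_genes smaller than the number of gene classes")

    @property
    def clutch_ids(self) -> list[str]:
        letters = string.ascii_uppercase
        if self.n_clutches <= len(letters):
            return list(letters[: self.n_clutches])
        return [f"C{i:02d}" for i in range(self.n_clutches)]

    def clutch_assays(self) -> dict[str, str]:
        """Assay label per clutch: first half rnaseq-like, rest qPCR-like."""
        ids = self.clutch_ids
        half = (len(ids) + 1) // 2
        return {c: ("rnaseq" if i < half else "htqpcr") for i, c in enumerate(ids)}

    def clutch_params(self) -> list[ClutchParams]:
        ids = self.clutch_ids
        if self.tradeoff_u is None:
            u = np.linspace(0.0, 1.0, len(ids))
        else:
            u = np.asarray(self.tradeoff_u, dtype=float)
            if u.shape != (len(ids),):
                raise ValueError("tradeoff_u must have one entry per clutch")
            if ((u < 0) | (u > 1)).any():
                raise ValueError("tradeoff_u entries must lie in [0, 1]")
        if np.isscalar(self.recovery_halftime_h):
            halftimes = np.full(len(ids), float(self.recovery_halftime_h))
        else:
            halftimes = np.asarray(self.recovery_halftime_h, dtype=float)
            if halftimes.shape != (len(ids),):
                raise ValueError("recovery_halftime_h must be scalar or per-clutch")
        if (halftimes <= 0).any():
            raise ValueError("recovery half-times must be positive")
        params = []
        for cid, ui, ht in zip(ids, u, halftimes):
            # complementary gains: a clutch strong against RA excess is
            # weak against RA depletion, and vice versa
            gain_ra = self.gain_scale * (0.6 + 0.8 * ui)
            gain_deab = self.gain_scale * (0.6 + 0.8 * (1.0 - ui))
            params.append(ClutchParams(cid, float(ui), gain_ra, gain_deab, float(ht)))
        return params


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset.

    ``genes`` carries the response class and, for the RNA-seq-half clutch
    average, the noise-free ternary patterns (fold threshold 1.3) of the
    RA-vs-Control and DEAB-vs-Control comparisons.  ``clutches`` carries
    the planted gains, half-times, integrated deviations and robustness
    ranks (rank 1 = most robust = smallest integrated deviation).
    """

    genes: pd.DataFrame  # index gene_id; class, sign, patterns, indices
    clutches: pd.DataFrame  # index clutch; gains, halftime, ranks

    def rank_order(self, treatment: str) -> list[str]:
        """Clutch ids sorted most-robust first for a treatment."""
        col = f"rank_{treatment.lower()}"
        return self.clutches.sort_values(col).index.tolist()


def simulate_expression_profile(
    gene_class: str,
    clutch_params: ClutchParams,
    treatment: str,
    times,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    baseline: float = 0.0,
    drift_slope: float = 0.0,
    sign: int = +1,
) -> np.ndarray:
    """One gene's log2 profile for a clutch x treatment across time.

    The treatment deflection starts at the planted clutch gain and
    relaxes exponentially with the clutch's recovery half-time; drift is
    a treatment-independent linear trend over the course.
    """
    times = np.asarray(times, dtype=float)
    if clutch_params.recovery_halftime_h <= 0:
        raise ValueError("recovery half-time must be positive")
    delta = class_delta(gene_class, treatment, sign)
    t_max = times.max() if times.max() > 0 else 1.0
    decay = 2.0 ** (-times / clutch_params.recovery_halftime_h)
    values = (
        baseline
        + drift_slope * times / t_max
        + delta * clutch_params.gain(treatment) * decay
    )
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=times.shape)
    return values


def _gene_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign ids, classes, signs, baselines and drift slopes to genes."""
    panel = list(RA_NETWORK_GENES) + list(HOX_GENES) + [HOUSEKEEPING_GENE]
    n_generic = config.n_genes - len(panel)
    if n_generic < len(GENE_CLASSES):
        raise ValueError(
            f"n_genes={config.n_genes} leaves fewer generic genes than classes "
            f"after the {len(panel)}-gene named panel"
        )
    # largest-remainder apportionment keeps class counts exact
    classes = [c for c in GENE_CLASSES if config.class_proportions.get(c, 0) > 0]
    quotas = np.array([config.class_proportions[c] * n_generic for c in classes])
    counts = np.floor(quotas).astype(int)
    for i in np.argsort(-(quotas - counts))[: n_generic - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    gene_ids = panel + [f"g{i:05d}" for i in range(n_generic)]
    gene_class = [
        *["both_opposite"] * (len(RA_NETWORK_GENES) + len(HOX_GENES)),
        "null",  # housekeeping
        *labels,
    ]
    # log-normal expression: normal baselines on the log2 scale, so the
    # low tail has support and strong down-deflections stay in-range
    baselines = rng.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=len(gene_ids)
    )
    # the named panel emulates genes the study quantified by qPCR under
    # every condition: solidly expressed, so a full down-deflection
    # leaves them well above the detection floor
    n_panel = len(panel)
    baselines[:n_panel] = rng.normal(
        config.baseline_log2_mean + 1.5, 1.0, size=n_panel
    )
    baselines[panel.index(HOUSEKEEPING_GENE)] = 10.0
    signs = np.where(rng.random(len(gene_ids)) < 0.5, -1, 1)
    signs[: len(panel)] = 1  # panel orientation fixed: RA up, DEAB down
    drift = rng.uniform(-config.drift_amplitude, config.drift_amplitude, len(gene_ids))
    drift[: len(RA_NETWORK_GENES) + len(HOX_GENES)] = config.panel_ramp
    drift[panel.index(HOUSEKEEPING_GENE)] = 0.0
    return pd.DataFrame(
        {
            "gene_class": gene_class,
            "sign": signs,
            "baseline": baselines,
            "drift_slope": drift,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _sample_id(clutch: str, treatment: str, time_h: float) -> str:
    return f"{clutch}_{treatment}_{time_h:g}h"


def _truth_patterns(
    genes: pd.DataFrame,
    params: list[ClutchParams],
    assays: dict[str, str],
    times: tuple[float, ...],
    fold_threshold: float = 1.3,
) -> pd.DataFrame:
    """Noise-free ternary vs-Control patterns for the RNA-seq clutch half."""
    from rarobust.patterns import encode_pattern, pattern_string

    rnaseq = [p for p in params if assays[p.clutch] == "rnaseq"]
    t = np.asarray(times)
    tau = math.log2(fold_threshold)
    out = {}
    for treatment in ("RA", "DEAB"):
        # clutch-averaged deflection amplitude at each time point
        amp = np.mean(
            [p.gain(treatment) * 2.0 ** (-t / p.recovery_halftime_h) for p in rnaseq],
            axis=0,
        )
        deltas = np.array(
            [
                class_delta(cls, treatment, sgn)
                for cls, sgn in zip(genes["gene_class"], genes["sign"])
            ]
        )
        diff = deltas[:, None] * amp[None, :]
        tern = np.where(diff >= tau, 1, np.where(diff <= -tau, -1, 0))
        out[f"pattern_{treatment.lower()}"] = [pattern_string(v) for v in tern]
        out[f"index_{treatment.lower()}"] = [encode_pattern(v) for v in tern]
    return genes.assign(**out)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CtTable, PlantedTruth]:
    """Draw one full synthetic study.

    Returns the log2 gene x sample matrix (all clutches, both assay
    labels), the qPCR Ct table for the qPCR-half clutches, and the
    planted ground truth.  Identical config (including seed) gives
    bit-identical output.
    """
    root = np.random.SeedSequence(config.seed)
    ss_genes, ss_noise, ss_ct = root.spawn(3)
    genes = _gene_table(config, np.random.default_rng(ss_genes))
    params = config.clutch_params()
    assays = config.clutch_assays()
    times = np.asarray(config.times_h)
    noise_rng = np.random.default_rng(ss_noise)

    columns, meta_rows = [], []
    values = np.empty((len(genes), config.n_clutches * len(config.treatments) * len(times)))
    t_max = times.max()
    decay_cache = {}
    col = 0
    deltas = {
        trt: np.array(
            [
                class_delta(cls, trt, sgn)
                for cls, sgn in zip(genes["gene_class"], genes["sign"])
            ]
        )
        for trt in config.treatments
    }
    base = genes["baseline"].to_numpy()
    drift = genes["drift_slope"].to_numpy()
    hk_pos = genes.index.get_loc(HOUSEKEEPING_GENE)
    for p in params:
        decay = 2.0 ** (-times / p.recovery_halftime_h)
        decay_cache[p.clutch] = decay
        for treatment in config.treatments:
            for j, t in enumerate(times):
                profile = (
                    base
                    + drift * t / t_max
                    + deltas[treatment] * p.gain(treatment) * decay[j]
                )
                if config.noise_sd > 0:
                    eps = noise_rng.normal(0.0, config.noise_sd, size=len(genes))
                    # the housekeeping reference is an idealized stable
                    # gene: constant level, no biological noise
                    eps[hk_pos] = 0.0
                    profile = profile + eps
                values[:, col] = profile
                columns.append(_sample_id(p.clutch, treatment, t))
                meta_rows.append(
                    {
                        "sample_id": _sample_id(p.clutch, treatment, t),
                        "clutch": p.clutch,
                        "treatment": treatment,
                        "time_h": float(t),
                        "assay": assays[p.clutch],
                    }
                )
                col += 1

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes.index, columns=columns),
        pd.DataFrame(meta_rows).set_index("sample_id"),
        scale="log2",
    )

    # clutch truth: integrated deviation drives the planted robustness rank
    rows = []
    for p in params:
        d_ra = float(p.gain_ra * decay_cache[p.clutch].sum())
        d_deab = float(p.gain_deab * decay_cache[p.clutch].sum())
        rows.append(
            {
                "clutch": p.clutch,
                "assay": assays[p.clutch],
                "tradeoff_u": p.tradeoff_u,
                "gain_ra": p.gain_ra,
                "gain_deab": p.gain_deab,
                "recovery_halftime_h": p.recovery_halftime_h,
                "deviation_ra": d_ra,
                "deviation_deab": d_deab,
            }
        )
    clutches = pd.DataFrame(rows).set_index("clutch")
    for trt in ("ra", "deab"):
        order = clutches.sort_values(
            [f"deviation_{trt}"], kind="mergesort"
        ).index  # stable: ties fall back to clutch-id order
        clutches[f"rank_{trt}"] = pd.Series(
            np.arange(1, len(order) + 1), index=order
        )
    truth = PlantedTruth(
        genes=_truth_patterns(genes, params, assays, config.times_h),
        clutches=clutches,
    )
    ct = simulate_ct_table(config, matrix, rng=np.random.default_rng(ss_ct))
    return matrix, ct, truth


def simulate_ct_table(
    config: SimulationConfig,
    expression: ExpressionMatrix,
    rng: np.random.Generator | None = None,
) -> CtTable:
    """Emulate the Fluidigm-style qPCR readout of the qPCR-half clutches.

    Ct = intercept - log2 expression, plus a pre-amplification-group
    offset and technical-replicate jitter; three groups (L-homeolog,
    S-homeolog, both) x three technical replicates per gene x sample.
    The housekeeping gene is simulated treatment-independent.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    panel = list(RA_NETWORK_GENES) + list(HOX_GENES) + [HOUSEKEEPING_GENE]
    missing = [g for g in panel if g not in expression.values.index]
    if HOUSEKEEPING_GENE in missing:
        raise ValueError(f"housekeeping gene {HOUSEKEEPING_GENE!r} missing")
    if missing:
        raise ValueError(f"qPCR panel genes missing from expression: {missing}")
    qpcr_samples = expression.samples.index[expression.samples["assay"] == "htqpcr"]
    expr = expression.values.loc[panel, qpcr_samples]

    records = []
    jitter = config.ct_jitter_sd
    for sample_id in qpcr_samples:
        for gene in panel:
            true_ct = config.ct_intercept - expr.at[gene, sample_id]
            for group in (1, 2, 3):
                group_offset = rng.normal(0.0, jitter) if jitter > 0 else 0.0
                for rep in (1, 2, 3):
                    eps = rng.normal(0.0, jitter) if jitter > 0 else 0.0
                    records.append(
                        (gene, sample_id, group, rep, true_ct + group_offset + eps)
                    )
    frame = pd.DataFrame(
        records, columns=["gene_id", "sample_id", "preamp_group", "tech_replicate", "ct"]
    )
    return CtTable(
        records=frame,
        samples=expression.samples.loc[qpcr_samples].copy(),
        housekeeping=HOUSEKEEPING_GENE,
    )
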
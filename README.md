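# rarobust

Analysis toolkit for quantifying the robustness of retinoic-acid (RA)
signaling in early embryos from treatment/control time-series
transcriptomics.

## The scientific problem

RA is a vitamin-A-derived morphogen whose level must be held in a tight
range during gastrulation; both excess and deficit are teratogenic.
Embryos counteract transient RA perturbations through a transcriptional
feedback network (synthesis, degradation, binding and transport genes).
The experimental design this package analyzes perturbs RA up (RA
addition) or down (the RALDH inhibitor DEAB) for a pulse, washes out,
and samples each egg clutch (one female's batch = one biological
replicate) at t = 0, 1.5, 3 and 4.5 h of recovery, across 12 clutches x
3 treatments x 4 time points = 144 samples split between an RNA-seq and
a high-throughput qPCR assay.

Three analyses are implemented:

1. **Dynamic pattern analysis.** Clutch-averaged differential profiles
   are discretized per time point to +1 / 0 / −1 (up / no change /
   down) against a fold-change threshold, giving each gene one of 3^T
   ordered patterns (27 for the t0-referenced analysis, 81 for the
   control-referenced one).
2. **COMPACT** (comparative matrix of pattern counts). The 81-pattern
   vectors for DEAB-vs-control (rows) and RA-vs-control (columns) are
   cross-tabulated into an 81 x 81 count matrix; coarse-graining by
   response onset (time and direction of the first non-zero call)
   yields a 9 x 9 summary. Quadrants classify genes as responding to
   both perturbations in the same direction (a, d), in opposite
   directions (b, c), to one only, or not at all.
3. **Principal-curve robustness score.** For a gene panel (6 *hox*
   targets = outcome; 16 RA-network genes = feedback effort), all 144
   Z-scored samples are projected on 3 principal components and a
   principal curve is fitted, starting from the centroid of the 0 h
   control samples. With λ the arc distance of a sample's projection
   from the curve start, the *net absolute expression shift* of clutch
   *cl* under treatment *T* is

   ```
   s(cl, T) = Σ_t | λ_T(cl, t) − λ_Control(cl, t) | / max(λ)
   ```

   A smaller s means the clutch returns to the unperturbed trajectory
   faster — it is more robust. Clutches are ranked by s and placed in
   efficiency/efficacy quadrants (hox shift vs network shift).

A synthetic-data generator reproduces the full study design — planted
gene response classes, clutch-specific feedback gains with a Pareto
trade-off (clutches robust to RA excess are fragile to RA depletion,
and vice versa), exponential post-washout recovery, and a qPCR Ct table
with pre-amplification groups — so every stage is testable end to end
with known ground truth.

## Worked example

```sh
rarobust all --seed 1 --outdir run
```

runs simulate → preprocess → patterns → COMPACT → trajectory and prints

```
pipeline done: 144 combined samples, COMPACT 81x81 -> run
```

The same from Python, with the numbers it produces:

```python
from rarobust import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(outdir="run", seed=1))
summary["n_samples_combined"]      # 144  (12 clutches x 3 treatments x 4 times)
summary["compact"]["fine_shape"]   # [81, 81]
summary["compact"]["n_cells_occupied"]  # 199 of 6561 pattern pairs hold genes
summary["category_counts"]
# {'non-responsive': 459, 'DEAB-only': 443, 'RA-only': 283,
#  'quadrant-d': 213, 'quadrant-a': 180, 'quadrant-b': 132, 'quadrant-c': 122}
summary["rankings"]["hox_RA"]
# ['C', 'A', 'D', 'B', 'E', 'F', 'I', 'G', 'H', 'K', 'L', 'J']
summary["rankings"]["hox_DEAB"]
# ['L', 'J', 'K', 'H', 'I', 'E', 'G', 'F', 'C', 'D', 'B', 'A']
```

Most genes respond to only one direction of RA perturbation
(DEAB-only + RA-only outnumber the shared quadrants), the minority of
opposite responders (quadrant b: up under RA, down under DEAB) is where
the planted RA-feedback genes live, and the two hox rankings run in
nearly opposite order — the robustness trade-off across clutches. The
run directory holds every intermediate table (TSV/CSV) plus
`summary.json`; two runs with the same config and seed are
byte-identical.

`clutch C` heads the RA ranking and sits at the tail of the DEAB
ranking: it buffers RA excess efficiently but compensates RA depletion
poorly.

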
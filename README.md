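# palm-mcquant

Quantitative analysis of photoactivation localization microscopy (PALM)
images of T-cell signaling microclusters (MCs) — the sub-micron assemblies of
ZAP70, SLP76 and LAT that form at the plasma membrane after T-cell receptor
triggering. The package implements the full measurement chain on synthetic
data with known ground truth, for microscopists and image analysts who want
each stage as a tested, reusable library function:

1. **Photophysics** — forward models and least-squares fitting for the
   photoswitching kinetics of GFP (`F → B`, rate *k_b*), tdEos
   (`G →(k_ps) R →(k_b) B`) and Dronpa (`I ⇌(k_pa, k_pda) A →(k_b) B`),
   with nested-model F-tests and rate-vs-illumination-intensity regression
   (a non-zero intercept flags spontaneous switching).
2. **Localization** — background subtraction (frame mean + opening-based
   estimate), three-threshold particle detection (T1; ≥ min pixels above
   T2 = 0.7·T1; ≤ max pixels above T3 = T1), shot-noise-weighted 2D Gaussian
   fitting, Thompson localization uncertainty, and rendering as unit-integral
   Gaussian spots truncated at 5×5 PALM pixels on an exactly-zero background.
3. **Colocalization** — Mander's coefficients per MC pair,
   `M1 = Σ R_i,coloc / Σ R_i` (and symmetrically M2), with the four
   association categories: isolated (M1 = 0 or M2 = 0), overlapping
   (max > 0.66), edge-connected (max < 0.33), partial (the rest); plus the
   relative phosphotyrosine enrichment ratio.
4. **Spatial statistics** — Ripley's
   `K̂(r) = (A/n²) Σ_{i≠j} k(i,j)/w_ij` with analytic Haase edge weights,
   the `L(r) − r = √(K̂/π) − r` transform, Monte-Carlo CSR calibration with
   `CI₉₉ = 1.68·√A/n` normalization to ±1, cluster-domain radius `r_max`,
   and cluster segmentation by area thresholding.
5. **Morphology** — Benkrid chain-code perimeter (straight link 1, diagonal
   √2), circularity `C = 4πa/p²` with classes C ≥ 0.66 / ≥ 0.33 / < 0.33,
   normalized radial distance r̃ (periphery band 0.7–1.0) and radial profiles
   of circularity and actin-type intensity (bin width 0.25).

The `synth` module generates every input class with ground truth: ensemble
decay traces, sparse-blinking emitter stacks (Poisson noise, even/uneven
background), CSR and disk-cluster point patterns, dual-color cluster scenes
with commanded center offsets, and analytic binary shapes.

## Worked example

```python
import numpy as np
from palm_mcquant import synth, photophysics as pp, spatial as sp

# recover tdEos rates from a noisy ensemble bleaching trace
cfg = synth.DecaySimConfig("tdeos", rates={"k_ps": 0.05, "k_b": 0.15}, seed=0)
fit = pp.fit_decay(synth.simulate_decay(cfg), "tdeos",
                   fixed_fractions={"g0": 0.5, "r0": 0.5})
print(round(fit.params["k_ps"], 4), round(fit.params["k_b"], 4))
# 0.0505 0.1495   (truth: 0.05, 0.15)

# cluster-domain radius of a disk-cluster point pattern
pat = synth.simulate_pattern(synth.PatternSimConfig(
    window=(0, 0, 10000, 10000), mode="disk-clusters",
    n_clusters=20, cluster_radius_nm=200, points_per_cluster=50, seed=0))
r = np.arange(0.0, 1210.0, 10.0)
lmr = sp.l_transform(sp.ripley_k(pat, r), r)
print(sp.extract_rmax(lmr, r))
# 340.0   (nm; the L(r) − r maximum for 200 nm disks)
```

The numbers are what the code prints for these seeds: the fitted rates land
within a few percent of the generating values, and `r_max` sits between one
and two true cluster radii, as expected for uniform-disk clusters (it is a
domain-scale summary, not an unbiased radius estimator).

## Analysis scripts

Numbered drivers under `analysis/` rerun the whole study on synthetic data
and write tables to `results/`:

| script | what it measures |
| --- | --- |
| `01_photophysics_rates.py` | rate fits per laser intensity, F-tests, rate-vs-intensity regression |
| `02_localization_recall.py` | event recall within 50 nm, localization error, false positives |
| `03_colocalization.py` | Mander's pairs/categories vs commanded offsets, pY ratio |
| `04_ripley_clustering.py` | CSR band calibration, r_max vs true cluster radius |
| `05_morphology_profiles.py` | circularity classes, radial circularity and actin profiles |

A one-command synthetic demo of the full pipeline:
`palm-mcquant run --out demo_out` (see `palm-mcquant --help` for per-stage
subcommands).

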
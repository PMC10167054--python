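# corticoflow

Corticomuscular coupling analysis for simultaneously recorded surface
EMG and fNIRS during isometric elbow contraction — for motor-control and
rehabilitation researchers who want the full chain from raw signals to
group statistics as tested, scriptable code, together with a synthetic
cohort generator that makes every stage verifiable without any
experimental data.

The pipeline quantifies, per subject and condition (20% / 80% of maximum
voluntary contraction, dominant / non-dominant arm):

- **EMG complexity** of biceps (BIC) and triceps (TRI) by **fuzzy
  approximate entropy**. For a window of N samples, baseline-removed
  embedding vectors `S_i^m = [e(i) … e(i+m−1)] − ē_i` are compared by
  Chebyshev distance `d_ij`, similarity is the fuzzy kernel
  `D_ij = exp(−d_ij^n / r)`, and

  `fApEn(m, r, n, N) = φ^m(r) − φ^{m+1}(r)`,

  where `φ^m` averages the log mean similarity over vectors (self-matches
  excluded). Defaults m = 2, n = 2, r = 0.15, N = 5000, applied to
  unit-variance standardized 5-s steady task segments at 1 kHz.
- **Co-contraction** by Winter's index on MVC-normalized linear
  envelopes: `%CCI = 2·common_area / (area_A + area_B) × 100`
  (trapezoidal areas; 0 = disjoint envelopes, 100 = identical).
- **Cortical hemodynamics** from 30-channel, dual-wavelength
  (730/850 nm, 30-mm separation) optical densities over six regions
  (LPFC, RPFC, LMC, RMC, LOL, ROL): modified Beer–Lambert conversion to
  ΔHbO2/ΔHbR, channel quality control, motion-artifact suppression,
  0.01–0.2 Hz band-pass, GLM task betas and baseline-corrected HbO2
  task-block integrals.
- **Brain networks**: Pearson functional connectivity (channel and
  region scope), directed effective connectivity by pairwise Granger
  causality, Onnela weighted clustering, node-local and global
  efficiency.
- **Group statistics**: paired t-tests across force levels, one-way
  ANOVA, cross-modal Pearson correlations (fApEn vs. regional HbO2 and
  network metrics), Benjamini–Hochberg FDR per declared family.

The synthetic generator programs ground-truth effects — motor-unit
recruitment growing with force, antagonist co-activation, region gains,
latent coupling, directed edges, and a shared per-subject drive that
couples muscle and cortex — so every direction the statistics report is
known by construction.

## Worked example

```python
from corticoflow.synthetic import Cohort
from corticoflow.pipeline import analyze_cohort
from corticoflow.stats import paired_compare, cross_modal_correlation

cohort = Cohort(n_subjects=6, seed=7)          # 6 subjects x 4 conditions
result = analyze_cohort(cohort)                # ~40 s on one CPU

t = paired_compare(result.features, "fapen_bic")
print(t[["side", "n_pairs", "mean_diff", "t", "p", "q"]].round(4))

c = cross_modal_correlation(result.features,
                            y_cols=["integral_LMC", "integral_RMC"])
print(c[["side", "y", "n", "r", "p", "q"]].round(4))
```

prints

```
        side  n_pairs  mean_diff       t   p   q
    dominant        6     0.3393 65.2259 0.0 0.0
non-dominant        6     0.3421 93.0153 0.0 0.0

        side            y  n      r      p      q
    dominant integral_LMC 12 0.8048 0.0016 0.0064
    dominant integral_RMC 12 0.6874 0.0135 0.0200
non-dominant integral_LMC 12 0.6550 0.0208 0.0208
non-dominant integral_RMC 12 0.6799 0.0150 0.0200
```

The first table says biceps fApEn is higher at 80% than at 20% MVC on
both sides (mean paired difference ≈ 0.34, p ≪ 0.001): stronger
contractions recruit more motor units and produce a more complex
interference signal. The second table shows the programmed cross-modal
coupling: subjects with more excitable motor drive show both higher EMG
complexity and larger contralateral motor-cortex HbO2 integrals
(r ≈ 0.65–0.80, FDR-significant), with the strongest association in the
hemisphere contralateral to the moving arm. The same run reports the
co-contraction index rising by ≈ 14.6 points from 20% to 80% MVC.

A full file-based run (cohort on disk, per-stage TSV outputs, figures,
`run.json` provenance) is:

```
corticoflow run --subjects 21 --seed 7 --out runs/demo
corticoflow validate runs/demo
```

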
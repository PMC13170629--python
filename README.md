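# axonet

Tools for relating a serum marker of axonal injury — neurofilament light
(NF-L) — to white-matter (WM) volume and tractography-derived structural
connectivity, in the study design typical of acute anorexia nervosa (AN)
research: an acutely underweight group and matched healthy controls (HC),
blood biomarkers (NF-L, leptin with left-censoring at the assay detection
limit), FreeSurfer-style ROI volume tables, and per-participant FA/NOS
connectivity matrices.

The package is aimed at researchers who want to run — or stress-test —
this analysis chain without patient data: every stage can be driven by a
seeded synthetic cohort whose effects (biomarker distributions, a negative
NF-L→volume slope, NF-L-associated connectome components, and a
leptin→connectivity→NF-L mediation chain) are planted with known values,
so recovery, error control and specificity are all measurable.

## What it computes

- **Network-based statistic (NBS).** For edge weight $y_e$, participant
  covariates $Z$ and predictor $x$ (log NF-L), fit per edge
  $y_e = \beta_0 + \beta_1 x + Z\gamma + \varepsilon$; keep edges with
  $t_{\beta_1}$ above a primary threshold (default $t = 3.2$, the
  one-sided $p \approx .001$ point at $n = 77$); extract connected
  components; control family-wise error by permuting $x$ (default 10,000
  permutations) and referring each component's edge count to the null
  distribution of the largest component, with the add-one p-value
  $p = (1 + \#\{S^{\text{null}} \ge S\})/(1 + n_{\text{perm}})$.
  A threshold sweep probes robustness across primary thresholds.
- **Deterministic FACT tractography on phantoms.** Voxel-to-voxel
  propagation along per-voxel principal eigenvectors, 8 seeds per voxel,
  stopping at FA < 0.1, turns > 45°, or mask exit; FA/NOS connectome
  construction from streamlines (pass-through edge rule, traversal-weighted
  FA means) and group-mask QC.
- **ROI volume models.** Per-ROI OLS of volume on log NF-L + age + eTIV
  within a group, standardized betas, Benjamini–Hochberg FDR over the 73
  WM ROIs; Wilcoxon/Welch group comparisons with effect sizes
  $r = |z|/\sqrt{n}$; partial correlations.
- **Component-level clinical models.** Mean component connectivity per
  participant; Huber M-estimated robust regressions (tuning 1.345, MAD
  scale) with Wald tests and FDR across components; sub-LOD leptin
  imputation; outlier exclusion at 3 group SDs.
- **Bootstrap mediation.** Standardized decomposition of the leptin→NF-L
  association into a direct path $c'$ and an indirect path $a \cdot b$
  through mean connectivity, with case-resampling percentile CIs;
  total $= c' + ab$ by construction.

## Worked example

```python
import numpy as np
from axonet import (CohortConfig, generate_cohort, generate_connectomes,
                    NBS, Mediation, mean_component_connectivity)

cohort = generate_cohort(CohortConfig(seed=42))          # 77 AN + 77 HC
planted = [(0, 1), (1, 2), (1, 3), (3, 4), (4, 5)]
conns = generate_connectomes(cohort, n_nodes=30,
                             planted_components=[planted],
                             mediation_components=[planted],
                             edge_effect=0.0205, seed=43)

an = cohort[cohort["group"] == "AN"].set_index("id")
mats = {p: conns[p]["FA"] for p in an.index}
model = NBS(mats, an["log_nfl"], an[["age", "motion"]])
res = model.fit(threshold=3.2, n_perm=1000, seed=44)
print(res.summary())

comp = res.significant[0]
mc = np.array([mean_component_connectivity(mats[p], comp)
               for p in an.index])
med = Mediation(np.log(an["leptin"]), mc, an["log_nfl"]).fit(n_boot=5000,
                                                             seed=45)
print(med.summary().round(3))
```

Output:

```
   component  n_edges  n_nodes     fwe_p
0          1        5        6  0.000999
          estimate      z      p  ci_lower  ci_upper
effect
direct      -0.252 -2.148  0.032    -0.480    -0.024
indirect    -0.410    NaN  0.000    -0.582    -0.251
total       -0.662 -6.398  0.000    -0.856    -0.450
```

The planted 5-edge component is recovered at the smallest achievable
permutation p-value (1/1001 with 1,000 permutations). The mediation
table decomposes the standardized leptin→log NF-L association: lower
leptin predicts higher NF-L both directly and through the component's
mean FA (all effects negative; the total, −0.662, sits near the
generator's planted standardized total of −0.675, and equals
direct + indirect exactly).

A command-line driver chains all stages
(`axonet simulate | qc | nbs | volumes | clinical | mediate | all`);
every report declares the decided defaults (imputation method, robust
estimator, FDR method, QC thresholds) in `run_manifest.json`.

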
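# ccdnet

Graph-theoretic analysis of structural brain connectomes in mouse corpus
callosum dysgenesis (CCD).

Corpus callosum dysgenesis is a developmental malformation in which the main
interhemispheric fiber tract is absent (complete CCD) or reduced (partial
CCD). Diffusion-MRI connectome studies of CCD mouse models compare
whole-brain weighted networks across four conditions — normal corpus
callosum, complete CCD, partial CCD, and an in-silico *virtual callosotomy*
control (a normal network with callosal edges deleted but no compensatory
rewiring) — to separate the consequences of losing callosal connections from
active reorganization such as intrahemispheric Probst bundles and the
asymmetric heterotopic *sigmoid bundle* through the callosal remnant.

`ccdnet` implements that analysis pipeline as a tested, reusable library:

- **Synthetic cohort generator** — a 76-region bilateral parcellation
  (38 areas per hemisphere) and condition-specific template networks from
  which individual weighted connectomes (FA-like edge weights in (0, 1))
  are sampled with controlled presence and weight noise, including the
  half-penetrance sigmoid edge of partial CCD.
- **Connectome construction** — two-step connection-retention on per-seed
  voxel connectivity maps, mean-FA edge weighting, virtual callosotomy,
  consensus connectomes (edges present in at least half the subjects),
  inter/intrahemispheric edge classification.
- **Graph metrics** — proportional sparsity thresholding (0.05–0.13 in
  steps of 0.01), weighted strength, betweenness (% of shortest paths),
  Onnela clustering, harmonic global/local efficiency, density; AUC of
  each metric across the threshold range; group comparison of AUCs with
  normality-gated t / Mann-Whitney tests and Holm-Sidak correction.
- **Community & hubs** — Louvain modularity with resolution γ = 1.2,
  consensus partitions, Guimerà–Amaral participation coefficients,
  connector/provincial hub classification, degree–participation
  correlation.
- **Network-based statistic (NBS)** — edge-wise one-sided two-sample t
  statistics, suprathreshold connected components, permutation null of
  the maximal component extent, FWER-corrected p-values, and the t* = 2…5
  threshold sweep with per-edge significance counts.
- **Variability & novelty** — per-edge coefficient of variation, pairwise
  network similarity (mean edge-wise correlation per subject, split by
  whole/inter/intrahemispheric edge class), and the novel-connection rule
  (present in ≥ 2 case subjects, absent from every control).

## Core statistics

For a weighted network `W` thresholded to sparsity `s` (top
`k = round(s·n(n−1)/2)` edges), each measure `M(s)` is summarized as
`AUC = ∫ M(s) ds` over the grid (trapezoidal rule). Modularity is
`Q = (1/2m) Σ_ij [w_ij − γ k_i k_j / 2m] δ(c_i, c_j)`, participation is
`P_v = 1 − Σ_m (s_vm / s_v)²`, and NBS component significance is
`p = (1 + #{null max size ≥ observed}) / (n_perm + 1)` under subject
relabeling.

## Worked example

```python
from ccdnet import (CohortConfig, generate_cohort, metric_auc,
                    threshold_sweep, discover_novel_edges)

cohorts = {c: generate_cohort(c, CohortConfig(condition=c, rng_seed=0))
           for c in ("normal_cc", "complete_ccd", "partial_ccd",
                     "virtual_callosotomy")}

for cond, cohort in cohorts.items():
    print(cond, metric_auc(cohort, "global_efficiency").mean())

sweep = threshold_sweep(cohorts["complete_ccd"],
                        cohorts["virtual_callosotomy"],
                        thresholds=(2, 3, 4, 5), n_perm=1000, seed=0)
report = discover_novel_edges(cohorts["partial_ccd"], cohorts["normal_cc"])
```

With the default study conditions (10 subjects per condition, seed 0) this
prints mean AUC global efficiency `0.0146` for normal controls against
`0.0133` (complete CCD), `0.0138` (partial CCD) and `0.0131` (virtual
callosotomy) — integration is lost with the callosum — while mean AUC
clustering rises from `0.0131` (normal) to `0.0148` (complete CCD): the
dysgenic network trades long-range integration for local segregation. The
NBS sweep finds FWER-significant intrahemispheric components anchored on
the frontal association cortex in complete CCD versus virtual callosotomy
(e.g. two components of 4 edges at t* = 3, p = 0.005), i.e. the Probst-bundle
rerouting, and the novelty report flags the planted sigmoid edge
`Fra,L–Hp,R` present in 3/10 partial-CCD subjects and no control.

The same stages are scriptable from the shell:

```bash
ccdnet simulate --condition partial_ccd --n 10 --seed 7 --out cohorts/partial
ccdnet metrics --cohort cohorts/partial --out auc.tsv
ccdnet run-all --out results/ --seed 7
```

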
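# Methods

## The model system

The package analyzes weighted structural connectomes over a bilateral
76-region adult mouse brain parcellation (38 areas per hemisphere, from the
subiculum to the cerebellum, mirrored left/right). A connectome is a
symmetric 76×76 matrix with zero diagonal; weights are FA-like tract
strengths in (0, 1) and an exact zero means "no connection". Four
conditions are compared: normal corpus callosum, complete callosal
dysgenesis, partial dysgenesis, and a virtual callosotomy control in which
callosal edges are deleted from normal networks without any other change.

## Synthetic cohort generator

Because no subject-level imaging data ships with the package, cohorts are
produced by a generative model whose defaults encode the study conditions:
ten subjects per condition, FA-like weights, and condition-specific
anatomy.

**Template anatomy.** For a given master seed, intrahemispheric wiring is
drawn once and mirrored into both hemispheres (gross anatomy is
bilaterally symmetric): within-lobe pairs are wired with probability 0.9
at mean weight 0.45, between-lobe pairs with probability 0.25 at weight
0.30, and between-lobe pairs touching an association "hub" area (Fra, Ac,
M2, Cl) with probability 0.55 — giving the normal network high-degree
frontal hubs. Homotopic callosal (`cc`) edges at weight 0.5 connect every
cortical pair not routed through another commissure; the anterior
commissure carries Pir, End, Am, Ob, the posterior commissure Sc, Ic, Pag,
and the hippocampal commissure Hp, Sub, Ent (commissural routing at the
region-pair level is not something tract-level imaging pins down; the
assignments are fixed here from standard mouse neuroanatomy and are
identical across conditions). Each edge's mean
weight receives a deterministic jitter (SD 0.06, clipped to [0.15, 0.6])
keyed by the node pair, so a given connection has the same template mean
in every condition — this anatomical heterogeneity is what makes pairwise
network correlations informative. All tract classes share the 0.5 weight
ceiling: the Onnela clustering coefficient normalizes by the network
maximum weight, so a condition-specific ceiling would bias clustering
comparisons between conditions.

**Condition transforms.** Complete dysgenesis removes all `cc` edges and
adds Probst-bundle edges from the frontal association cortex to six
ipsilateral posterior targets (Pa, A1, A2, V1, V2l, V2ml) in both
hemispheres at weight 0.5; the Probst phenotype is modeled as fully
penetrant and highly consistent (presence 1.0, retention 0.95), matching
its description as a consistent projection. Partial dysgenesis keeps an
anteriorly biased 30% of callosal edges (ranked by a frontal-proximity
score — lobe anteroposterior rank, then atlas order — deterministically
given the seed), carries reduced Probst edges (presence 0.5), and adds two
asymmetric interhemispheric sigmoid edges through the remnant: left
frontal association → right hippocampus at penetrance 0.5 and → right
parietal association at penetrance 0.2. Virtual callosotomy cohorts are
derived subject-by-subject from the paired normal cohort (same seeds) by
zeroing callosal entries, so intrahemispheric blocks are identical — the
generator-level realization of the in-silico control.

**Subject sampling.** Each template edge is retained independently per
subject with probability `presence_prob × consistency(tract class)`;
retained weights are drawn from a normal about the template mean (SD
0.05) truncated to (0, 1). Per-subject RNG streams are spawned from the
master seed (`SeedSequence(seed, spawn_key=(subject,))`), so cohorts are
bit-reproducible and subjects independent. Condition-specific consistency
tables drive the variability phenotype: normal networks are consistent
(0.9–0.95 per class), dysgenic networks less so intrahemispherically
(0.85 complete, 0.8 partial), and the partial remnant is the least
consistent interhemispheric class (0.6). Sigmoid carriers are recorded in
cohort metadata — the ground truth for penetrance checks.

**What the generator does not emulate.** No spatial embedding, streamline
count weighting, distance-dependent connection probability, subject-level
global FA differences, or registration/partial-volume artifacts. Passing
tests therefore demonstrate that the *analysis* recovers the directional
phenotypes planted by this edge-wise model, not that it would behave
identically on tractography data.

## Connectome construction

The voxel path operates on toy label volumes (region k occupies voxels
labeled k+1; volumes are assumed pre-eroded, so no morphology is applied).
A connection is retained when the sum of seed-map connectivity values over
the target region divided by the region's voxel count exceeds zero. The
two-step rule first proposes candidates from the per-seed maps, then
confirms each candidate on pair-masked maps, required from **both** seeds
(the stricter reading of an ambiguous criterion; configurable in
principle). Pair-constrained maps reuse the step-1 maps masked to the pair
rather than re-simulating streamlines — a documented simplification.
Confirmed edges are weighted by the mean FA over voxels whose combined
(elementwise-max) pair map exceeds 0.001; an edge with no suprathreshold
voxel is absent (exact zero).

Consensus connectomes keep edges present in at least `⌈f·n⌉` subjects
(default f = 0.5, i.e. "present in half", inclusive) and average weights
over the subjects carrying the edge. Averaging over carriers rather than
all subjects preserves FA semantics (an FA of zero is not a measurement of
the tract); the all-subject mean is available via `carrier_mean=False`.

## Graph analysis

**Thresholding.** Networks are proportionally thresholded at sparsities
0.05–0.13 (step 0.01): the `k = round(s·n(n−1)/2)` strongest edges are
kept (banker's rounding; ties at the cutoff broken by node-index order,
so results are deterministic). Thresholded edge sets are nested in `s`.
If a network has fewer nonzero edges than `k` it is returned unchanged
with a warning; the generator's defaults keep every condition's density
above the top of the grid so this does not occur in the standard design.

**Measures.** Path lengths are reciprocal weights (strong connections are
short) — the standard convention for FA-weighted connectomes; −log w is a
possible alternative not currently exposed. Global efficiency uses the
harmonic form (mean of inverse distances, zero for disconnected pairs),
which stays finite on disconnected graphs, where "inverse of the mean path
length" would not; local efficiency of a node is the global efficiency of
its neighbor-induced subgraph. Betweenness is reported as the percentage
of shortest paths through a node, normalized by (n−1)(n−2)/2 unordered
pairs. Clustering is the Onnela geometric-mean variant with weights
normalized by the network maximum. Weights below 1e−12 are treated as
absent in path computations (their reciprocals overflow). AUC uses the
trapezoidal rule; on the uniform grid this differs from a rectangle rule
only at the endpoints.

**Group AUC comparisons.** Per measure: D'Agostino–Pearson omnibus
normality on both groups; if both pass, an unpaired two-tailed t test
(Welch when an F test rejects equal variances at α = 0.05), otherwise
Mann-Whitney U. Raw p-values are Holm-Sidak adjusted across the measure
family. The Welch gate is applied to every measure uniformly.

**Communities.** Louvain maximization of resolution-γ modularity
(γ = 1.2, the value that maximizes modularity on normal controls and is
then applied to all conditions; `gamma_sweep` reproduces that optimization
step). Determinism: restarts (default 20) are seeded from a master seed
and the best-Q partition kept, with Q evaluated by the package's own
direct formula. Consensus partitions cluster the co-assignment matrix of
repeated runs until the runs agree. Participation is the Guimerà–Amaral
coefficient against a given partition; hub classes split nodes at the 0.8
strength quantile into connector (P ≥ 0.5) versus provincial hubs — both
cutoffs are unstated in the source analysis and are configurable.

**NBS.** One-sided pooled-variance two-sample t statistics per edge
(absent edges contribute weight 0; zero-variance edges get t = 0);
components of edges with t > t* are measured by edge count (the extent
statistic; intensity is not offered). The null is the maximal component
extent over full subject-relabeling permutations (duplicates allowed —
standard Monte-Carlo NBS), and p-values carry the +1 correction, so
p ≥ 1/(n_perm+1). NBS runs on raw weighted matrices, not thresholded ones
(toolbox convention). The threshold sweep (t* = 2…5) counts, per edge, the
thresholds at which the edge sat in an FWER-significant component.

**Variability and novelty.** Per-edge coefficient of variation includes
zeros (an absent edge is a zero-strength observation) and is undefined
(NaN) for edges absent everywhere. Pairwise similarity correlates two
subjects' edge-weight vectors restricted to an edge class and to the union
of edges present in at least one of the pair — including structural zeros
shared by both would inflate the correlation; this is configurable
(`union_only`), as is Spearman instead of Pearson. Each subject's n−1 pair
correlations are averaged (self-comparison excluded). Novel edges are
evaluated on unthresholded individual connectomes (the rule precedes
thresholding in the workflow): present in ≥ 2 case subjects and in no
control subject; preserved edges appear in both groups' consensus
networks.

## Calibration and problem sizes

The NBS null calibration (acceptance script and test) uses 200 replicate
pairs of 10-subject cohorts from a single normal template with 1000
permutations at t* = 3 — sizes chosen to put Monte-Carlo error around the
nominal 5% level at a few percent while completing in about a minute. The
end-to-end pipeline test runs 5 subjects per condition with 150
permutations for the same reason; the library defaults remain the study
values (10 subjects, 5000 permutations).

## Known limitations

- The degree–participation correlation's sign under the default generator
  is reliably negative for complete dysgenesis (connector roles shift to
  low-degree commissural subcortical nodes) but is seed-dependent for
  normal networks: Louvain at γ = 1.2 on a consensus network sometimes
  returns two hemispheric modules, in which case high-degree nodes are
  mechanically intra-module and the correlation turns negative. Tests
  assert only the robust direction.
- Consensus partitions on near-tied co-assignment structure may terminate
  at the modal run after the iteration cap rather than exact agreement.
- The voxel-path construction is exercised on toy volumes only; no
  erosion, registration, or streamline simulation is implemented.
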
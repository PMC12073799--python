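"""Synthetic cohort generator for mouse callosal-dysgenesis connectomes.

Generates ground-truth template networks for four callosal conditions —
normal corpus callosum (``normal_cc``), complete dysgenesis
(``complete_ccd``), partial dysgenesis (``partial_ccd``) and an in-silico
virtual callosotomy control (``virtual_callosotomy``) — over a bilateral
76-region (38 per hemisphere) adult mouse brain parcellation, and samples
individual-subject weighted connectomes with controlled presence/weight
noise.

Template anatomy, by condition:

* ``normal_cc`` — dense within-lobe and sparse between-lobe intrahemispheric
  edges, homotopic callosal (``cc``) edges for cortical pairs, and anterior
  / posterior / hippocampal commissure (``ac``/``pc``/``hc``) edges for
  designated subcortical and hippocampal pairs.
* ``complete_ccd`` — all ``cc`` edges removed; Probst-bundle edges added
  from the frontal association cortex to ipsilateral posterior (parietal,
  auditory, visual) regions in both hemispheres, with elevated weight.
* ``partial_ccd`` — an anteriorly biased fraction of ``cc`` edges kept
  (the callosal remnant), reduced Probst edges, and asymmetric heterotopic
  "sigmoid" edges from the left frontal association cortex to the
  contralateral hippocampus (and, less often, parietal association cortex)
  carried by only a fraction of subjects (incomplete penetrance).
* ``virtual_callosotomy`` — the normal network with ``cc`` edges deleted
  and nothing else changed; cohorts are derived subject-by-subject from the
  paired ``normal_cc`` samples so intrahemispheric blocks match exactly.

``ac``/``pc``/``hc`` edges are identical across all conditions: the study
system shows no loss of the non-callosal commissures in dysgenesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

CONDITIONS = ("normal_cc", "complete_ccd", "partial_ccd", "virtual_callosotomy")

#: Tract tags an edge may carry. cc/ac/pc/hc are commissural (interhemispheric);
#: probst is intrahemispheric rerouting; sigmoid is the asymmetric heterotopic
#: interhemispheric edge through the callosal remnant.
TRACT_TAGS = ("cc", "ac", "pc", "hc", "intra", "probst", "sigmoid")

# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

#: The 38 atlas areas (name, abbreviation) of one hemisphere, in canonical
#: atlas order, with the lobe group and cortical flag used by the generator.
#: Lobe grouping and cortical flags follow standard mouse neuroanatomy; the
#: atlas itself only fixes the area list and order.
_ATLAS_AREAS: list[tuple[str, str, str, bool]] = [
    ("Subiculum", "Sub", "hippocampal", True),
    ("Entorhinal cortex", "Ent", "hippocampal", True),
    ("Dorsolateral orbital cortex", "Dlo", "frontal", True),
    ("Frontal association cortex", "Fra", "frontal", True),
    ("Lateral orbital cortex", "Lo", "frontal", True),
    ("Primary motor cortex", "M1", "frontal", True),
    ("Secondary motor cortex", "M2", "frontal", True),
    ("Ventromedial orbital cortex", "Vmo", "frontal", True),
    ("Parietal association cortex", "Pa", "parietal", True),
    ("Primary somatosensory cortex", "S1", "parietal", True),
    ("Secondary somatosensory cortex", "S2", "parietal", True),
    ("Primary auditory cortex", "A1", "temporal", True),
    ("Secondary auditory cortex", "A2", "temporal", True),
    ("Temporal association area", "Ta", "temporal", True),
    ("Primary visual cortex", "V1", "occipital", True),
    ("Secondary visual cortex lateral", "V2l", "occipital", True),
    ("Secondary visual cortex mediolateral", "V2ml", "occipital", True),
    ("Anterior cingulate", "Ac", "frontal", True),
    ("Retrosplenial area", "Rs", "occipital", True),
    ("Insular cortex", "In", "temporal", True),
    ("Ectorhinal cortex", "Ect", "temporal", True),
    ("Perirhinal cortex", "Pr", "temporal", True),
    ("Claustrum", "Cl", "ventral_pallial", True),
    ("Endopiriform nucleus", "End", "ventral_pallial", True),
    ("Piriform nucleus", "Pir", "ventral_pallial", True),
    ("Amygdala", "Am", "ventral_pallial", True),
    ("Hippocampus", "Hp", "hippocampal", True),
    ("Caudate putamen", "Cp", "subcortical", False),
    ("Lateral globus pallidus", "Lgp", "subcortical", False),
    ("Olfactory bulb", "Ob", "subcortical", False),
    ("Accumbens nucleus", "An", "subcortical", False),
    ("Hypothalamus", "Hyp", "subcortical", False),
    ("Septum", "Sep", "subcortical", False),
    ("Thalamus", "Thal", "subcortical", False),
    ("Superior colliculus", "Sc", "midbrain_cerebellar", False),
    ("Inferior colliculus", "Ic", "midbrain_cerebellar", False),
    ("Periaqueductal grey", "Pag", "midbrain_cerebellar", False),
    ("Cerebellum", "Cb", "midbrain_cerebellar", False),
]


@dataclass(frozen=True)
class Node:
    region_id: int
    name: str
    abbreviation: str
    hemisphere: str  # "L" or "R"
    lobe: str
    is_cortical: bool

    @property
    def label(self) -> str:
        """Canonical node label, e.g. ``Fra,L``."""
        return f"{self.abbreviation},{self.hemisphere}"


@dataclass(frozen=True)
class Parcellation:
    """Ordered bilateral node set: all left-hemisphere areas in atlas order,
    then their right-hemisphere mirrors in the same order."""

    nodes: tuple[Node, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def homotopic_partner(self, i: int) -> int:
        """Index of the mirror node in the opposite hemisphere."""
        half = self.n_nodes // 2
        return i + half if i < half else i - half

    def hemispheres(self) -> np.ndarray:
        return np.array([n.hemisphere for n in self.nodes])

    def interhemispheric_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix: True where the two nodes lie in opposite
        hemispheres (diagonal False)."""
        h = self.hemispheres()
        return h[:, None] != h[None, :]


def build_parcellation() -> Parcellation:
    """Mirror the 38 atlas areas into left and right hemispheres.

    Returns the canonical 76-node parcellation: nodes 0..37 are the left
    hemisphere in atlas order, nodes 38..75 the homotopic right partners.
    """
    nodes: list[Node] = []
    for hemi in ("L", "R"):
        for k, (name, abbrev, lobe, cortical) in enumerate(_ATLAS_AREAS):
            nodes.append(
                Node(
                    region_id=len(nodes),
                    name=name,
                    abbreviation=abbrev,
                    hemisphere=hemi,
                    lobe=lobe,
                    is_cortical=cortical,
                )
            )
    return Parcellation(nodes=tuple(nodes))


# ---------------------------------------------------------------------------
# Template networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateEdge:
    i: int  # i < j
    j: int
    mean_weight: float
    tract_tag: str
    presence_prob: float = 1.0


@dataclass(frozen=True)
class TemplateNetwork:
    parcellation: Parcellation
    condition: str
    edges: tuple[TemplateEdge, ...]

    def edges_by_tag(self, tag: str) -> list[TemplateEdge]:
        return [e for e in self.edges if e.tract_tag == tag]


# Generative defaults. Template anatomy is drawn once per cohort seed:
# each candidate intrahemispheric pair enters the template with the
# edge-class probability below (mirrored across hemispheres, since gross
# anatomy is bilaterally symmetric) and is then retained per subject with
# the tract-class consistency — so subjects share most of their wiring and
# pairwise similarity is governed by consistency. Within-lobe connectivity
# is dense and strong, between-lobe sparse and weaker. Association "hub"
# areas carry denser between-lobe connectivity so the normal network has
# high-degree, high-participation frontal hubs. All tract-class mean
# weights share the 0.5 ceiling so the weight scale is comparable across
# conditions (max-normalized measures would otherwise be biased).
WITHIN_LOBE_P = 0.9
WITHIN_LOBE_W = 0.45
BETWEEN_LOBE_P = 0.25
BETWEEN_LOBE_W = 0.30
HUB_BETWEEN_LOBE_P = 0.55
HUB_ABBREVS = ("Fra", "Ac", "M2", "Cl")
CC_W = 0.5
COMMISSURE_W = 0.5
PROBST_W = 0.5
PROBST_P = 1.0
PROBST_P_PARTIAL = 0.5
SIGMOID_W = 0.5
#: Secondary sigmoid target (left frontal association to contralateral
#: parietal association), seen at lower penetrance than the hippocampal one.
SIGMOID_SECONDARY_PENETRANCE = 0.2
#: SD of the per-edge anatomical weight heterogeneity (shared across
#: subjects and conditions, keyed by node pair); gives edge-weight vectors
#: the between-edge spread that makes pairwise network correlations
#: informative. Jittered means are clipped to this range.
EDGE_WEIGHT_JITTER_SD = 0.06
EDGE_WEIGHT_RANGE = (0.15, 0.6)

#: Homotopic pairs routed through each non-callosal commissure.
AC_ABBREVS = ("Pir", "End", "Am", "Ob")  # anterior commissure
PC_ABBREVS = ("Sc", "Ic", "Pag")  # posterior commissure
HC_ABBREVS = ("Hp", "Sub", "Ent")  # hippocampal commissure

#: Ipsilateral Probst-bundle targets of the frontal association cortex.
PROBST_TARGETS = ("Pa", "A1", "A2", "V1", "V2l", "V2ml")

#: Anteroposterior rank of lobe groups, used to bias the callosal remnant
#: of partial dysgenesis toward anterior (frontal) homotopic pairs.
_LOBE_AP_RANK = {
    "frontal": 0,
    "parietal": 1,
    "ventral_pallial": 2,
    "temporal": 3,
    "occipital": 4,
    "hippocampal": 5,
    "subcortical": 6,
    "midbrain_cerebellar": 7,
}

#: Per-condition edge-retention consistency by tract class.  Retention
#: probability of a template edge in one subject is presence_prob times the
#: consistency of its tract class, so lower consistency yields less
#: reproducible (more variable) networks for that class — dysgenic
#: conditions have less consistent intrahemispheric wiring, and the partial
#: remnant is the least consistent interhemispheric class.
DEFAULT_CONSISTENCY: dict[str, dict[str, float]] = {
    "normal_cc": {"cc": 0.95, "ac": 0.95, "pc": 0.95, "hc": 0.95, "intra": 0.9},
    "complete_ccd": {
        "ac": 0.95, "pc": 0.95, "hc": 0.95, "intra": 0.85, "probst": 0.95,
    },
    "partial_ccd": {
        "cc": 0.6, "ac": 0.9, "pc": 0.9, "hc": 0.9,
        "intra": 0.8, "probst": 0.85, "sigmoid": 1.0,
    },
    "virtual_callosotomy": {
        "cc": 0.95, "ac": 0.95, "pc": 0.95, "hc": 0.95, "intra": 0.9,
    },
}


@dataclass
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    ``edge_consistency`` defaults to the condition-specific table
    :data:`DEFAULT_CONSISTENCY`; ``sigmoid_penetrance`` is the fraction of
    partial-dysgenesis subjects carrying the primary sigmoid edge;
    ``remnant_fraction`` the fraction of callosal edges surviving in the
    remnant, selected anterior-first.
    """

    condition: str = "normal_cc"
    n_subjects: int = 10
    weight_sd: float = 0.05
    edge_consistency: dict[str, float] | None = None
    sigmoid_penetrance: float = 0.5
    remnant_fraction: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0 < self.sigmoid_penetrance <= 1:
            raise ValueError("sigmoid_penetrance must be in (0, 1]")
        if self.edge_consistency is not None:
            for tag, c in self.edge_consistency.items():
                if not 0 < c <= 1:
                    raise ValueError(f"consistency for {tag!r} not in (0, 1]")

    def consistency(self, tract_tag: str) -> float:
        table = self.edge_consistency
        if table is None:
            table = DEFAULT_CONSISTENCY[self.condition]
        return table.get(tract_tag, 1.0)


def _template_rng(rng_seed: int) -> np.random.Generator:
    """Template-anatomy stream, disjoint from the per-subject streams."""
    ss = np.random.SeedSequence(rng_seed, spawn_key=(1_000_000,))
    return np.random.default_rng(ss)


def _base_edges(parc: Parcellation, rng_seed: int) -> list[TemplateEdge]:
    """Intrahemispheric edges plus the non-callosal commissures, shared by
    every condition built from the same seed.

    Which intrahemispheric pairs are wired is drawn once per seed from the
    edge-class probabilities and mirrored into both hemispheres; included
    edges have presence probability 1 (inter-subject variation comes from
    the tract-class consistency at sampling time).
    """
    edges: list[TemplateEdge] = []
    half = parc.n_nodes // 2
    hubs = set(HUB_ABBREVS)
    rng = _template_rng(rng_seed)
    for a in range(half):
        for b in range(a + 1, half):
            na, nb = parc.nodes[a], parc.nodes[b]
            if na.lobe == nb.lobe:
                p, w = WITHIN_LOBE_P, WITHIN_LOBE_W
            elif na.abbreviation in hubs or nb.abbreviation in hubs:
                p, w = HUB_BETWEEN_LOBE_P, BETWEEN_LOBE_W
            else:
                p, w = BETWEEN_LOBE_P, BETWEEN_LOBE_W
            if rng.random() < p:  # bilaterally mirrored anatomy
                edges.append(TemplateEdge(a, b, w, "intra", 1.0))
                edges.append(TemplateEdge(half + a, half + b, w, "intra", 1.0))
    for tag, abbrevs in (("ac", AC_ABBREVS), ("pc", PC_ABBREVS), ("hc", HC_ABBREVS)):
        for abbrev in abbrevs:
            i = parc.index(f"{abbrev},L")
            edges.append(
                TemplateEdge(i, parc.homotopic_partner(i), COMMISSURE_W, tag, 1.0)
            )
    return edges


def _cc_edges(parc: Parcellation) -> list[TemplateEdge]:
    """Homotopic callosal edges: one per cortical, non-commissure-routed
    homotopic pair (hippocampal-lobe pairs cross via hc, ventral pallial via
    ac — except the claustrum, which is callosally connected)."""
    via_other = set(AC_ABBREVS) | set(PC_ABBREVS) | set(HC_ABBREVS)
    edges = []
    for k, node in enumerate(parc.nodes[: parc.n_nodes // 2]):
        if node.is_cortical and node.abbreviation not in via_other:
            if node.lobe == "hippocampal":
                continue
            edges.append(
                TemplateEdge(k, parc.homotopic_partner(k), CC_W, "cc", 1.0)
            )
    return edges


def _frontal_proximity_rank(parc: Parcellation, edge: TemplateEdge) -> tuple:
    node = parc.nodes[edge.i]
    return (_LOBE_AP_RANK[node.lobe], edge.i)


def _probst_edges(parc: Parcellation, presence: float) -> list[TemplateEdge]:
    edges = []
    for hemi in ("L", "R"):
        src = parc.index(f"Fra,{hemi}")
        for target in PROBST_TARGETS:
            dst = parc.index(f"{target},{hemi}")
            i, j = min(src, dst), max(src, dst)
            edges.append(TemplateEdge(i, j, PROBST_W, "probst", presence))
    return edges


def build_template(
    parcellation: Parcellation,
    condition: str,
    config: CohortConfig | None = None,
) -> TemplateNetwork:
    """Deterministic ground-truth network for one callosal condition.

    The four conditions share identical intrahemispheric base wiring and
    non-callosal commissures; they differ only in callosal edges, Probst
    rerouting and the sigmoid remnant edges (see module docstring).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition: {condition!r}")
    if config is None:
        config = CohortConfig(condition=condition)
    edges = _base_edges(parcellation, config.rng_seed)
    cc = _cc_edges(parcellation)

    if condition in ("normal_cc", "virtual_callosotomy"):
        if condition == "normal_cc":
            edges.extend(cc)
        edges = _jitter_weights(edges, config.rng_seed, parcellation.n_nodes)
        return TemplateNetwork(parcellation, condition, tuple(edges))

    # Probst rerouting replaces the base between-lobe edges on its pairs.
    presence = PROBST_P if condition == "complete_ccd" else PROBST_P_PARTIAL
    probst = _probst_edges(parcellation, presence)
    probst_pairs = {(e.i, e.j) for e in probst}
    edges = [e for e in edges if (e.i, e.j) not in probst_pairs]
    edges.extend(probst)

    if condition == "partial_ccd":
        n_keep = int(round(config.remnant_fraction * len(cc)))
        remnant = sorted(cc, key=lambda e: _frontal_proximity_rank(parcellation, e))
        edges.extend(remnant[:n_keep])
        fra_l = parcellation.index("Fra,L")
        for target, pen in (
            ("Hp,R", config.sigmoid_penetrance),
            ("Pa,R", SIGMOID_SECONDARY_PENETRANCE),
        ):
            dst = parcellation.index(target)
            i, j = min(fra_l, dst), max(fra_l, dst)
            edges.append(TemplateEdge(i, j, SIGMOID_W, "sigmoid", pen))

    edges = _jitter_weights(edges, config.rng_seed, parcellation.n_nodes)
    return TemplateNetwork(parcellation, condition, tuple(edges))


def _jitter_weights(
    edges: list[TemplateEdge], rng_seed: int, n_nodes: int
) -> list[TemplateEdge]:
    """Apply deterministic per-edge anatomical heterogeneity to the class
    mean weights. The jitter is keyed by (seed, node pair), so a given
    connection has the same template mean in every condition built from
    the same seed."""
    out = []
    lo, hi = EDGE_WEIGHT_RANGE
    for e in edges:
        rng = np.random.default_rng(
            np.random.SeedSequence(rng_seed, spawn_key=(2_000_000, e.i * n_nodes + e.j))
        )
        w = float(np.clip(e.mean_weight + rng.normal(0, EDGE_WEIGHT_JITTER_SD), lo, hi))
        out.append(TemplateEdge(e.i, e.j, w, e.tract_tag, e.presence_prob))
    return out


# ---------------------------------------------------------------------------
# Individual sampling
# ---------------------------------------------------------------------------


@dataclass
class Connectome:
    """A single subject's weighted structural network.

    ``weights`` is symmetric with zero diagonal and entries in [0, 1]
    (FA-like strengths); exact zero means "no connection".
    """

    parcellation: Parcellation
    weights: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if W.shape[0] != self.parcellation.n_nodes:
            raise ValueError("weight matrix does not match parcellation size")
        if not np.allclose(W, W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero")
        if W.min() < 0 or W.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def _subject_rng(rng_seed: int, subject_index: int) -> np.random.Generator:
    """Per-subject stream: the ``subject_index``-th spawn of the master
    seed sequence, so subjects are independent and reproducible."""
    ss = np.random.SeedSequence(rng_seed, spawn_key=(subject_index,))
    return np.random.default_rng(ss)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float
) -> float:
    """Draw from N(mean, sd) truncated to the open interval (0, 1)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if 0 < x < 1:
            return float(x)
    raise RuntimeError("truncated normal rejection sampling failed")


def sample_individual(
    template: TemplateNetwork,
    config: CohortConfig,
    subject_index: int,
) -> Connectome:
    """Sample one subject from a condition template.

    Each template edge is retained independently with probability
    ``presence_prob * consistency(tract_tag)``; retained edges get a weight
    drawn from a truncated normal about the template mean. Deterministic
    given ``(config.rng_seed, subject_index)``.
    """
    rng = _subject_rng(config.rng_seed, subject_index)
    n = template.parcellation.n_nodes
    W = np.zeros((n, n))
    for e in template.edges:
        u = rng.random()
        w_draw = _truncated_normal(rng, e.mean_weight, config.weight_sd)
        if u < e.presence_prob * config.consistency(e.tract_tag):
            W[e.i, e.j] = W[e.j, e.i] = w_draw
    return Connectome(
        parcellation=template.parcellation,
        weights=W,
        subject_id=f"{template.condition}_{subject_index:02d}",
        condition=template.condition,
    )


@dataclass
class Cohort:
    """A group of subjects sharing a parcellation and condition label."""

    condition: str
    parcellation: Parcellation
    connectomes: list[Connectome]
    config: CohortConfig | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.connectomes)

    def weight_stack(self) -> np.ndarray:
        """(n_subjects, n, n) array of all weight matrices."""
        return np.stack([c.weights for c in self.connectomes])


def generate_cohort(condition: str, config: CohortConfig | None = None) -> Cohort:
    """Generate a full cohort for one condition.

    ``virtual_callosotomy`` is derived from the paired ``normal_cc`` cohort
    sampled with the same seeds, with callosal edges zeroed afterwards —
    the in-silico control shares every other connection with its normal
    counterpart, subject by subject.

    Metadata records per-subject seeds and, for ``partial_ccd``, the carrier
    subjects of each sigmoid-tagged edge (the ground-truth penetrance log).
    """
    if config is None:
        config = CohortConfig(condition=condition)
    elif config.condition != condition:
        config = replace(config, condition=condition)
    parc = build_parcellation()

    if condition == "virtual_callosotomy":
        normal_cfg = replace(config, condition="normal_cc")
        base = generate_cohort("normal_cc", normal_cfg)
        cc = _cc_edges(parc)
        subjects = []
        for k, c in enumerate(base.connectomes):
            W = c.weights.copy()
            for e in cc:
                W[e.i, e.j] = W[e.j, e.i] = 0.0
            subjects.append(
                Connectome(parc, W, f"virtual_callosotomy_{k:02d}", condition)
            )
        meta = {
            "condition": condition,
            "rng_seed": config.rng_seed,
            "subject_seeds": base.metadata["subject_seeds"],
            "paired_with": "normal_cc",
            "cc_edges_removed": [[e.i, e.j] for e in cc],
        }
        return Cohort(condition, parc, subjects, config, meta)

    template = build_template(parc, condition, config)
    return sample_cohort(template, config)


def sample_cohort(template: TemplateNetwork, config: CohortConfig) -> Cohort:
    """Sample ``config.n_subjects`` subjects from an existing template.

    Useful for null designs where several groups must share one template
    anatomy while drawing independent subjects (vary ``config.rng_seed``).
    """
    parc = template.parcellation
    subjects = [
        sample_individual(template, config, k) for k in range(config.n_subjects)
    ]
    meta: dict = {
        "condition": template.condition,
        "rng_seed": config.rng_seed,
        "subject_seeds": [
            [config.rng_seed, k] for k in range(config.n_subjects)
        ],
        "template_edges": [
            {
                "i": e.i,
                "j": e.j,
                "mean_weight": e.mean_weight,
                "tract_tag": e.tract_tag,
                "presence_prob": e.presence_prob,
            }
            for e in template.edges
        ],
    }
    sigmoid = template.edges_by_tag("sigmoid")
    if sigmoid:
        carriers = {}
        for e in sigmoid:
            label = f"{parc.nodes[e.i].label}-{parc.nodes[e.j].label}"
            carriers[label] = [
                k
                for k, c in enumerate(subjects)
                if c.weights[e.i, e.j] > 0
            ]
        meta["sigmoid_carriers"] = carriers
    return Cohort(template.condition, parc, subjects, config, meta)
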
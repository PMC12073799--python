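"""File formats and pipeline orchestration.

Interchange formats: labeled square CSV for weight matrices (header row and
index column carry node labels like ``Fra,L``), TSV for node tables,
GraphML for graph tools, JSON for reports and run manifests, YAML for
configuration. Node order is canonical (atlas order, left hemisphere then
right); matrices are stored in that order.

``run_pipeline`` executes the full analysis in study order — simulate,
consensus, metric AUCs, group comparisons, community/hub analysis, NBS
threshold sweeps, variability and novelty — and writes a manifest making
the run reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .build import ConsensusConnectome, build_consensus
from .community import (
    Partition,
    classify_hubs,
    degree_participation_correlation,
    hub_table,
    louvain,
)
from .metrics import AnalysisConfig, cohort_auc_table, compare_groups_auc, NETWORK_MEASURES
from .nbs import threshold_sweep
from .synthetic import (
    CONDITIONS,
    Cohort,
    CohortConfig,
    Connectome,
    Parcellation,
    build_parcellation,
    generate_cohort,
)
from .variability import discover_novel_edges, group_compare_similarity, pairwise_similarity

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9


# ---------------------------------------------------------------------------
# Node tables and matrices
# ---------------------------------------------------------------------------


def write_node_table(parcellation: Parcellation, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": n.region_id,
                "name": n.name,
                "abbreviation": n.abbreviation,
                "hemisphere": n.hemisphere,
                "lobe": n.lobe,
                "is_cortical": n.is_cortical,
            }
            for n in parcellation.nodes
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_node_table(path: str | Path) -> Parcellation:
    from .synthetic import Node

    df = pd.read_csv(path, sep="\t")
    nodes = tuple(
        Node(
            region_id=int(r.id),
            name=str(r.name),
            abbreviation=str(r.abbreviation),
            hemisphere=str(r.hemisphere),
            lobe=str(r.lobe),
            is_cortical=bool(r.is_cortical),
        )
        for r in df.itertuples()
    )
    return Parcellation(nodes=nodes)


def write_connectome(connectome: Connectome, path: str | Path) -> None:
    labels = connectome.parcellation.labels
    pd.DataFrame(connectome.weights, index=labels, columns=labels).to_csv(path)


def read_connectome(
    path: str | Path,
    parcellation: Parcellation,
    subject_id: str = "",
    condition: str = "",
) -> Connectome:
    """Read and validate a labeled square CSV weight matrix.

    Rejects non-square matrices, label mismatches with the node table,
    negative weights and asymmetry beyond ``SYMMETRY_TOL`` (matrices within
    tolerance are symmetrized exactly).
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError("row and column labels differ")
    if list(df.index) != parcellation.labels:
        raise ValueError("matrix labels do not match the node table")
    W = df.to_numpy(dtype=float)
    if W.min() < 0:
        raise ValueError("negative weights are not allowed")
    if np.abs(W - W.T).max() > SYMMETRY_TOL:
        raise ValueError(f"matrix asymmetric beyond tolerance {SYMMETRY_TOL}")
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return Connectome(parcellation, W, subject_id or Path(path).stem, condition)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write a cohort as per-subject CSV matrices, a node table TSV and a
    JSON metadata file (seeds, condition, template edge list)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_node_table(cohort.parcellation, out / "nodes.tsv")
    for c in cohort.connectomes:
        write_connectome(c, out / f"{c.subject_id}.csv")
    meta = dict(cohort.metadata)
    meta["condition"] = cohort.condition
    meta["subjects"] = [c.subject_id for c in cohort.connectomes]
    if cohort.config is not None:
        meta["config"] = asdict(cohort.config)
    (out / "metadata.json").write_text(json.dumps(meta, indent=1))
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    out = Path(in_dir)
    meta = json.loads((out / "metadata.json").read_text())
    parc = read_node_table(out / "nodes.tsv")
    condition = meta.get("condition", "")
    connectomes = [
        read_connectome(out / f"{sid}.csv", parc, sid, condition)
        for sid in meta["subjects"]
    ]
    config = None
    if "config" in meta:
        cfg = dict(meta["config"])
        if cfg.get("edge_consistency") is not None:
            cfg["edge_consistency"] = dict(cfg["edge_consistency"])
        config = CohortConfig(**cfg)
    return Cohort(condition, parc, connectomes, config, meta)


# ---------------------------------------------------------------------------
# GraphML
# ---------------------------------------------------------------------------


def write_graphml(
    network: Connectome | ConsensusConnectome,
    path: str | Path,
    partition: Partition | None = None,
    participation_values: np.ndarray | None = None,
) -> None:
    """GraphML export with node attributes (label, hemisphere, lobe,
    strength, optional module and participation) and the edge weight."""
    connectome = getattr(network, "connectome", network)
    W = connectome.weights
    parc = connectome.parcellation
    G = nx.Graph()
    strength = W.sum(axis=1)
    for k, node in enumerate(parc.nodes):
        attrs = {
            "label": node.label,
            "hemisphere": node.hemisphere,
            "lobe": node.lobe,
            "strength": float(strength[k]),
        }
        if partition is not None:
            attrs["module"] = int(partition.labels[k])
        if participation_values is not None:
            attrs["participation"] = float(participation_values[k])
        G.add_node(k, **attrs)
    iu, ju = np.nonzero(np.triu(W, k=1))
    for i, j in zip(iu, ju):
        G.add_edge(int(i), int(j), weight=float(W[i, j]))
    nx.write_graphml(G, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path, node_type=int)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Record of one end-to-end run: config, seed, package version and the
    SHA-256 hash of every artifact written."""

    seed: int
    config: dict
    version: str
    outputs: dict[str, str]  # relative path -> sha256

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


#: Pipeline NBS contrasts: (case, control, direction label in output names).
PIPELINE_CONTRASTS = [
    ("complete_ccd", "virtual_callosotomy"),
    ("complete_ccd", "normal_cc"),
    ("partial_ccd", "virtual_callosotomy"),
    ("partial_ccd", "normal_cc"),
    ("normal_cc", "virtual_callosotomy"),
]


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    analysis: AnalysisConfig | None = None,
    cohort_config: CohortConfig | None = None,
    conditions: tuple[str, ...] = CONDITIONS,
) -> RunManifest:
    """Simulate all conditions and run the complete analysis.

    Stages, in order: cohort simulation; consensus connectomes; per-subject
    metric AUCs and group comparisons against normal controls; community
    detection, participation and hubs on each consensus network; NBS
    threshold sweeps for the study contrasts; pairwise similarity by edge
    class with group comparisons; novelty discovery for the dysgenic
    conditions. Everything is written under ``out_dir`` with a manifest.
    """
    analysis = analysis or AnalysisConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("simulating cohorts (seed=%d)", seed)
    cohorts: dict[str, Cohort] = {}
    for cond in conditions:
        cfg = (
            replace(cohort_config, condition=cond, rng_seed=seed)
            if cohort_config is not None
            else CohortConfig(condition=cond, rng_seed=seed)
        )
        cohorts[cond] = generate_cohort(cond, cfg)
        write_cohort(cohorts[cond], out / "cohorts" / cond)

    logger.info("building consensus connectomes")
    consensus: dict[str, ConsensusConnectome] = {}
    for cond, cohort in cohorts.items():
        consensus[cond] = build_consensus(cohort, analysis.consensus_fraction)
        write_connectome(consensus[cond].connectome, out / f"consensus_{cond}.csv")

    logger.info("computing metric AUCs")
    auc_tables = {
        cond: cohort_auc_table(cohort, config=analysis)
        for cond, cohort in cohorts.items()
    }
    pd.concat(auc_tables.values(), ignore_index=True).to_csv(
        out / "metric_auc.tsv", sep="\t", index=False
    )

    logger.info("group AUC comparisons vs normal controls")
    measures = list(NETWORK_MEASURES)
    reports = []
    for cond in conditions:
        if cond == "normal_cc":
            continue
        rep = compare_groups_auc(
            {m: auc_tables[cond][m].to_numpy() for m in measures},
            {m: auc_tables["normal_cc"][m].to_numpy() for m in measures},
            alpha=analysis.alpha,
            labels=(cond, "normal_cc"),
        )
        reports.append(rep)
    pd.concat(reports, ignore_index=True).to_json(
        out / "auc_group_tests.json", orient="records", indent=1
    )

    logger.info("community and hub analysis (gamma=%.2f)", analysis.gamma)
    community_summary = {}
    for cond, cons in consensus.items():
        part = louvain(cons, gamma=analysis.gamma, seed=seed)
        table = hub_table(cons, part, labels=cons.parcellation.labels)
        table = classify_hubs(table)
        table.to_csv(out / f"hubs_{cond}.tsv", sep="\t", index=False)
        r, p = degree_participation_correlation(table)
        community_summary[cond] = {
            "q": part.q,
            "n_modules": part.n_modules,
            "degree_participation_r": r,
            "degree_participation_p": p,
        }
        write_graphml(
            cons, out / f"consensus_{cond}.graphml",
            partition=part,
            participation_values=table["participation"].to_numpy(),
        )
    (out / "community.json").write_text(json.dumps(community_summary, indent=1))

    logger.info("NBS threshold sweeps")
    nbs_summary = {}
    for k, (case, control) in enumerate(PIPELINE_CONTRASTS):
        if case not in cohorts or control not in cohorts:
            continue
        sweep = threshold_sweep(
            cohorts[case],
            cohorts[control],
            thresholds=analysis.nbs_thresholds,
            n_perm=analysis.nbs_permutations,
            seed=seed + 10 * k,
            alpha=analysis.alpha,
        )
        name = f"{case}_gt_{control}"
        labels = cohorts[case].parcellation.labels
        pd.DataFrame(sweep.counts, index=labels, columns=labels).to_csv(
            out / f"nbs_counts_{name}.csv"
        )
        nbs_summary[name] = [
            {
                "t_star": res.t_star,
                "component_sizes": [len(c) for c in res.components],
                "p_values": res.p_values.tolist(),
            }
            for res in sweep.results
        ]
    (out / "nbs.json").write_text(json.dumps(nbs_summary, indent=1))

    logger.info("variability and novelty")
    sim_summary = {}
    for cond, cohort in cohorts.items():
        sim_summary[cond] = {}
        for edge_class in ("whole", "inter", "intra"):
            rep = pairwise_similarity(cohort, edge_class)
            sim_summary[cond][edge_class] = {
                "per_subject": rep.per_subject.tolist(),
                "mean": rep.mean,
                "sem": rep.sem,
            }
    (out / "similarity.json").write_text(json.dumps(sim_summary, indent=1))

    novelty_summary = {}
    if "normal_cc" in cohorts:
        for case in ("partial_ccd", "complete_ccd"):
            if case not in cohorts:
                continue
            report = discover_novel_edges(
                cohorts[case], cohorts["normal_cc"], analysis.novelty_min_count
            )
            report.novel.to_csv(out / f"novel_{case}.tsv", sep="\t", index=False)
            novelty_summary[case] = {
                "n_novel": len(report.novel),
                "n_preserved": len(report.preserved),
            }
    (out / "novelty.json").write_text(json.dumps(novelty_summary, indent=1))

    outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        seed=seed,
        config={
            "analysis": asdict(analysis),
            "cohort": asdict(cohort_config) if cohort_config else None,
            "conditions": list(conditions),
        },
        version=__version__,
        outputs=outputs,
    )
    manifest.write(out / "manifest.json")
    logger.info("pipeline complete: %d artifacts", len(outputs))
    return manifest
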
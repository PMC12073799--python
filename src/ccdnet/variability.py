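"""Edge-weight variability, pairwise network similarity, and novel-edge
discovery.

Variability is quantified two ways: the per-edge normalized standard
deviation (coefficient of variation of weights across subjects, zeros
included), and the pairwise network-similarity statistic — for every pair
of subjects in a cohort, the Pearson correlation of their edge-weight
vectors restricted to an edge class (whole network, interhemispheric or
intrahemispheric) and to the union of edges present in at least one of the
pair; each subject's n-1 pair correlations are averaged, giving one
similarity value per subject.

Novel connections are edges present in at least ``min_count`` case subjects
but absent from every control subject (evaluated on unthresholded
individual connectomes, presence = weight > 0); preserved connections
appear in both groups' consensus connectomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .build import build_consensus
from .metrics import compare_groups_auc
from .synthetic import Cohort

logger = logging.getLogger(__name__)

EDGE_CLASSES = ("whole", "inter", "intra")


def _class_mask(cohort: Cohort, edge_class: str) -> np.ndarray:
    """Upper-triangle boolean mask selecting the requested edge class."""
    n = cohort.parcellation.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    if edge_class == "whole":
        return np.ones(iu.size, dtype=bool), iu, ju
    inter = cohort.parcellation.interhemispheric_mask()[iu, ju]
    if edge_class == "inter":
        return inter, iu, ju
    if edge_class == "intra":
        return ~inter, iu, ju
    raise ValueError(f"unknown edge class: {edge_class!r}")


def edge_normalized_sd(cohort: Cohort) -> np.ndarray:
    """Per-edge coefficient of variation across subjects (sample SD divided
    by the mean weight, zeros included). Edges absent in every subject are
    NaN; the diagonal is NaN."""
    stack = cohort.weight_stack()
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    np.fill_diagonal(cv, np.nan)
    return cv


@dataclass
class SimilarityReport:
    """Per-subject mean pairwise correlations for one edge class."""

    edge_class: str
    per_subject: np.ndarray
    n_pairs_skipped: int
    correlation: str = "pearson"

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_subject))

    @property
    def sem(self) -> float:
        vals = self.per_subject[~np.isnan(self.per_subject)]
        return float(stats.sem(vals)) if vals.size > 1 else np.nan


def pairwise_similarity(
    cohort: Cohort,
    edge_class: str = "whole",
    method: str = "pearson",
    union_only: bool = True,
) -> SimilarityReport:
    """Mean pairwise edge-weight correlation per subject.

    For each subject pair, the correlation is computed over edges of the
    requested class that are present in at least one of the two subjects
    (``union_only=True``, the default — structural zeros shared by the pair
    would otherwise inflate the correlation). Pairs with a zero-variance
    vector are skipped and logged.
    """
    if cohort.n_subjects < 3:
        raise ValueError("pairwise similarity needs at least 3 subjects")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    mask, iu, ju = _class_mask(cohort, edge_class)
    stack = cohort.weight_stack()[:, iu, ju][:, mask]
    n = cohort.n_subjects
    corr = np.full((n, n), np.nan)
    skipped = 0
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for a in range(n):
        for b in range(a + 1, n):
            x, y = stack[a], stack[b]
            if union_only:
                present = (x > 0) | (y > 0)
                x, y = x[present], y[present]
            if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
                skipped += 1
                logger.debug(
                    "skipping degenerate pair (%d, %d) in class %s", a, b, edge_class
                )
                continue
            r = fn(x, y)[0]
            corr[a, b] = corr[b, a] = r
    per_subject = np.nanmean(corr, axis=1)
    return SimilarityReport(edge_class, per_subject, skipped, method)


def group_compare_similarity(
    report_a: SimilarityReport, report_b: SimilarityReport
) -> pd.DataFrame:
    """Two-sample comparison of per-subject similarity values (t test or
    Mann-Whitney by normality, as for the AUC comparisons)."""
    key = f"similarity_{report_a.edge_class}"
    return compare_groups_auc(
        {key: report_a.per_subject}, {key: report_b.per_subject}
    )


@dataclass
class NoveltyReport:
    """Novel and preserved connections of a case cohort vs controls."""

    novel: pd.DataFrame  # columns: i, j, edge, case_count, control_count
    preserved: pd.DataFrame
    min_count: int
    n_cases: int
    n_controls: int


def discover_novel_edges(
    cases: Cohort,
    controls: Cohort,
    min_count: int = 2,
    consensus_fraction: float = 0.5,
) -> NoveltyReport:
    """Flag novel connections (present in >= ``min_count`` case subjects,
    absent from every control subject) and preserved connections (present
    in both cohorts' consensus connectomes). Presence is weight > 0 on
    unthresholded individual connectomes."""
    parc = cases.parcellation
    if parc.n_nodes != controls.parcellation.n_nodes:
        raise ValueError("cohorts must share a parcellation")
    n = parc.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    case_count = (cases.weight_stack() > 0).sum(axis=0)[iu, ju]
    control_count = (controls.weight_stack() > 0).sum(axis=0)[iu, ju]
    labels = parc.labels
    novel_mask = (case_count >= min_count) & (control_count == 0)
    novel = pd.DataFrame(
        {
            "i": iu[novel_mask],
            "j": ju[novel_mask],
            "edge": [
                f"{labels[a]}-{labels[b]}"
                for a, b in zip(iu[novel_mask], ju[novel_mask])
            ],
            "case_count": case_count[novel_mask],
            "control_count": control_count[novel_mask],
        }
    ).sort_values("case_count", ascending=False, ignore_index=True)

    cons_case = build_consensus(cases, consensus_fraction).weights[iu, ju] > 0
    cons_ctrl = build_consensus(controls, consensus_fraction).weights[iu, ju] > 0
    pres_mask = cons_case & cons_ctrl
    preserved = pd.DataFrame(
        {
            "i": iu[pres_mask],
            "j": ju[pres_mask],
            "edge": [
                f"{labels[a]}-{labels[b]}"
                for a, b in zip(iu[pres_mask], ju[pres_mask])
            ],
            "case_count": case_count[pres_mask],
            "control_count": control_count[pres_mask],
        }
    )
    return NoveltyReport(
        novel, preserved, min_count, cases.n_subjects, controls.n_subjects
    )
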
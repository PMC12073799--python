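"""Connectome construction from per-seed connectivity maps.

Mirrors the tractography-to-matrix rules of the study: a two-step
connection-retention criterion on per-seed voxel connectivity maps, mean-FA
edge weighting over suprathreshold voxels, in-silico callosotomy (deleting a
listed set of callosal edges), group consensus connectomes, and
inter/intrahemispheric edge classification.

The voxel path here works on small toy label volumes (NumPy arrays); real
tractography and atlas registration are out of scope. Step 2 of the
retention rule reuses the step-1 seed maps masked to the candidate pair —
a documented simplification of re-running pair-constrained streamline
generation — and requires the criterion to hold from both seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import Cohort, Connectome, Parcellation

#: Voxels with connectivity above this value contribute to the mean-FA
#: edge weight.
FA_TRACT_THRESHOLD = 1e-3


@dataclass
class SeedConnectivityMap:
    """Streamline-fraction map for one seed region.

    ``values``: voxelwise fraction of streamlines (>= 0) seeded from
    ``seed_region``; ``labels``: same-shape integer volume mapping voxels to
    region ids (0 = background, region ids are 1-based: region k at label
    k + 1); ``fa``: optional aligned FA volume.
    """

    seed_region: int
    values: np.ndarray
    labels: np.ndarray
    fa: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != self.labels.shape:
            raise ValueError("values and label volume shapes differ")
        if self.values.min() < 0:
            raise ValueError("connectivity values must be non-negative")
        if self.fa is not None:
            self.fa = np.asarray(self.fa, dtype=float)
            if self.fa.shape != self.values.shape:
                raise ValueError("FA volume shape differs from map")

    def region_mask(self, region: int) -> np.ndarray:
        return self.labels == region + 1

    def masked_to(self, regions: tuple[int, ...]) -> "SeedConnectivityMap":
        """Map restricted to the voxels of the given regions (pair mask)."""
        keep = np.isin(self.labels, [r + 1 for r in regions])
        return SeedConnectivityMap(
            self.seed_region, np.where(keep, self.values, 0.0), self.labels, self.fa
        )


def retain_connection(seed_map: SeedConnectivityMap, target_region: int) -> bool:
    """Retention criterion: the sum of connectivity values over the target
    region's voxels, divided by the region volume, is greater than zero —
    i.e. any nonzero streamline overlap with the target."""
    mask = seed_map.region_mask(target_region)
    volume = int(mask.sum())
    if volume == 0:
        raise ValueError(
            f"region {target_region} has zero volume in the label image"
        )
    return float(seed_map.values[mask].sum()) / volume > 0


def edge_weight_fa(
    seed_map: SeedConnectivityMap,
    fa_volume: np.ndarray | None = None,
    tract_threshold: float = FA_TRACT_THRESHOLD,
) -> float:
    """Mean FA over voxels with connectivity above ``tract_threshold``.

    Returns 0.0 (the absent-edge marker) when no voxel qualifies.
    """
    fa = seed_map.fa if fa_volume is None else np.asarray(fa_volume, dtype=float)
    if fa is None:
        raise ValueError("no FA volume available")
    if fa.shape != seed_map.values.shape:
        raise ValueError("FA volume shape differs from map")
    qualifying = seed_map.values > tract_threshold
    if not qualifying.any():
        return 0.0
    return float(fa[qualifying].mean())


def build_connectome(
    maps: dict[int, SeedConnectivityMap],
    parcellation: Parcellation,
    subject_id: str = "",
    condition: str = "",
) -> Connectome:
    """Two-step connectome construction.

    Step 1 proposes candidate region pairs: seeding from region i, the
    retention criterion must hold for target j. Step 2 confirms each
    candidate on pair-masked maps, required from both seeds. Confirmed
    edges are weighted by the mean FA over suprathreshold voxels of the
    combined (elementwise-max) pair map; output is symmetric.
    """
    n = parcellation.n_nodes
    missing = [r for r in range(n) if r not in maps]
    if missing:
        raise ValueError(f"missing seed maps for regions: {missing}")
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # step 1: candidate if either seeding direction overlaps
            if not (
                retain_connection(maps[i], j) or retain_connection(maps[j], i)
            ):
                continue
            # step 2: pair-constrained confirmation from both seeds
            mi = maps[i].masked_to((i, j))
            mj = maps[j].masked_to((i, j))
            if not (retain_connection(mi, j) and retain_connection(mj, i)):
                continue
            combined = SeedConnectivityMap(
                i,
                np.maximum(mi.values, mj.values),
                maps[i].labels,
                maps[i].fa,
            )
            W[i, j] = W[j, i] = edge_weight_fa(combined)
    return Connectome(parcellation, W, subject_id, condition)


def virtual_callosotomy(
    connectome: Connectome, cc_edge_list: list[tuple[int, int]]
) -> Connectome:
    """Zero the listed callosal edges; everything else is untouched."""
    W = connectome.weights.copy()
    for i, j in cc_edge_list:
        W[i, j] = W[j, i] = 0.0
    return Connectome(
        connectome.parcellation,
        W,
        connectome.subject_id,
        "virtual_callosotomy",
    )


def cortical_homotopic_edges(parcellation: Parcellation) -> list[tuple[int, int]]:
    """All cortical homotopic interhemispheric pairs — the default callosal
    edge list when no template metadata is available."""
    half = parcellation.n_nodes // 2
    return [
        (k, parcellation.homotopic_partner(k))
        for k in range(half)
        if parcellation.nodes[k].is_cortical
    ]


@dataclass
class ConsensusConnectome:
    """Group-level network: edges present in at least a stated fraction of
    subjects, weighted by the mean strength over the subjects carrying
    them."""

    connectome: Connectome
    support: np.ndarray  # per-edge carrier counts (n, n)
    min_fraction: float
    n_subjects: int

    @property
    def weights(self) -> np.ndarray:
        return self.connectome.weights

    @property
    def parcellation(self) -> Parcellation:
        return self.connectome.parcellation


def build_consensus(
    cohort: Cohort, min_fraction: float = 0.5, carrier_mean: bool = True
) -> ConsensusConnectome:
    """Consensus connectome of a cohort.

    An edge is kept iff it is present (weight > 0) in at least
    ``ceil(min_fraction * n)`` subjects ("present in half" at the default).
    Kept-edge weight is the mean over carriers (default) or over all
    subjects including zeros (``carrier_mean=False``).
    """
    if cohort.n_subjects < 2:
        raise ValueError("consensus requires at least 2 subjects")
    stack = cohort.weight_stack()
    support = (stack > 0).sum(axis=0)
    threshold = int(np.ceil(min_fraction * cohort.n_subjects))
    keep = support >= threshold
    with np.errstate(invalid="ignore"):
        if carrier_mean:
            mean = np.where(support > 0, stack.sum(axis=0) / np.maximum(support, 1), 0.0)
        else:
            mean = stack.mean(axis=0)
    W = np.where(keep, mean, 0.0)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2
    consensus = Connectome(
        cohort.parcellation, W, f"consensus_{cohort.condition}", cohort.condition
    )
    return ConsensusConnectome(consensus, np.where(keep, support, 0), min_fraction, cohort.n_subjects)


def classify_edge(parcellation: Parcellation, i: int, j: int) -> str:
    """'interhemispheric' if the nodes lie in opposite hemispheres, else
    'intrahemispheric'. Self-edges are undefined."""
    if i == j:
        raise ValueError("self-edges cannot be classified")
    hi = parcellation.nodes[i].hemisphere
    hj = parcellation.nodes[j].hemisphere
    return "interhemispheric" if hi != hj else "intrahemispheric"
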
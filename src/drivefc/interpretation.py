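"""Atlas-level interpretation of fitted models: binary region-pair
patterns, Jaccard distances, UPGMA clustering, and per-cluster common
edges annotated by canonical functional network.

Each participant's selected channel-pair edges are projected onto the
116-region AAL parcellation as a symmetric binary matrix; participants are
then clustered by the Jaccard distance between those matrices (UPGMA /
average linkage), and the edges shared by every member of a cluster are
read out with their (network, network) labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .connectivity import edge_to_pair

# The 116 region labels of the AAL parcellation, standard ordering
# (90 cerebral, 18 cerebellar hemispheric, 8 vermis).
AAL116: tuple[str, ...] = tuple(
    name
    for pair in [
        "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
        "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
        "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
        "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
        "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
        "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
        "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
        "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
        "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
        "Pallidum", "Thalamus", "Heschl", "Temporal_Sup",
        "Temporal_Pole_Sup", "Temporal_Mid", "Temporal_Pole_Mid",
        "Temporal_Inf", "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3",
        "Cerebelum_4_5", "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8",
        "Cerebelum_9", "Cerebelum_10",
    ]
    for name in (f"{pair}_L", f"{pair}_R")
) + tuple(
    f"Vermis_{v}" for v in ("1_2", "3", "4_5", "6", "7", "8", "9", "10")
)

assert len(AAL116) == 116

#: Canonical functional-network membership of the montage's AAL regions.
DEFAULT_NETWORKS: dict[str, str] = {
    "Frontal_Sup_L": "DAN", "Frontal_Sup_R": "DAN",
    "Parietal_Sup_L": "DAN", "Parietal_Sup_R": "DAN",
    "Frontal_Mid_L": "VAN", "Frontal_Mid_R": "VAN",
    "SupraMarginal_L": "VAN", "SupraMarginal_R": "VAN",
    "Frontal_Sup_Medial_L": "DMN", "Frontal_Sup_Medial_R": "DMN",
    "Angular_L": "DMN", "Angular_R": "DMN",
    "Precentral_L": "SMN", "Precentral_R": "SMN",
    "Postcentral_L": "SMN", "Postcentral_R": "SMN",
    "Frontal_Inf_Tri_L": "FPN", "Frontal_Inf_Tri_R": "FPN",
    "Parietal_Inf_L": "FPN", "Parietal_Inf_R": "FPN",
    "Insula_L": "SN", "Insula_R": "SN",
}


@dataclass
class EdgePattern:
    """Binary 116 x 116 region-pair selection matrix for one participant."""

    participant: str
    matrix: np.ndarray
    regions: tuple[str, ...] = AAL116

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.shape != (len(self.regions), len(self.regions)):
            raise ValueError("pattern shape must match the region list")
        if not np.array_equal(m, m.T):
            raise ValueError("pattern must be symmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("pattern entries must be 0/1")
        self.matrix = m.astype(np.uint8)

    def edge_set(self) -> frozenset[tuple[int, int]]:
        """Nonzero upper-triangle-plus-diagonal entries as (i, j), i <= j."""
        ii, jj = np.nonzero(np.triu(self.matrix))
        return frozenset(zip(ii.tolist(), jj.tolist()))

    def edge_names(self) -> set[tuple[str, str]]:
        return {(self.regions[i], self.regions[j]) for i, j in self.edge_set()}


def edges_to_region_matrix(
    selected_edges,
    montage: pd.DataFrame,
    participant: str = "",
    regions: tuple[str, ...] = AAL116,
) -> EdgePattern:
    """Project selected channel-pair edges onto the region parcellation.

    Each selected edge (channels i, j) sets the (region(i), region(j))
    entry and its transpose to 1; a pair mapping to one region sets the
    diagonal.

    Parameters
    ----------
    selected_edges : iterable of edge-vector indices
    montage : DataFrame with ``channel``, ``is_short`` and ``aal_region``
        columns; long-channel rows in channel order define the mapping.
    """
    long_rows = montage.loc[~montage["is_short"].astype(bool)]
    ch_regions = list(long_rows["aal_region"])
    region_idx = {name: k for k, name in enumerate(regions)}
    n_ch = len(ch_regions)
    for ch, reg in zip(long_rows["channel"], ch_regions):
        if reg not in region_idx:
            raise ValueError(f"channel {ch} has unknown region label {reg!r}")
    m = np.zeros((len(regions), len(regions)), dtype=np.uint8)
    for e in selected_edges:
        i, j = edge_to_pair(int(e), n_ch)
        a, b = region_idx[ch_regions[i]], region_idx[ch_regions[j]]
        m[a, b] = 1
        m[b, a] = 1
    return EdgePattern(participant=participant, matrix=m, regions=regions)


def jaccard_distance(a: EdgePattern, b: EdgePattern) -> float:
    """1 - |A & B| / |A | B| over the patterns' nonzero entry sets.

    Two empty patterns are defined as distance 0 (with a warning), so the
    metric stays total.
    """
    if a.regions != b.regions:
        raise ValueError("patterns use different region sets")
    sa, sb = a.edge_set(), b.edge_set()
    union = sa | sb
    if not union:
        warnings.warn("both edge patterns are empty; distance defined as 0")
        return 0.0
    return 1.0 - len(sa & sb) / len(union)


def pairwise_jaccard(patterns: list[EdgePattern]) -> np.ndarray:
    """Condensed pairwise Jaccard distance vector (scipy ordering)."""
    n = len(patterns)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            out.append(jaccard_distance(patterns[i], patterns[j]))
    return np.asarray(out)


@dataclass
class ClusterTree:
    """UPGMA merge tree over participants' edge patterns."""

    linkage: np.ndarray
    participants: list[str]
    assignments: np.ndarray
    n_clusters: int
    patterns: list[EdgePattern] = field(repr=False, default_factory=list)

    def members(self, cluster_id: int) -> list[int]:
        return np.flatnonzero(self.assignments == cluster_id).tolist()

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(set(self.assignments.tolist()))

    def plot_dendrogram(self, ax=None, **kwargs):
        """Dendrogram of the merge tree (Jaccard distance on the axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hierarchy.dendrogram(
            self.linkage, labels=self.participants, ax=ax, **kwargs
        )
        ax.set_ylabel("Jaccard distance")
        return ax


def upgma_cluster(
    patterns: list[EdgePattern],
    n_clusters: int | None = 5,
    height: float | None = None,
) -> ClusterTree:
    """Average-linkage (UPGMA) clustering of edge patterns.

    The tree is cut either at a requested cluster count (default 5) or at a
    Jaccard-distance threshold.  Input order fixes tie-breaking.
    """
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns to cluster")
    if n_clusters is not None and n_clusters > len(patterns):
        raise ValueError("more clusters requested than patterns")
    dist = pairwise_jaccard(patterns)
    Z = hierarchy.linkage(dist, method="average")
    if height is not None:
        assign = hierarchy.fcluster(Z, t=height, criterion="distance")
        k = len(set(assign))
    else:
        assign = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
        k = n_clusters
    return ClusterTree(
        linkage=Z,
        participants=[p.participant for p in patterns],
        assignments=np.asarray(assign),
        n_clusters=int(k),
        patterns=list(patterns),
    )


def cluster_common_edges(
    tree: ClusterTree,
    patterns: list[EdgePattern] | None = None,
    networks: dict[str, str] | None = None,
) -> dict[int, list[dict]]:
    """Edges shared by every member of each cluster, with network labels.

    Returns, per cluster id, a list of records
    ``{"regions": (r1, r2), "networks": (n1, n2)}`` sorted for
    reproducibility.  Regions without a network label are annotated
    "unassigned" with a warning.
    """
    patterns = patterns if patterns is not None else tree.patterns
    networks = DEFAULT_NETWORKS if networks is None else networks
    warned = False
    result: dict[int, list[dict]] = {}
    for cid in tree.cluster_ids:
        members = [patterns[i] for i in tree.members(cid)]
        common = members[0].edge_set()
        for p in members[1:]:
            common = common & p.edge_set()
        regions = members[0].regions
        records = []
        for i, j in sorted(common):
            r1, r2 = regions[i], regions[j]
            nets = []
            for r in (r1, r2):
                if r not in networks and not warned:
                    warnings.warn(f"region {r} has no network label")
                    warned = True
                nets.append(networks.get(r, "unassigned"))
            records.append(
                {"regions": (r1, r2), "networks": tuple(sorted(nets))}
            )
        result[cid] = records
    return result


def common_network_pairs(common: dict[int, list[dict]]) -> dict[int, set]:
    """Per-cluster set of (network, network) pairs among common edges."""
    return {
        cid: {rec["networks"] for rec in records}
        for cid, records in common.items()
    }
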
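"""Node-level graph metrics, epicenter selection, and the design matrix.

Nine vulnerability templates are computed per region and grouped into five
topological descriptors, each a proxy for a propagation mechanism:

* centrality (nodal stress): betweenness, closeness, weighted degree,
  clustering coefficient;
* segregation (trophic failure): inverse degree, inverse clustering;
* network proximity (trans-neuronal spread): weighted shortest-path distance
  to the disease epicenter;
* cortical proximity (diffusive spread): spatial distance to the epicenter;
* constant progression (uniform loss): a column of ones.

All metrics are computed on the full lateralized graph, averaged across
hemisphere pairs afterwards, and min-max scaled to [0, 1]. Distance-type
columns are inverted (1 - minmax distance) so proximity to the epicenter
means high vulnerability.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .atlas import RegionAtlas
from .cohort import ZScoreCohort
from .connectome import Connectome
from .errors import DataError

log = logging.getLogger(__name__)

METRIC_NAMES = (
    "betweenness",
    "closeness",
    "weighted_degree",
    "clustering",
    "inverse_degree",
    "inverse_clustering",
    "shortest_path",
    "spatial_distance",
    "constant",
)

DESCRIPTOR_NAMES = (
    "centrality",
    "segregation",
    "network_proximity",
    "cortical_proximity",
    "constant_progression",
)

#: metric -> descriptor grouping
METRIC_GROUPS = {
    "betweenness": "centrality",
    "closeness": "centrality",
    "weighted_degree": "centrality",
    "clustering": "centrality",
    "inverse_degree": "segregation",
    "inverse_clustering": "segregation",
    "shortest_path": "network_proximity",
    "spatial_distance": "cortical_proximity",
    "constant": "constant_progression",
}

#: metrics whose definition involves the epicenter (one extra fitted parameter)
EPICENTER_METRICS = ("shortest_path", "spatial_distance")

CONNECTIVITY_METRICS = METRIC_NAMES[:6]


def compute_node_metrics(conn: Connectome) -> pd.DataFrame:
    """Raw values of the six connectivity metrics on the lateralized graph.

    Path-based metrics use travel lengths 1/weight; clustering is the weighted
    (geometric-mean) clustering coefficient. Inverse metrics are guarded: a
    node with zero degree or clustering gets the post-hoc column maximum of
    the inverse metric, with a warning.
    """
    g = conn.to_graph()
    n = conn.n_regions
    degree = conn.weights.sum(axis=1)
    betweenness = np.array(
        [nx.betweenness_centrality(g, weight="length", normalized=False)[i] for i in range(n)]
    )
    closeness = np.array([nx.closeness_centrality(g, distance="length")[i] for i in range(n)])
    clustering_map = nx.clustering(g, weight="weight")
    clustering = np.array([clustering_map[i] for i in range(n)])

    def _guarded_inverse(values, name):
        out = np.full_like(values, np.nan, dtype=float)
        ok = values > 0
        out[ok] = 1.0 / values[ok]
        if not ok.all():
            if not ok.any():
                log.warning("all nodes have zero %s; inverse metric degenerates "
                            "to a zero column", name)
                out[:] = 0.0
                return out
            log.warning(
                "%d node(s) with zero %s; inverse set to column max", int((~ok).sum()), name
            )
            out[~ok] = out[ok].max()
        return out

    table = pd.DataFrame(
        {
            "betweenness": betweenness,
            "closeness": closeness,
            "weighted_degree": degree,
            "clustering": clustering,
            "inverse_degree": _guarded_inverse(degree, "degree"),
            "inverse_clustering": _guarded_inverse(clustering, "clustering"),
        }
    )
    if conn.atlas is not None:
        table.index = list(conn.atlas.names)
    if not np.all(np.isfinite(table.to_numpy())):
        raise DataError("non-finite metric value")
    return table


def select_epicenter(z: ZScoreCohort):
    """Per-subject and cohort epicenters from last-visit atrophy z-scores.

    The subject epicenter is the most atrophied (highest z) bilateral region
    at the last follow-up; the cohort epicenter is the modal subject
    epicenter, ties broken toward the lowest region index with a warning.

    Returns
    -------
    (subject_epicenters, cohort_epicenter) : (pd.Series, str)
    """
    regions = list(z.volumes.columns)
    picks = {}
    for s in z.subjects:
        last = z.volumes.loc[s].iloc[-1]
        if last.isna().all():
            log.warning("subject %r has all-NaN last visit; skipped", s)
            continue
        picks[s] = last.idxmax()
    if not picks:
        raise DataError("no subject with a usable last visit")
    series = pd.Series(picks, name="epicenter")
    counts = series.value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index, key=regions.index)
    if len(winners) > 1:
        log.warning("cohort epicenter tie between %s; taking lowest index", winners)
    return series, winners[0]


@dataclass
class DesignMatrix:
    """Bilateral regions x 9 vulnerability matrix in [0, 1].

    ``sigma`` rows are pair labels in atlas order; every non-constant column
    spans [0, 1] exactly, the constant column is all ones.
    """

    sigma: pd.DataFrame
    epicenter: str
    rank_deficient: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if tuple(self.sigma.columns) != METRIC_NAMES:
            raise DataError("design matrix columns must be the nine metrics in order")
        vals = self.sigma.to_numpy(float)
        if not np.allclose(vals[:, -1], 1.0):
            raise DataError("constant column must be all ones")

    @property
    def values(self) -> np.ndarray:
        return self.sigma.to_numpy(float)

    @property
    def regions(self) -> list:
        return list(self.sigma.index)

    def to_csv(self, path) -> None:
        self.sigma.rename_axis("region").to_csv(path)


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = np.min(col), np.max(col)
    if hi - lo <= 0:
        return np.zeros_like(col)
    return (col - lo) / (hi - lo)


def build_design_matrix(
    metrics: pd.DataFrame,
    conn: Connectome,
    dist: np.ndarray,
    epicenter: str,
    atlas: RegionAtlas,
    invert_proximity: bool = True,
) -> DesignMatrix:
    """Assemble the normalized design matrix for a given epicenter.

    Epicenter distances are computed on the lateralized graph (shortest-path
    lengths 1/weight, multi-source over both members of the epicenter pair),
    then all eight non-constant columns are hemisphere-averaged, distance-type
    columns inverted to proximities (unless ``invert_proximity`` is off), each
    column min-max scaled, and the constant column appended.
    """
    if epicenter not in atlas.bilateral_labels:
        raise DataError(f"epicenter {epicenter!r} is not a bilateral label")
    sources = atlas.members_of(epicenter)
    g = conn.to_graph()
    lengths = nx.multi_source_dijkstra_path_length(g, set(sources), weight="length")
    net_dist = np.full(atlas.n_regions, np.inf)
    for node, d in lengths.items():
        net_dist[node] = d
    unreachable = ~np.isfinite(net_dist)
    if unreachable.any():
        log.warning(
            "%d node(s) unreachable from epicenter; network proximity set to 0",
            int(unreachable.sum()),
        )
    spa_dist = np.asarray(dist, float)[:, sources].min(axis=1)

    lateral = metrics.copy()
    lateral["shortest_path"] = net_dist
    lateral["spatial_distance"] = spa_dist
    lateral.index = pd.Index(list(atlas.pair_id), name="pair")
    bilateral = lateral.groupby(level=0, sort=False).mean()
    bilateral = bilateral.loc[atlas.bilateral_labels]

    out = {}
    for name in METRIC_NAMES[:-1]:
        col = bilateral[name].to_numpy(float)
        if name in EPICENTER_METRICS:
            bad = ~np.isfinite(col)
            col = np.where(bad, np.nanmax(np.where(bad, np.nan, col)), col)
            col = _minmax(col)
            if invert_proximity:
                col = 1.0 - col
            col[bad] = 0.0 if invert_proximity else 1.0
            col = _minmax(col)
        else:
            col = _minmax(col)
        out[name] = col
    out["constant"] = np.ones(len(bilateral))
    sigma = pd.DataFrame(out, index=bilateral.index)
    rank = np.linalg.matrix_rank(sigma.to_numpy())
    deficient = rank < sigma.shape[1]
    if deficient:
        log.warning("design matrix is rank deficient (rank %d < 9)", rank)
    return DesignMatrix(
        sigma=sigma,
        epicenter=epicenter,
        rank_deficient=deficient,
        provenance={"invert_proximity": invert_proximity},
    )


def metric_table(design: DesignMatrix) -> pd.DataFrame:
    """Export-friendly table: scaled metric values under descriptor grouping."""
    scaled = design.sigma.copy()
    scaled.columns = pd.MultiIndex.from_tuples(
        [(METRIC_GROUPS[m], m) for m in scaled.columns], names=["descriptor", "metric"]
    )
    return scaled
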
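"""Structural connectomes: loading, averaging, normalization, spatial distances.

A connectome is a symmetric non-negative weight matrix over the atlas regions
with zero diagonal and weights scaled to [0, 1]. Cohort-average connectomes
are built by element-wise averaging of subject matrices followed by global
max-scaling, which preserves relative connection strengths.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .atlas import RegionAtlas
from .errors import DataError

_TOL = 1e-9


@dataclass
class Connectome:
    """Symmetric [0, 1] weight matrix, optionally tied to an atlas."""

    weights: np.ndarray
    atlas: RegionAtlas | None = field(default=None, repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DataError("connectome weights must be a square matrix")
        if not np.allclose(w, w.T, atol=_TOL):
            raise DataError("connectome weights must be symmetric")
        if np.abs(np.diag(w)).max(initial=0.0) > _TOL:
            raise DataError("connectome diagonal must be zero")
        if w.min(initial=0.0) < -_TOL or w.max(initial=0.0) > 1 + _TOL:
            raise DataError("connectome weights must lie in [0, 1]")
        if self.atlas is not None and w.shape[0] != self.atlas.n_regions:
            raise DataError("connectome size does not match atlas")
        self.weights = np.clip((w + w.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.weights, 0.0)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def to_graph(self) -> nx.Graph:
        """Weighted graph; each positive-weight edge also carries a travel
        length = 1/weight, the conversion used by path-based metrics."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            w = float(self.weights[i, j])
            g.add_edge(i, j, weight=w, length=1.0 / w)
        return g

    def to_graphml(self, path) -> None:
        g = self.to_graph()
        if self.atlas is not None:
            nx.relabel_nodes(g, dict(enumerate(self.atlas.names)), copy=False)
        nx.write_graphml(g, path)


def average_connectomes(matrices, atlas: RegionAtlas | None = None,
                        normalize: str = "after") -> Connectome:
    """Element-wise mean of subject matrices, max-scaled to [0, 1].

    ``normalize='after'`` (default) rescales the averaged matrix by its global
    maximum; ``'per_subject'`` max-scales each matrix before averaging.
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise DataError("no matrices given")
    shape = mats[0].shape
    for m in mats:
        if m.shape != shape:
            raise DataError(f"shape mismatch: {m.shape} vs {shape}")
        if m.min() < 0:
            raise DataError("negative connectome entry")
    if normalize == "per_subject":
        mats = [m / m.max() if m.max() > 0 else m for m in mats]
    elif normalize != "after":
        raise DataError(f"unknown normalize mode {normalize!r}")
    mean = np.mean(mats, axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    top = mean.max()
    if top > 0:
        mean = mean / top
    return Connectome(mean, atlas=atlas)


def read_adjacency(path, atlas: RegionAtlas | None = None, sep=None) -> np.ndarray:
    """Read a dense delimited adjacency matrix.

    A header row of region names is optional; when present and an atlas is
    given, names are validated and rows/columns reordered to atlas order.
    ``.npy`` files are loaded directly.
    """
    if str(path).endswith(".npy"):
        return np.load(path)
    with open(path) as fh:
        first = fh.readline()
    delim = sep or ("," if "," in first else None)
    tokens = first.strip().split(delim)

    def _is_number(tok):
        try:
            float(tok)
            return True
        except ValueError:
            return False

    if all(_is_number(t) for t in tokens if t):
        return np.loadtxt(path, delimiter=delim)
    df = pd.read_csv(path, sep=delim or r"\s+", engine="python")
    names = [str(c) for c in df.columns]
    if atlas is not None:
        if set(names) != set(atlas.names):
            raise DataError("adjacency header names do not match atlas")
        df = df[list(atlas.names)]
    return df.to_numpy(float)


def write_adjacency(conn: Connectome, path) -> None:
    names = list(conn.atlas.names) if conn.atlas is not None else None
    pd.DataFrame(conn.weights, columns=names).to_csv(path, index=False, header=names is not None)


def spatial_distance_matrix(atlas: RegionAtlas) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between region barycenters.

    A straight-line approximation of inter-barycenter cortical distance; a
    user-supplied distance matrix can stand in wherever this one is used.
    """
    d = cdist(atlas.coords, atlas.coords)
    np.fill_diagonal(d, 0.0)
    return d
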
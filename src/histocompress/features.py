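"""Nuclear-architecture features and their stability under compression.

From a nuclear segmentation (label mask + centroids) this module computes
77 first-order summary statistics over five families describing tissue
architecture:

* ``voronoi`` (12): per-cell {area, perimeter, chord length} of the Voronoi
  tessellation clipped to the image bounds, each summarized by
  {mean, std, min/max, disorder};
* ``delaunay`` (8): per-triangle {side length, area} of the Delaunay
  triangulation, same four summaries;
* ``mst`` (4): edge lengths of the Euclidean minimum spanning tree;
* ``nuclear`` (27): per-object {area, eccentricity, compactness 4piA/P^2}
  (4 summaries each), k-nearest-neighbor distances for k in {1,3,5,7}
  ({mean, std, disorder} each), plus {density per 10^4 px^2, object count,
  occupied area fraction};
* ``subgraph`` (26): cell-cluster graph measures — components of the
  centroid graph linked under ``link_radius`` with >= 3 nodes — per-cluster
  {node count, edge count, average degree, hop diameter, convex-hull area,
  nearest inter-cluster distance} (4 summaries each) plus
  {cluster count, clustered-cell fraction}.

The disorder statistic is 1 - 1/(1 + sigma/mu), a bounded transform of the
coefficient of variation. Standard deviations are population (ddof=0).
Statistics whose denominator vanishes (mu = 0 for disorder, max = 0 for
min/max) or whose inputs are unavailable (e.g. 7-NN with < 8 objects) are
recorded as missing (NaN), never as errors.

Stability across a compression ladder is the per-feature absolute change
from the lossless level, averaged over images, then normalized per feature
by its maximum over levels — yielding the (0,1) relative-difference matrix
plotted as a level x feature heat map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial.distance import cdist
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from shapely.geometry import MultiPoint, box
from shapely.ops import voronoi_diagram
from skimage.measure import regionprops

from .errors import DegenerateGeometryError, ParameterError

__all__ = [
    "FeatureTable", "StabilityMatrix", "FEATURE_NAMES", "FEATURE_FAMILIES",
    "FAMILY_COUNTS", "label_objects", "graph_measures", "nuclear_measures",
    "subgraph_measures", "summarize", "compute_feature_table",
    "stability_matrix",
]

_FULL = ("mean", "std", "minmax", "disorder")
_KNN_STATS = ("mean", "std", "disorder")
_KNN_KS = (1, 3, 5, 7)

_LEDGER: list[tuple[str, str, tuple[str, ...]]] = (
    [("voronoi", m, _FULL) for m in ("area", "perimeter", "chord")]
    + [("delaunay", m, _FULL) for m in ("side_length", "triangle_area")]
    + [("mst", "edge_length", _FULL)]
    + [("nuclear", m, _FULL) for m in ("area", "eccentricity", "compactness")]
    + [("nuclear", f"knn_{k}", _KNN_STATS) for k in _KNN_KS]
    + [("nuclear", m, ("value",)) for m in ("density", "count", "area_fraction")]
    + [("subgraph", m, _FULL)
       for m in ("nodes", "edges", "degree", "diameter", "hull_area",
                 "intercluster_distance")]
    + [("subgraph", m, ("value",)) for m in ("cluster_count", "clustered_fraction")]
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{fam}.{meas}.{st}" if st != "value" else f"{fam}.{meas}"
    for fam, meas, stats in _LEDGER for st in stats
)
FEATURE_FAMILIES: tuple[str, ...] = tuple(
    fam for fam, _, stats in _LEDGER for _ in stats
)
FAMILY_COUNTS = {
    "voronoi": 12, "delaunay": 8, "mst": 4, "nuclear": 27, "subgraph": 26,
}
assert len(FEATURE_NAMES) == 77
assert {f: FEATURE_FAMILIES.count(f) for f in FAMILY_COUNTS} == FAMILY_COUNTS


@dataclass
class FeatureTable:
    """77 named, family-tagged summary statistics for one image."""

    names: tuple[str, ...]
    families: tuple[str, ...]
    values: np.ndarray  # (77,) float, NaN = missing

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


@dataclass
class StabilityMatrix:
    """Level x feature relative differences vs the lossless level."""

    levels: np.ndarray        # achieved/nominal PSNR per row, ascending
    names: tuple[str, ...]
    families: tuple[str, ...]
    rel_diff: np.ndarray      # levels x 77 in [0, 1]
    raw_diff: np.ndarray      # same shape, unnormalized mean |delta|

    def to_dataframe(self, which: str = "rel") -> pd.DataFrame:
        data = self.rel_diff if which == "rel" else self.raw_diff
        return pd.DataFrame(data, index=self.levels, columns=list(self.names))


def label_objects(mask: np.ndarray, min_area: int = 1):
    """8-connected components of a binary mask, small ones removed.

    Returns ``(label_mask, centroids)`` with contiguous ids 1..K and area
    centroids as an (K, 2) array of (row, col).
    """
    if min_area < 1:
        raise ParameterError("min_area must be >= 1")
    mask = np.asarray(mask, bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels.astype(np.int32), np.empty((0, 2))
    areas = ndimage.sum_labels(np.ones_like(mask, dtype=float), labels,
                               index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    labels = remap[labels]
    if len(keep) == 0:
        return labels, np.empty((0, 2))
    cents = ndimage.center_of_mass(mask, labels, index=np.arange(1, len(keep) + 1))
    return labels, np.asarray(cents, float)


def _voronoi_measures(pts: np.ndarray, bounds) -> dict:
    # shapely's Voronoi regions are unbounded at the hull; clipping every
    # region to the image rectangle makes all cells finite
    clip = box(0.0, 0.0, float(bounds[1]), float(bounds[0]))  # (x, y) order
    cells = voronoi_diagram(MultiPoint([(x, y) for y, x in pts]), envelope=clip)
    areas, perims, chords = [], [], []
    for cell in cells.geoms:
        poly = cell.intersection(clip)
        if poly.is_empty or poly.geom_type != "Polygon":
            continue
        areas.append(poly.area)
        perims.append(poly.length)
        verts = np.asarray(poly.exterior.coords)[:-1]
        if len(verts) >= 2:
            d = cdist(verts, verts)
            chords.extend(d[np.triu_indices(len(verts), k=1)].tolist())
    return {"area": areas, "perimeter": perims, "chord": chords}


def _delaunay_measures(pts: np.ndarray):
    tri = Delaunay(pts)
    sides, areas = [], []
    edges = set()
    for simplex in tri.simplices:
        p = pts[simplex]
        for i, j in ((0, 1), (1, 2), (0, 2)):
            sides.append(float(np.hypot(*(p[i] - p[j]))))
            edges.add((min(simplex[i], simplex[j]), max(simplex[i], simplex[j])))
        u, v = p[1] - p[0], p[2] - p[0]
        areas.append(0.5 * abs(u[0] * v[1] - u[1] * v[0]))
    return {"side_length": sides, "triangle_area": areas}, edges


def _mst_edge_lengths(pts: np.ndarray, delaunay_edges=None) -> list[float]:
    n = len(pts)
    if delaunay_edges:
        ii, jj = zip(*delaunay_edges)
        ii, jj = np.asarray(ii), np.asarray(jj)
    else:  # degenerate (e.g. collinear) layouts: fall back to the complete graph
        ii, jj = np.triu_indices(n, k=1)
    w = np.hypot(pts[ii, 0] - pts[jj, 0], pts[ii, 1] - pts[jj, 1])
    # zero-weight edges (coincident points) must survive sparsification
    graph = coo_matrix((w + 1e-12, (ii, jj)), shape=(n, n))
    mst = minimum_spanning_tree(graph)
    return np.maximum(mst.data - 1e-12, 0.0).tolist()


def graph_measures(centroids: np.ndarray, bounds) -> tuple[dict, list[str]]:
    """Raw Voronoi / Delaunay / MST measure lists over cell centroids.

    *bounds* is the ``(height, width)`` of the image; Voronoi cells are
    clipped to it. Families that are degenerate for the given points
    (Voronoi/Delaunay need >= 4 points in general position; MST needs >= 2)
    are skipped and listed in the second return value. If nothing is
    computable a :class:`DegenerateGeometryError` is raised naming all
    skipped families.
    """
    pts = np.asarray(centroids, float).reshape(-1, 2)
    measures: dict[str, dict[str, list[float]]] = {}
    skipped: list[str] = []

    delaunay_edges = None
    if len(pts) >= 4:
        try:
            measures["delaunay"], delaunay_edges = _delaunay_measures(pts)
        except Exception:  # noqa: BLE001 — qhull degeneracies
            skipped.append("delaunay")
        try:
            measures["voronoi"] = _voronoi_measures(pts, bounds)
        except Exception:  # noqa: BLE001
            skipped.append("voronoi")
    else:
        skipped += ["voronoi", "delaunay"]

    if len(pts) >= 2:
        measures["mst"] = {"edge_length": _mst_edge_lengths(pts, delaunay_edges)}
    else:
        skipped.append("mst")

    if not measures:
        raise DegenerateGeometryError(
            f"no spatial-graph family computable for {len(pts)} point(s); "
            f"skipped: {', '.join(skipped)}", skipped=skipped)
    return measures, skipped


def nuclear_measures(label_mask: np.ndarray, centroids: np.ndarray) -> dict:
    """Per-object morphology and nearest-neighbor spacing measures.

    Compactness is 4*pi*A/P^2 (1 for a disk). k-NN distances for k with
    too few objects are returned as empty lists (missing downstream).
    """
    label_mask = np.asarray(label_mask)
    pts = np.asarray(centroids, float).reshape(-1, 2)
    n = len(pts)
    if n == 0 or label_mask.max() == 0:
        raise DegenerateGeometryError("nuclear measures need >= 1 object")
    areas, eccs, compact = [], [], []
    for rp in regionprops(label_mask):
        areas.append(float(rp.area))
        eccs.append(float(rp.eccentricity))
        per = rp.perimeter
        compact.append(4.0 * math.pi * rp.area / per**2 if per > 0 else np.nan)
    out = {"area": areas, "eccentricity": eccs, "compactness": compact}
    tree = cKDTree(pts)
    kmax = max(k for k in _KNN_KS if k < n) if n > 1 else 0
    if kmax:
        dist, _ = tree.query(pts, k=kmax + 1)
    for k in _KNN_KS:
        out[f"knn_{k}"] = dist[:, k].tolist() if k < n else []
    h, w = label_mask.shape
    out["density"] = n / (h * w) * 1e4
    out["count"] = float(n)
    out["area_fraction"] = float(np.count_nonzero(label_mask) / (h * w))
    return out


def subgraph_measures(centroids: np.ndarray, link_radius: float) -> dict:
    """Cell-cluster graph measures.

    Centroid pairs within ``link_radius`` are linked; connected components
    with >= 3 nodes are clusters. Inter-cluster distance is the nearest
    node-to-node distance to any other cluster (missing with < 2 clusters).
    """
    if link_radius <= 0:
        raise ParameterError("link_radius must be positive")
    pts = np.asarray(centroids, float).reshape(-1, 2)
    out = {k: [] for k in ("nodes", "edges", "degree", "diameter",
                           "hull_area", "intercluster_distance")}
    out["cluster_count"] = 0.0
    out["clustered_fraction"] = 0.0 if len(pts) else np.nan
    if len(pts) < 2:
        return out
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    g.add_edges_from(cKDTree(pts).query_pairs(link_radius))
    clusters = [c for c in nx.connected_components(g) if len(c) >= 3]
    out["cluster_count"] = float(len(clusters))
    out["clustered_fraction"] = sum(len(c) for c in clusters) / len(pts)
    members = [np.array(sorted(c)) for c in clusters]
    for idx, c in zip(members, clusters):
        sub = g.subgraph(c)
        v, e = sub.number_of_nodes(), sub.number_of_edges()
        out["nodes"].append(float(v))
        out["edges"].append(float(e))
        out["degree"].append(2.0 * e / v)
        out["diameter"].append(float(nx.diameter(sub)))
        out["hull_area"].append(MultiPoint(pts[idx]).convex_hull.area)
    if len(clusters) >= 2:
        for i, mi in enumerate(members):
            others = np.concatenate([m for j, m in enumerate(members) if j != i])
            out["intercluster_distance"].append(
                float(cdist(pts[mi], pts[others]).min()))
    return out


def summarize(values, stats=_FULL) -> dict[str, float]:
    """First-order summaries of a raw measure list.

    ``minmax`` is min/max (missing when max = 0); ``disorder`` is
    1 - 1/(1 + sigma/mu) (missing when mu = 0). An empty input yields all
    summaries missing (NaN).
    """
    v = np.asarray([x for x in np.ravel(values) if np.isfinite(x)], float)
    out: dict[str, float] = {}
    for st in stats:
        if len(v) == 0:
            out[st] = np.nan
            continue
        mu = float(v.mean())
        sd = float(v.std())  # population
        if st == "mean":
            out[st] = mu
        elif st == "std":
            out[st] = sd
        elif st == "minmax":
            mx = float(v.max())
            out[st] = float(v.min()) / mx if mx != 0 else np.nan
        elif st == "disorder":
            out[st] = 1.0 - 1.0 / (1.0 + sd / mu) if mu != 0 else np.nan
        else:
            raise ParameterError(f"unknown statistic {st!r}")
    return out


def compute_feature_table(label_mask: np.ndarray, centroids: np.ndarray,
                          link_radius: float) -> FeatureTable:
    """Assemble the full 77-statistic table for one segmented image.

    Families that cannot be computed (too few objects) contribute missing
    values rather than errors, so tables remain comparable across a
    compression ladder even when heavy compression destroys the
    segmentation.
    """
    pts = np.asarray(centroids, float).reshape(-1, 2)
    raw: dict[str, dict] = {f: {} for f in FAMILY_COUNTS}
    try:
        gm, _ = graph_measures(pts, bounds=np.asarray(label_mask).shape)
        for fam in ("voronoi", "delaunay", "mst"):
            raw[fam] = gm.get(fam, {})
    except DegenerateGeometryError:
        pass
    try:
        raw["nuclear"] = nuclear_measures(label_mask, pts)
    except DegenerateGeometryError:
        pass
    raw["subgraph"] = subgraph_measures(pts, link_radius)

    values = []
    for fam, meas, stats in _LEDGER:
        if stats == ("value",):
            values.append(float(raw[fam].get(meas, np.nan)))
        else:
            summ = summarize(raw[fam].get(meas, []), stats)
            values.extend(summ[st] for st in stats)
    return FeatureTable(names=FEATURE_NAMES, families=FEATURE_FAMILIES,
                        values=np.asarray(values, float))


def stability_matrix(tables: dict[float, list[FeatureTable]],
                     lossless_level: float) -> StabilityMatrix:
    """Relative-difference matrix of features across compression levels.

    ``raw_diff[l, j]`` is |f_l,j - f_lossless,j| averaged over images
    (missing pairs ignored); ``rel_diff`` normalizes each feature column by
    its maximum over levels (0/0 -> 0), so every nonzero column peaks at
    exactly 1 and the lossless row is identically 0.
    """
    if lossless_level not in tables:
        raise ParameterError("lossless level missing from tables")
    levels = sorted(tables)
    ref_names = tables[levels[0]][0].names
    for lv in levels:
        for t in tables[lv]:
            if t.names != ref_names:
                raise ParameterError("inconsistent feature names across tables")
    base = np.stack([t.values for t in tables[lossless_level]])  # images x 77
    raw = np.zeros((len(levels), len(ref_names)))
    for i, lv in enumerate(levels):
        vals = np.stack([t.values for t in tables[lv]])
        if vals.shape[0] != base.shape[0]:
            raise ParameterError("unequal image counts across levels")
        diff = np.abs(vals - base)
        all_nan = np.all(np.isnan(diff), axis=0)
        diff = np.where(np.isnan(diff), 0.0, diff)
        counts = np.maximum((~np.isnan(np.abs(vals - base))).sum(axis=0), 1)
        raw[i] = np.where(all_nan, 0.0, diff.sum(axis=0) / counts)
    colmax = raw.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(colmax > 0, raw / np.where(colmax > 0, colmax, 1.0), 0.0)
    fams = tables[levels[0]][0].families
    return StabilityMatrix(levels=np.asarray(levels, float), names=ref_names,
                           families=fams, rel_diff=rel, raw_diff=raw)
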
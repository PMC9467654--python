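"""Cell-adjacency graphs, interface extraction and position classification.

All measurements use 4-connectivity: two cells are adjacent iff some pixel of
one is 4-adjacent to some pixel of the other, and an interface is the ordered
set of shared pixel *faces* between them.  Interface length is the face count
times the pixel size — a Manhattan measure that slightly overestimates
oblique boundaries but is unambiguous and additive (the sum of a cell's
interface lengths equals its internal 4-connected perimeter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    AdjacencyError,
    AxisInferenceError,
    ClassificationError,
    EmptyInputError,
)
from .image import CellMap, PHLOEM_TYPES, VASCULAR_TYPES

# 4-neighbourhood offsets (row, col)
_OFFSETS = ((0, 1), (1, 0), (0, -1), (-1, 0))


@dataclass
class Interface:
    """Shared boundary between two labelled cells.

    ``faces`` has shape (n, 4): each row is ``(ra, ca, rb, cb)`` where pixel
    ``(ra, ca)`` belongs to ``cell_a`` and ``(rb, cb)`` to ``cell_b``; the two
    pixels are 4-adjacent and the face between them is part of the boundary.
    Faces are ordered along the boundary polyline.  ``ingrowth_mask`` is one
    boolean per face, filled by the ingrowth module (or by the synthetic
    generator as ground truth).
    """

    cell_a: int
    cell_b: int
    faces: np.ndarray
    pixel_size: float
    ingrowth_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell_a >= self.cell_b:
            raise ValueError("canonical ordering requires cell_a < cell_b")
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 4)
        if len(self.faces) == 0:
            raise AdjacencyError(f"cells {self.cell_a} and {self.cell_b} share no faces")
        if self.ingrowth_mask is None:
            self.ingrowth_mask = np.zeros(len(self.faces), dtype=bool)
        self.ingrowth_mask = np.asarray(self.ingrowth_mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.faces)

    @property
    def length(self) -> float:
        """Interface length in micrometres."""
        return len(self.faces) * self.pixel_size

    @property
    def covered_length(self) -> float:
        """Length of the ingrowth-covered part, in micrometres."""
        return int(self.ingrowth_mask.sum()) * self.pixel_size

    @property
    def pair(self) -> tuple[int, int]:
        return (self.cell_a, self.cell_b)

    def other(self, cell: int) -> int:
        if cell == self.cell_a:
            return self.cell_b
        if cell == self.cell_b:
            return self.cell_a
        raise KeyError(f"cell {cell} not part of interface {self.pair}")

    def side_pixels(self, cell: int) -> np.ndarray:
        """Boundary pixels of this interface on the given cell's side, (n, 2)."""
        if cell == self.cell_a:
            return self.faces[:, :2]
        if cell == self.cell_b:
            return self.faces[:, 2:]
        raise KeyError(f"cell {cell} not part of interface {self.pair}")

    def inward_normals(self, cell: int) -> np.ndarray:
        """Per-face unit steps pointing from the boundary into ``cell``."""
        d = self.faces[:, :2] - self.faces[:, 2:]
        return d if cell == self.cell_a else -d


@dataclass
class PositionClass:
    """Abaxial / middle / adaxial position of a cell within the vein.

    ``hops_to_abaxial_BS`` / ``hops_to_adaxial_BS`` are graph distances (in
    cell hops) to the nearest bundle-sheath cell of the respective half;
    ``None`` when unreachable.
    """

    value: str
    hops_to_abaxial_BS: int | None
    hops_to_adaxial_BS: int | None

    def __post_init__(self) -> None:
        if self.value not in ("abaxial", "middle", "adaxial"):
            raise ValueError(f"invalid position class {self.value!r}")


def build_adjacency(cmap: CellMap) -> nx.Graph:
    """Cell-adjacency graph: nodes are labels, edges join 4-adjacent cells."""
    lab = cmap.labels
    ids = cmap.cell_ids
    if not ids:
        raise EmptyInputError("label map contains no cells")
    g = nx.Graph()
    g.add_nodes_from(ids)
    # horizontal and vertical neighbour pairs
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        sel = (a != b) & (a > 0) & (b > 0)
        pairs = np.stack([a[sel], b[sel]], axis=1)
        if pairs.size:
            lo = pairs.min(axis=1)
            hi = pairs.max(axis=1)
            g.add_edges_from(np.unique(np.stack([lo, hi], axis=1), axis=0))
    return g


def _face_array(cmap: CellMap, a: int, b: int) -> np.ndarray:
    """All faces between cells a and b, unordered, as (n, 4) rows (pa, pb)."""
    lab = cmap.labels
    rows = []
    for dr, dc in ((0, 1), (1, 0)):
        s_a = lab[: lab.shape[0] - dr, : lab.shape[1] - dc]
        s_b = lab[dr:, dc:]
        for x, y in ((a, b), (b, a)):
            sel = (s_a == x) & (s_b == y)
            rr, cc = np.nonzero(sel)
            if rr.size == 0:
                continue
            pa = np.stack([rr, cc], axis=1)
            pb = pa + (dr, dc)
            rows.append(np.hstack([pa, pb]) if x == a else np.hstack([pb, pa]))
    if not rows:
        return np.empty((0, 4), dtype=np.int64)
    return np.vstack(rows).astype(np.int64)


def _order_faces(faces: np.ndarray) -> np.ndarray:
    """Order faces along the boundary polyline (see :func:`face_order`)."""
    return faces[face_order(faces)]


def face_order(faces: np.ndarray) -> np.ndarray:
    """Permutation ordering faces along the boundary polyline.

    Faces are chained by midpoint proximity (two consecutive faces share a
    pixel corner, so their midpoints are at most 1 pixel apart); the walk
    starts from an end of the chain (anywhere on a closed cycle).
    Deterministic: ties broken lexicographically.
    """
    n = len(faces)
    if n <= 2:
        return np.lexsort((faces[:, 1] + faces[:, 3], faces[:, 0] + faces[:, 2]))
    mid = (faces[:, :2] + faces[:, 2:]) / 2.0
    d2 = ((mid[:, None, :] - mid[None, :, :]) ** 2).sum(axis=2)
    adj = (d2 <= 1.02) & ~np.eye(n, dtype=bool)
    deg = adj.sum(axis=1)
    lex = np.lexsort((mid[:, 1], mid[:, 0]))
    # start at a chain end if one exists, else at the lexicographic minimum
    ends = [i for i in lex if deg[i] <= 1]
    start = ends[0] if ends else lex[0]
    visited = np.zeros(n, dtype=bool)
    order: list[int] = []
    stack = [start]
    while stack:
        i = stack.pop()
        if visited[i]:
            continue
        visited[i] = True
        order.append(i)
        nbrs = [j for j in np.nonzero(adj[i])[0] if not visited[j]]
        # nearest (then lexicographic) neighbour continues the chain; push
        # farther ones first so the nearest is popped next
        nbrs.sort(key=lambda j: (d2[i, j], mid[j, 0], mid[j, 1]), reverse=True)
        stack.extend(nbrs)
    if not visited.all():  # disconnected boundary: append remaining chains
        for i in lex:
            if not visited[i]:
                visited[i] = True
                order.append(i)
    return np.array(order)


def extract_interface(cmap: CellMap, a: int, b: int) -> Interface:
    """Extract the ordered interface between two adjacent cells.

    Raises :class:`AdjacencyError` if the cells share no pixel face.
    """
    a, b = (a, b) if a < b else (b, a)
    faces = _face_array(cmap, a, b)
    if len(faces) == 0:
        raise AdjacencyError(f"cells {a} and {b} are not 4-adjacent")
    return Interface(a, b, _order_faces(faces), cmap.pixel_size)


def extract_all_interfaces(cmap: CellMap, graph: nx.Graph | None = None) -> dict:
    """All interfaces of the map, keyed by canonical (a, b) pair."""
    if graph is None:
        graph = build_adjacency(cmap)
    return {
        (min(a, b), max(a, b)): extract_interface(cmap, a, b)
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges)
    }


def abaxial_axis(cmap: CellMap) -> np.ndarray:
    """Unit (row, col) vector pointing abaxially.

    Inferred from tissue anatomy: xylem sits adaxially, phloem abaxially, so
    the axis runs from the xylem centroid toward the phloem centroid.  Raises
    :class:`AxisInferenceError` when either tissue is absent or the centroids
    coincide; the caller may then supply an axis explicitly.
    """
    xy = cmap.cells_of_type("XY")
    ph = cmap.cells_of_type(*PHLOEM_TYPES)
    if not xy or not ph:
        raise AxisInferenceError("axis inference needs xylem and phloem cells")
    cx = np.mean([cmap.centroid(c) for c in xy], axis=0)
    cp = np.mean([cmap.centroid(c) for c in ph], axis=0)
    v = cp - cx
    norm = np.linalg.norm(v)
    if norm == 0:
        raise AxisInferenceError("xylem and phloem centroids coincide")
    return v / norm


def _bs_halves(cmap: CellMap, axis: np.ndarray) -> tuple[list[int], list[int], float]:
    """Split bundle-sheath cells into abaxial / adaxial halves by the median
    of their centroid projections on the abaxial axis."""
    bs = cmap.cells_of_type("BS")
    if not bs:
        raise ClassificationError("no bundle-sheath cells in map")
    proj = {c: float(cmap.centroid(c) @ axis) for c in bs}
    med = float(np.median(list(proj.values())))
    abx = [c for c in bs if proj[c] >= med]
    adx = [c for c in bs if proj[c] < med]
    if not adx:  # all projections equal: fall back to an even split
        abx = bs[: len(bs) // 2]
        adx = bs[len(bs) // 2 :]
    return abx, adx, med


def classify_position(
    cell: int, graph: nx.Graph, cmap: CellMap, axis: np.ndarray
) -> PositionClass:
    """Classify a cell as abaxial / middle / adaxial.

    A cell is *abaxial* when it lies directly adjacent to (1 hop) or just one
    cell away from (2 hops) an abaxial-half bundle-sheath cell; *adaxial*
    analogously for the adaxial half; *middle* otherwise.  A cell within two
    hops of both halves is resolved by its own centroid projection relative
    to the bundle-sheath median.  Intervening cells may be of any type.
    """
    abx_bs, adx_bs, med = _bs_halves(cmap, axis)
    dist = nx.single_source_shortest_path_length(graph, cell, cutoff=None)
    d_abx = min((dist[c] for c in abx_bs if c in dist), default=None)
    d_adx = min((dist[c] for c in adx_bs if c in dist), default=None)
    near_abx = d_abx is not None and d_abx <= 2
    near_adx = d_adx is not None and d_adx <= 2
    if near_abx and near_adx:
        own = float(cmap.centroid(cell) @ axis)
        value = "abaxial" if own >= med else "adaxial"
    elif near_abx:
        value = "abaxial"
    elif near_adx:
        value = "adaxial"
    else:
        value = "middle"
    return PositionClass(value, d_abx, d_adx)


def vein_size(cmap: CellMap) -> float:
    """Vascular-bundle area in µm²: combined pixel area of xylem and phloem
    cells (XY, SE, CC, PP); bundle sheath and OTHER excluded."""
    vas = cmap.cells_of_type(*VASCULAR_TYPES)
    if not vas:
        return 0.0
    n_px = int(np.isin(cmap.labels, vas).sum())
    return n_px * cmap.pixel_size**2


def interface_table(interfaces: dict, cmap: CellMap) -> pd.DataFrame:
    """Tabulate interfaces for CSV export."""
    rows = []
    for (a, b), itf in sorted(interfaces.items()):
        rows.append(
            {
                "cell_a": a,
                "cell_b": b,
                "type_a": cmap.types[a],
                "type_b": cmap.types[b],
                "n_faces": len(itf),
                "length_um": itf.length,
                "covered_length_um": itf.covered_length,
                "coverage_fraction": itf.covered_length / itf.length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_a",
            "cell_b",
            "type_a",
            "type_b",
            "n_faces",
            "length_um",
            "covered_length_um",
            "coverage_fraction",
        ],
    )
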
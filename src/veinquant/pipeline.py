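"""End-to-end measurement of one vein: geometry -> ingrowth -> scores.

`analyze_vein` ties the modules together for a single registered
(image, label map) pair and returns per-cell and per-interface tables plus
a :class:`~veinquant.stats_report.VeinSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry, ingrowth
from .errors import AxisInferenceError
from .image import CellMap, VeinImage
from .stats_report import VeinSummary, summarize_vein


@dataclass
class VeinResult:
    """Result bundle for one analysed vein."""

    cells: pd.DataFrame
    interfaces: pd.DataFrame
    summary: VeinSummary
    classes: dict
    positions: dict
    interface_objects: dict


def analyze_vein(
    image: VeinImage,
    cmap: CellMap,
    factor: float = ingrowth.DEFAULT_FACTOR,
    min_run: int = ingrowth.DEFAULT_MIN_RUN,
    small_cc: float = ingrowth.DEFAULT_SMALL_CC,
    full: float = ingrowth.DEFAULT_FULL,
    axis: np.ndarray | None = None,
) -> VeinResult:
    """Run the full measurement pipeline on one vein.

    Builds the adjacency graph and interfaces, classifies PP-cell positions
    (axis inferred from anatomy unless supplied), detects wall-ingrowth
    deposition on each PP cell, assigns deposition classes and scores, and
    tallies the vein.
    """
    if image.shape != cmap.labels.shape:
        raise ValueError("image and label map are not registered")
    graph = geometry.build_adjacency(cmap)
    interfaces = geometry.extract_all_interfaces(cmap, graph)
    if axis is None:
        axis = geometry.abaxial_axis(cmap)

    wall_mask = ingrowth.binarize_wall(image.wall)
    classes = {}
    positions = {}
    for pp in cmap.cells_of_type("PP"):
        classes[pp] = ingrowth.classify_cell(
            image.wall,
            cmap,
            pp,
            interfaces,
            factor=factor,
            min_run=min_run,
            small_cc=small_cc,
            full=full,
            wall_mask=wall_mask,
        )
        try:
            positions[pp] = geometry.classify_position(pp, graph, cmap, axis)
        except Exception as exc:  # no BS cells etc.
            positions[pp] = None

    summary = summarize_vein(cmap, classes, positions, interfaces, graph)

    cell_rows = []
    for c in cmap.cell_ids:
        row = {
            "cell_id": c,
            "type": cmap.types[c],
            "area_um2": float((cmap.labels == c).sum()) * cmap.pixel_size**2,
        }
        if c in classes:
            dep = classes[c]
            pos = positions.get(c)
            row.update(
                position=pos.value if pos else "",
                coverage_SE=dep.coverage_SE,
                max_coverage_CC=max(dep.coverage_CC, default=0.0),
                deposition_class=dep.value,
                cell_score=ingrowth.score_cell(dep).cell_score,
            )
        cell_rows.append(row)
    cells = pd.DataFrame(cell_rows)

    interfaces_df = geometry.interface_table(interfaces, cmap)
    return VeinResult(
        cells=cells,
        interfaces=interfaces_df,
        summary=summary,
        classes=classes,
        positions=positions,
        interface_objects=interfaces,
    )
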
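"""Cohort-level survey statistics and significance tests.

Aggregates per-cell and per-vein measurements into the survey quantities a
minor-vein census reports: phloem cell counts per vein, the percentage of
PP transfer cells in the abaxial position, how many veins carry more than a
pair of transfer cells, interface-length and coverage summaries, the
transfer-cell/vein-size correlation, and two-sample comparisons (pooled
Student's t by default, Welch behind a flag).

A PP cell counts as a transfer cell (PP TC) when its deposition class is at
least II — i.e. when it has any discernible wall-ingrowth deposition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyInputError, ClassificationError
from .geometry import Interface, PositionClass, vein_size
from .image import CellMap
from .ingrowth import DepositionClass, score_cell


@dataclass
class VeinSummary:
    """Per-vein tallies and measurements."""

    n_xy: int
    n_se: int
    n_cc: int
    n_pp: int
    n_pp_tc: int
    vein_area_um2: float
    pp_positions: dict = field(default_factory=dict)  # PP label -> position
    pp_scores: dict = field(default_factory=dict)  # PP label -> cell score
    pp_classes: dict = field(default_factory=dict)  # PP label -> class name
    n_cc_abutting_pp_tc: int = 0
    n_se_abutting_pp_tc: int = 0
    n_cc_abutting_ingrowth: int = 0
    n_se_abutting_ingrowth: int = 0
    interface_lengths: dict = field(default_factory=dict)  # "PP-CC" -> [µm]
    covered_lengths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_pp_tc > self.n_pp:
            raise ValueError("n_pp_tc cannot exceed n_pp")
        if self.vein_area_um2 < 0:
            raise ValueError("vein area must be >= 0")

    @property
    def vein_score(self) -> int:
        return int(sum(self.pp_scores.values()))


def summarize_vein(
    cmap: CellMap,
    classes: dict,
    positions: dict,
    interfaces: dict,
    graph=None,
) -> VeinSummary:
    """Tally one vein from its label map and per-cell results.

    ``classes`` maps PP label -> :class:`DepositionClass`, ``positions``
    PP label -> :class:`PositionClass` (or plain position strings);
    ``interfaces`` maps canonical pairs to :class:`Interface` with detection
    masks filled.  A CC or SE "abuts wall ingrowths" iff its interface with
    a PP TC has coverage > 0.
    """
    pp_cells = cmap.cells_of_type("PP")
    missing = set(pp_cells) - set(classes)
    if missing:
        raise EmptyInputError(f"missing deposition classes for PP cells {sorted(missing)}")
    pp_classes = {}
    pp_scores = {}
    for c in pp_cells:
        dep = classes[c]
        if not isinstance(dep, DepositionClass):
            raise ClassificationError(f"cell {c}: expected DepositionClass")
        pp_classes[c] = dep.value
        pp_scores[c] = score_cell(dep).cell_score
    pp_tc = [c for c in pp_cells if pp_classes[c] != "I"]

    pos = {}
    for c in pp_cells:
        p = positions.get(c)
        pos[c] = p.value if isinstance(p, PositionClass) else p

    cc_abut, se_abut = set(), set()
    cc_ing, se_ing = set(), set()
    lengths: dict[str, list] = {}
    covered: dict[str, list] = {}
    for (a, b), itf in sorted(interfaces.items()):
        ta, tb = cmap.types[a], cmap.types[b]
        key = "-".join(sorted((ta, tb)))
        lengths.setdefault(key, []).append(itf.length)
        covered.setdefault(key, []).append(itf.covered_length)
        for pp in (x for x in (a, b) if x in pp_tc):
            other = itf.other(pp)
            if cmap.types[other] == "CC":
                cc_abut.add(other)
                if itf.covered_length > 0:
                    cc_ing.add(other)
            elif cmap.types[other] == "SE":
                se_abut.add(other)
                if itf.covered_length > 0:
                    se_ing.add(other)

    return VeinSummary(
        n_xy=len(cmap.cells_of_type("XY")),
        n_se=len(cmap.cells_of_type("SE")),
        n_cc=len(cmap.cells_of_type("CC")),
        n_pp=len(pp_cells),
        n_pp_tc=len(pp_tc),
        vein_area_um2=vein_size(cmap),
        pp_positions=pos,
        pp_scores=pp_scores,
        pp_classes=pp_classes,
        n_cc_abutting_pp_tc=len(cc_abut),
        n_se_abutting_pp_tc=len(se_abut),
        n_cc_abutting_ingrowth=len(cc_ing),
        n_se_abutting_ingrowth=len(se_ing),
        interface_lengths=lengths,
        covered_lengths=covered,
    )


def percentage(n: int, total: int) -> int:
    """Integer percentage, rounded half away from zero (200 of 339 -> 59)."""
    if total <= 0:
        raise EmptyInputError("percentage undefined for empty total")
    if not 0 <= n <= total:
        raise ValueError("count must lie in [0, total]")
    x = 100.0 * n / total
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def two_sample_t(x, y, pooled: bool = True) -> tuple[float, float, float]:
    """Two-sample t test: (t, df, two-sided p).

    Pooled-variance Student's t by default; ``pooled=False`` gives Welch's
    unequal-variance test.  Degenerate input (zero pooled variance with
    equal means) reports t = 0, p = 1 with a warning.
    """
    import warnings

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 2 or len(y) < 2:
        raise EmptyInputError("each sample needs at least two observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        warnings.warn("zero variance in both samples; p = 1 reported", stacklevel=2)
        df = len(x) + len(y) - 2 if pooled else float("nan")
        return (0.0, float(df), 1.0) if x.mean() == y.mean() else (
            math.inf if x.mean() > y.mean() else -math.inf,
            float(df),
            0.0,
        )
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return float(res.statistic), float(res.df), float(res.pvalue)


def correlation_check(n_pp_tc, vein_area) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-vein transfer-cell
    counts and vein areas; reported descriptively, not asserted."""
    n_pp_tc = np.asarray(n_pp_tc, dtype=np.float64)
    vein_area = np.asarray(vein_area, dtype=np.float64)
    if len(n_pp_tc) != len(vein_area) or len(n_pp_tc) < 3:
        raise EmptyInputError("need >= 3 paired observations")
    if np.std(n_pp_tc) == 0 or np.std(vein_area) == 0:
        raise EmptyInputError("correlation undefined for constant input")
    r, p = sps.pearsonr(n_pp_tc, vein_area)
    return float(r), float(p)


@dataclass
class CohortSummary:
    """Cohort-level survey of many veins."""

    n_veins: int
    n_pp_tc_total: int
    mean_counts: dict
    pct_abaxial_pp_tc: int | None
    pct_veins_multi_pp_tc: int | None
    mean_interface_lengths: dict
    mean_coverage: dict
    frac_cc_abutting_ingrowth: float | None
    size_correlation: tuple | None
    score_comparison: dict | None

    def to_json(self, path: str | Path, **extra) -> None:
        d = asdict(self)
        d.update(extra)
        Path(path).write_text(json.dumps(d, indent=2, default=float))


def summarize_cohort(veins: list) -> CohortSummary:
    """Aggregate :class:`VeinSummary` objects into the survey statistics.

    An empty cohort yields a valid all-empty summary with ``n_veins = 0``.
    """
    n = len(veins)
    if n == 0:
        return CohortSummary(
            n_veins=0,
            n_pp_tc_total=0,
            mean_counts={},
            pct_abaxial_pp_tc=None,
            pct_veins_multi_pp_tc=None,
            mean_interface_lengths={},
            mean_coverage={},
            frac_cc_abutting_ingrowth=None,
            size_correlation=None,
            score_comparison=None,
        )
    mean_counts = {
        k: float(np.mean([getattr(v, k) for v in veins]))
        for k in ("n_xy", "n_se", "n_cc", "n_pp", "n_pp_tc")
    }
    # positions and scores of transfer cells only
    tc_positions = []
    scores_by_pos: dict[str, list] = {}
    for v in veins:
        for c, cls in v.pp_classes.items():
            if cls == "I":
                continue
            pos = v.pp_positions.get(c)
            if pos:
                tc_positions.append(pos)
                scores_by_pos.setdefault(pos, []).append(v.pp_scores[c])
    n_tc = sum(v.n_pp_tc for v in veins)
    pct_abx = (
        percentage(sum(p == "abaxial" for p in tc_positions), len(tc_positions))
        if tc_positions
        else None
    )
    pct_multi = percentage(sum(v.n_pp_tc > 2 for v in veins), n)

    lengths: dict[str, list] = {}
    covered: dict[str, list] = {}
    for v in veins:
        for k, vals in v.interface_lengths.items():
            lengths.setdefault(k, []).extend(vals)
        for k, vals in v.covered_lengths.items():
            covered.setdefault(k, []).extend(vals)
    mean_lengths = {k: float(np.mean(v)) for k, v in lengths.items()}
    mean_cov = {
        k: float(np.sum(covered[k]) / np.sum(lengths[k]))
        for k in lengths
        if np.sum(lengths[k]) > 0
    }

    cc_tot = sum(v.n_cc_abutting_pp_tc for v in veins)
    frac_cc_ing = (
        sum(v.n_cc_abutting_ingrowth for v in veins) / cc_tot if cc_tot else None
    )

    size_corr = None
    counts = [v.n_pp_tc for v in veins]
    areas = [v.vein_area_um2 for v in veins]
    try:
        size_corr = correlation_check(counts, areas)
    except EmptyInputError:
        pass

    score_cmp = None
    abx = scores_by_pos.get("abaxial", [])
    adx = scores_by_pos.get("adaxial", [])
    if len(abx) >= 2 and len(adx) >= 2:
        t, df, p = two_sample_t(abx, adx)
        score_cmp = {
            "mean_abaxial": float(np.mean(abx)),
            "mean_adaxial": float(np.mean(adx)),
            "t": t,
            "df": df,
            "p": p,
        }

    return CohortSummary(
        n_veins=n,
        n_pp_tc_total=n_tc,
        mean_counts=mean_counts,
        pct_abaxial_pp_tc=pct_abx,
        pct_veins_multi_pp_tc=pct_multi,
        mean_interface_lengths=mean_lengths,
        mean_coverage=mean_cov,
        frac_cc_abutting_ingrowth=frac_cc_ing,
        size_correlation=size_corr,
        score_comparison=score_cmp,
    )


def cohort_table(veins: list) -> pd.DataFrame:
    """One row per vein, for CSV export."""
    rows = []
    for i, v in enumerate(veins):
        rows.append(
            {
                "vein_id": i,
                "n_xy": v.n_xy,
                "n_se": v.n_se,
                "n_cc": v.n_cc,
                "n_pp": v.n_pp,
                "n_pp_tc": v.n_pp_tc,
                "vein_area_um2": v.vein_area_um2,
                "vein_score": v.vein_score,
                "n_abaxial_pp_tc": sum(
                    1
                    for c, cls in v.pp_classes.items()
                    if cls != "I" and v.pp_positions.get(c) == "abaxial"
                ),
            }
        )
    return pd.DataFrame(rows)


def plot_counts_vs_area(veins: list, path: str | Path) -> None:
    """Scatter of transfer-cell count against vein area (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(
        [v.vein_area_um2 for v in veins], [v.n_pp_tc for v in veins], s=14, alpha=0.7
    )
    ax.set_xlabel("vascular bundle area (µm²)")
    ax.set_ylabel("PP TCs per vein")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
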
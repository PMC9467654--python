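"""Wall-ingrowth detection, coverage fractions and deposition classes.

Ingrowths appear in the wall-stain channel as local thickening of the
primary wall on the PP side of an interface.  Detection measures a per-face
wall-thickness profile (inward scan perpendicular to the boundary through
the binarized wall stain), flags faces thicker than ``factor`` times the
cell's primary-wall baseline, and suppresses isolated runs shorter than
``min_run`` faces.

The five-class scheme summarises a cell's deposition state from the
coverage of its SE-facing and CC-facing interfaces:

=====  =============================================================
Class  Definition
=====  =============================================================
I      no coverage anywhere
II     partial SE coverage (0 < SE < full)
III    full SE coverage, at most a small CC portion (max CC <= small_cc)
IV     full SE coverage, considerable CC portion (small_cc < max CC < full)
V      full SE coverage and at least one fully covered CC interface
=====  =============================================================

with ``full = 0.95`` operationalising "entirely covering" and ``small_cc =
0.2`` "a small portion"; both are configurable.  The ordinal cell score is
class index - 1 (0..4) and a vein's score is the sum over its PP cells, so
a typical two-PP-TC vein spans 0..8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ProfileError, EmptyInputError
from .geometry import Interface
from .image import CellMap

CLASS_NAMES = ("I", "II", "III", "IV", "V")

#: Default detection parameters.  The visual-assessment origin of the class
#: scheme gives no numeric criterion; a 1.5x thickness factor with a 3-face
#: minimum run separates k >= 2 deposition from noise at the generator's
#: default signal-to-noise ratio.
DEFAULT_FACTOR = 1.5
DEFAULT_MIN_RUN = 3
#: Half-width (faces) of the edge trim applied to detected runs: the soft
#: pixel attribution leaks a thick pad laterally by up to ~4 faces past the
#: true arc end, and the trim removes exactly that margin.
DEFAULT_TRIM = 4
#: CC-facing interfaces with fewer scorable faces than this are too short
#: for a partial-coverage estimate at the attribution/trim scale and are
#: excluded from class assignment.
MIN_CC_FACES = 20
#: Detected runs ending within this many faces of a wall junction are not
#: trimmed there: junction geometry (wedges, pad fusion) shifts run ends by
#: a few faces, and there is no attribution leak to remove at a junction.
JUNCTION_PROTECT = 6
#: Faces of a CC interface adjacent to the SE junction excluded from the
#: class-assignment coverage (pad fusion zone, ~2 µm at default pixel size).
CC_JUNCTION_SKIP = 10
#: Faces between a run end and a junction must read at least this multiple
#: of the baseline for the end to count as junction-fused (and escape the
#: leak trim).
RAMP_LEVEL_FACTOR = 1.2
DEFAULT_SMALL_CC = 0.2
#: Measured coverage counting as "entire".  Faces within ~1 µm of a wall
#: junction are intrinsically ambiguous at 0.2 µm resolution (the pad fuses
#: with the junction), so a fully covered interface measures in the
#: 0.83-1.0 range on calibration veins while half coverage stays below
#: 0.6; 0.8 splits the gap with margin on both sides.
DEFAULT_FULL = 0.8


@dataclass
class ThicknessProfile:
    """Per-face local wall thickness (µm) along one interface, plus the
    cell's primary-wall baseline (µm)."""

    thicknesses: np.ndarray
    baseline: float
    pixel_size: float

    def __post_init__(self) -> None:
        self.thicknesses = np.asarray(self.thicknesses, dtype=np.float64)
        if (self.thicknesses < 0).any():
            raise ProfileError("thicknesses must be >= 0")


@dataclass
class DepositionClass:
    """Class I–V assignment with the coverages that produced it."""

    value: str
    coverage_SE: float
    coverage_CC: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.value not in CLASS_NAMES:
            raise ValueError(f"invalid class {self.value!r}")

    @property
    def index(self) -> int:
        """1-based class index (I -> 1 ... V -> 5)."""
        return CLASS_NAMES.index(self.value) + 1


@dataclass
class IngrowthScore:
    """Ordinal deposition score: per cell 0–4 (= class index - 1); per vein
    the sum over PP cells."""

    cell_score: int
    vein_score: int | None = None


def binarize_wall(wall_channel: np.ndarray) -> np.ndarray:
    """Binary wall mask via 8-bit conversion and the default (intermeans)
    threshold."""
    from .fluorquant import to_8bit, default_threshold

    ch8 = to_8bit(wall_channel)
    return ch8 > default_threshold(ch8)


#: Attribution slack (pixels): a wall pixel contributes to every anchor
#: within this margin of its nearest anchor.  Just above the half-pixel
#: aliasing of staircase boundaries, so no anchor is shadowed by a corner
#: neighbour; the price is a bounded lateral leak of roughly
#: sqrt(2 * depth * slack) faces at an arc end, removed by the matching
#: edge trim in detection.
_ATTRIB_SLACK = 0.8


def _face_depths(
    wall_mask: np.ndarray,
    cell_mask: np.ndarray,
    anchors: np.ndarray,
    max_px: int = 32,
) -> np.ndarray:
    """Per-anchor wall depth (pixels) on one cell's side of its boundary.

    ``anchors`` (n, 2) are boundary pixels of the cell.  Every wall-positive
    pixel inside the cell is attributed to each anchor within
    :data:`_ATTRIB_SLACK` of its nearest anchor; an anchor's wall depth is
    one plus the largest attribution distance it receives (its own boundary
    pixel contributes depth 1), and zero when its own boundary pixel is not
    wall-positive.  This is a local morphological wall width: isotropic on
    staircase boundaries, with each face reading the wall column above its
    own stretch of boundary.
    """
    from scipy.spatial import cKDTree

    inside = wall_mask & cell_mask
    out = np.zeros(len(anchors), dtype=np.float64)
    rr, cc = np.nonzero(inside)
    if rr.size == 0:
        return out
    pts = np.stack([rr, cc], axis=1)
    k = min(12, len(anchors))
    dist, idx = cKDTree(anchors).query(pts, k=k)
    dist = np.atleast_2d(dist.reshape(len(pts), -1))
    idx = np.atleast_2d(idx.reshape(len(pts), -1))
    near = (dist <= dist[:, :1] + _ATTRIB_SLACK) & (dist <= max_px)
    np.maximum.at(out, idx[near], np.floor(dist[near] + 1.0 + 1e-9))
    # a face whose own boundary pixel carries no wall stain has no wall
    anchor_wall = wall_mask[anchors[:, 0], anchors[:, 1]] & cell_mask[
        anchors[:, 0], anchors[:, 1]
    ]
    out[~anchor_wall] = 0.0
    return out


def _rolling_max(x: np.ndarray, window: int) -> np.ndarray:
    """Rolling maximum over a centred window of half-width ``window``."""
    if window <= 0 or len(x) == 0:
        return x.copy()
    return ndimage.maximum_filter1d(x, size=2 * window + 1, mode="nearest")


def _background_anchors(cell_map: CellMap, cell: int) -> np.ndarray:
    """Boundary pixels of a cell that face the image background, (n, 2)."""
    lab = cell_map.labels
    mask = lab == cell
    padded = np.pad(lab, 1, constant_values=0)
    bg_nbr = np.zeros(lab.shape, dtype=bool)
    for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
        bg_nbr |= padded[1 + dr : lab.shape[0] + 1 + dr, 1 + dc : lab.shape[1] + 1 + dc] == 0
    rr, cc = np.nonzero(mask & bg_nbr)
    return np.stack([rr, cc], axis=1) if rr.size else np.empty((0, 2), dtype=np.int64)


def thickness_profile(
    wall_channel: np.ndarray,
    interface: Interface,
    cell_map: CellMap,
    cell: int | None = None,
    wall_mask: np.ndarray | None = None,
    max_px: int = 32,
    baseline: float | None = None,
    extra_anchors: np.ndarray | None = None,
) -> ThicknessProfile:
    """Wall thickness at each face of one interface, on the focal cell's side.

    ``cell`` defaults to the PP-typed side of the interface.  Thickness at a
    face is the deepest wall-stain pixel attributed to it by the
    distance-transform measure of :func:`_face_depths`, in µm; a face with
    no wall-positive pixel on its boundary has thickness zero.
    ``extra_anchors`` may supply boundary pixels of the cell's *other*
    interfaces so their wall bands are not attributed to this one;
    :func:`cell_profiles` does this automatically.  When no baseline is
    supplied, the 25th percentile of the (smoothed) profile is used;
    pooling over all of a cell's interfaces via :func:`cell_baseline` is
    more robust.
    """
    if wall_channel.shape != cell_map.labels.shape:
        raise EmptyInputError("wall channel and label map shapes differ")
    if cell is None:
        pp_sides = [c for c in interface.pair if cell_map.types[c] == "PP"]
        if len(pp_sides) != 1:
            raise ProfileError(
                f"interface {interface.pair}: focal cell ambiguous, pass cell="
            )
        cell = pp_sides[0]
    if wall_mask is None:
        wall_mask = binarize_wall(wall_channel)
    side = interface.side_pixels(cell)
    anchors = side if extra_anchors is None or not len(extra_anchors) else np.vstack(
        [side, extra_anchors]
    )
    depths = _face_depths(wall_mask, cell_map.mask(cell), anchors, max_px)[: len(side)]
    thick = depths * cell_map.pixel_size
    if baseline is None:
        baseline = float(np.percentile(thick, 25))
    return ThicknessProfile(thick, baseline, cell_map.pixel_size)


def cell_profiles(
    wall_channel: np.ndarray,
    cell_map: CellMap,
    cell: int,
    interfaces: dict,
    wall_mask: np.ndarray | None = None,
    max_px: int = 32,
) -> dict:
    """Thickness profiles for all interfaces of one cell in a single pass.

    All boundary pixels of the cell — every interface plus any
    background-facing stretch — anchor the wall-pixel attribution jointly,
    so each interface only receives its own wall band.  Use
    :func:`cell_baseline` to pool the per-interface baselines.
    """
    if wall_mask is None:
        wall_mask = binarize_wall(wall_channel)
    own = {pair: itf for pair, itf in interfaces.items() if cell in pair}
    if not own:
        raise EmptyInputError(f"cell {cell} has no interfaces")
    pairs = sorted(own)
    sides = [own[p].side_pixels(cell) for p in pairs]
    bg = _background_anchors(cell_map, cell)
    anchors = np.vstack(sides + ([bg] if len(bg) else []))
    depths = _face_depths(wall_mask, cell_map.mask(cell), anchors, max_px)
    out = {}
    offset = 0
    for p, side in zip(pairs, sides):
        thick = depths[offset : offset + len(side)] * cell_map.pixel_size
        base = float(np.percentile(thick, 25))
        out[p] = ThicknessProfile(thick, base, cell_map.pixel_size)
        offset += len(side)
    return out


def cell_baseline(
    profiles: dict,
    known_zero: list | None = None,
) -> float:
    """Primary-wall baseline for one cell from its interface profiles.

    ``profiles`` maps interface pair -> :class:`ThicknessProfile`.  When
    ``known_zero`` lists pairs known to carry no deposition (e.g. from
    generator truth), the baseline is the median thickness over their
    faces; otherwise it is the 25th percentile of all the cell's face
    thicknesses.
    """
    if known_zero:
        vals = np.concatenate([profiles[p].thicknesses for p in known_zero])
        return float(np.median(vals))
    vals = np.concatenate([p.thicknesses for p in profiles.values()])
    return float(np.percentile(vals, 25))


def detect_ingrowth(
    profile: ThicknessProfile,
    factor: float = DEFAULT_FACTOR,
    min_run: int = DEFAULT_MIN_RUN,
    trim: int = 0,
) -> np.ndarray:
    """Boolean per-face ingrowth mask.

    Faces whose thickness exceeds ``factor`` times the baseline are
    flagged, and contiguous runs of fewer than ``min_run`` flagged faces
    are suppressed as speckle.  ``trim`` additionally erodes each run by
    that many faces per end — the correction :func:`classify_cell` applies
    (cyclically) for the lateral leak of the image-derived soft depth
    attribution; it is off by default so that the operation is exact on
    externally supplied profiles.  Runs touching the profile ends are
    never trimmed there (the interface continues into a wall junction).
    """
    if factor <= 1:
        raise ValueError("factor must be > 1")
    if profile.baseline <= 0:
        raise ProfileError("profile baseline is zero")
    flags = profile.thicknesses > factor * profile.baseline
    if trim > 0 and flags.any() and not flags.all():
        flags = ndimage.binary_erosion(
            flags, structure=np.ones(2 * trim + 1, dtype=bool), border_value=1
        )
    return _suppress_short_runs(flags, min_run)


def _trim_runs_cyclic(
    flags: np.ndarray,
    seg_id: np.ndarray,
    trim: int,
    depth: np.ndarray | None = None,
    ramp_level: float = 0.0,
    protect: int = 2,
) -> np.ndarray:
    """Trim each flagged run by ``trim`` faces per end on a cyclic profile.

    The soft depth attribution leaks a pad past its true end only where the
    pad stops mid-interface; a run ending at a wall junction is bounded by
    the junction itself and carries no leak.  A run end is therefore
    *protected* from trimming when it lies within ``protect`` faces of a
    segment (interface) transition **and** every face between the end and
    the transition reads at least ``ramp_level`` — the rising-wedge
    signature of a pad fused into the junction.  A mere base-thickness gap
    next to a junction is no such evidence, and the end is trimmed as a
    leak.
    """
    n = len(flags)
    if n == 0 or trim <= 0 or not flags.any() or flags.all():
        return flags.copy()
    trans = np.nonzero(seg_id != np.roll(seg_id, 1))[0]  # segment start positions
    trans_set = set(int(t) for t in trans)

    def head_protected(a: int) -> bool:
        # walk backwards from the run head toward the previous transition
        for g in range(protect + 1):
            if (a - g) % n in trans_set:
                return True
            probe = (a - g - 1) % n
            if depth is not None and depth[probe] < ramp_level:
                return False
        return False

    def tail_protected(b: int) -> bool:
        for g in range(protect + 1):
            if (b + g + 1) % n in trans_set:
                return True
            probe = (b + g + 1) % n
            if depth is not None and depth[probe] < ramp_level:
                return False
        return False

    out = flags.copy()
    start0 = int(np.nonzero(~flags)[0][0])
    i = start0
    for _ in range(2 * n):
        j = i
        while not flags[j % n]:
            j += 1
            if (j - start0) >= n + 1:
                return out
        a = j % n
        while flags[j % n]:
            j += 1
        b = (j - 1) % n  # run is [a..b] cyclic
        length = (b - a) % n + 1
        if not head_protected(a):
            for d in range(min(trim, length)):
                out[(a + d) % n] = False
        if not tail_protected(b):
            for d in range(min(trim, length)):
                out[(b - d) % n] = False
        i = j
        if (j - start0) >= n:
            break
    return out


def _suppress_short_runs(flags: np.ndarray, min_run: int) -> np.ndarray:
    out = flags.copy()
    n = len(flags)
    i = 0
    while i < n:
        if out[i]:
            j = i
            while j < n and out[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def coverage_fraction(interface: Interface) -> float:
    """Covered fraction of an interface: flagged face length / total length."""
    if len(interface) == 0:
        raise EmptyInputError("zero-length interface")
    return float(interface.ingrowth_mask.sum()) / len(interface)


def assign_class(
    coverage_SE: float,
    coverage_CC,
    small_cc: float = DEFAULT_SMALL_CC,
    full: float = DEFAULT_FULL,
) -> DepositionClass:
    """Assign the Class I–V deposition category from coverage fractions.

    ``coverage_SE`` is the covered fraction of the cell's total SE-facing
    interface length; ``coverage_CC`` lists per-CC-interface fractions.
    Thresholds are inclusive: SE coverage >= ``full`` counts as entire, and
    max CC coverage == ``small_cc`` still counts as a small portion.  A cell
    with zero SE coverage but nonzero CC coverage has no counterpart in the
    scheme (deposition nucleates at the SE interface); it raises a
    consistency warning and is binned as Class II.
    """
    coverage_CC = tuple(float(c) for c in np.atleast_1d(coverage_CC))
    if not (0.0 <= coverage_SE <= 1.0) or any(not 0 <= c <= 1 for c in coverage_CC):
        raise ValueError("coverage fractions must lie in [0, 1]")
    max_cc = max(coverage_CC, default=0.0)
    if coverage_SE == 0.0:
        if max_cc > 0.0:
            warnings.warn(
                "CC-interface coverage without SE coverage: inconsistent with "
                "SE-nucleated deposition; returning Class II",
                stacklevel=2,
            )
            return DepositionClass("II", coverage_SE, coverage_CC)
        return DepositionClass("I", coverage_SE, coverage_CC)
    if coverage_SE < full:
        return DepositionClass("II", coverage_SE, coverage_CC)
    if max_cc >= full:
        return DepositionClass("V", coverage_SE, coverage_CC)
    if max_cc <= small_cc:
        return DepositionClass("III", coverage_SE, coverage_CC)
    return DepositionClass("IV", coverage_SE, coverage_CC)


def score_cell(dep: DepositionClass) -> IngrowthScore:
    """Ordinal score of one cell: class index - 1 (Class I -> 0, V -> 4)."""
    return IngrowthScore(cell_score=dep.index - 1)


def score_vein(deps) -> int:
    """Vein score: sum of cell scores over the vein's PP cells (0 for a
    vein without PP cells)."""
    return int(sum(score_cell(d).cell_score for d in deps))


def classify_cell(
    wall_channel: np.ndarray,
    cell_map: CellMap,
    cell: int,
    interfaces: dict,
    factor: float = DEFAULT_FACTOR,
    min_run: int = DEFAULT_MIN_RUN,
    small_cc: float = DEFAULT_SMALL_CC,
    full: float = DEFAULT_FULL,
    wall_mask: np.ndarray | None = None,
    known_zero: list | None = None,
) -> DepositionClass:
    """Full per-cell detection: profile every interface of ``cell``, derive
    the cell's primary-wall baseline, flag ingrowth faces on SE- and
    CC-facing interfaces (writing each interface's ``ingrowth_mask``), and
    assign the deposition class.

    ``interfaces`` maps canonical pairs to :class:`~veinquant.geometry.Interface`;
    only pairs involving ``cell`` are consulted.

    Detection runs on the *cyclic* thickness profile of the cell's whole
    boundary (all interfaces concatenated in boundary order).  A deposition
    pad that reaches a wall junction fuses with the neighbouring wall there,
    so the per-interface profile alone dips ambiguously near its ends;
    on the closed cell boundary the pad is one contiguous thick stretch and
    junction dips are bridged by the rolling-maximum smoothing.
    """
    from . import geometry

    if wall_mask is None:
        wall_mask = binarize_wall(wall_channel)
    own = {pair: itf for pair, itf in interfaces.items() if cell in pair}
    if not own:
        raise EmptyInputError(f"cell {cell} has no interfaces")
    profiles = cell_profiles(wall_channel, cell_map, cell, own, wall_mask=wall_mask)
    base = cell_baseline(profiles, known_zero)
    if base <= 0:
        raise ProfileError(f"cell {cell}: primary-wall baseline is zero")

    # cyclic boundary order over all faces of the cell
    pairs = sorted(own)
    all_faces = np.vstack([own[p].faces for p in pairs])
    owner = np.concatenate(
        [np.full(len(own[p]), i, dtype=np.int64) for i, p in enumerate(pairs)]
    )
    within = np.concatenate([np.arange(len(own[p])) for p in pairs])
    perm = geometry.face_order(all_faces)
    depth_cyc = np.concatenate([profiles[p].thicknesses for p in pairs])[perm]

    flags = depth_cyc > factor * base
    flags = _trim_runs_cyclic(
        flags,
        owner[perm],
        DEFAULT_TRIM,
        depth=depth_cyc,
        ramp_level=RAMP_LEVEL_FACTOR * base,
        protect=JUNCTION_PROTECT,
    )
    flags = _suppress_short_runs(flags, min_run)

    # scatter flags back to the per-interface masks
    for i, p in enumerate(pairs):
        mask = np.zeros(len(own[p]), dtype=bool)
        sel = owner[perm] == i
        mask[within[perm][sel]] = flags[sel]
        own[p].ingrowth_mask = mask

    se_px = [
        itf.side_pixels(cell)
        for pair, itf in sorted(own.items())
        if cell_map.types[itf.other(cell)] == "SE"
    ]
    se_px = np.vstack(se_px) if se_px else None

    se_cov_len = 0.0
    se_tot_len = 0.0
    cc_cov: list[float] = []
    for pair, itf in sorted(own.items()):
        other_type = cell_map.types[itf.other(cell)]
        if other_type == "SE":
            se_cov_len += itf.covered_length
            se_tot_len += itf.length
        elif other_type == "CC":
            cov = _cc_scored_coverage(itf, cell, se_px)
            if cov is not None:
                cc_cov.append(cov)
        else:
            # deposition is scored only on SE- and CC-facing interfaces
            itf.ingrowth_mask = np.zeros(len(itf), dtype=bool)
    coverage_se = se_cov_len / se_tot_len if se_tot_len > 0 else 0.0
    return assign_class(coverage_se, cc_cov, small_cc=small_cc, full=full)


#: Minimum CC-interface length (faces) for a cell's class IV/V distinction
#: to be resolvable: the scored stretch beyond the junction zone must be
#: long enough that a "considerable proportion" is distinguishable from
#: junction fusion alone.
MIN_CLASSIFIABLE_CC_FACES = 40


def cc_classifiable(interfaces: dict, cell_map: CellMap, cell: int) -> bool:
    """Whether ``cell`` has a CC-facing interface long enough for the
    class IV/V distinction to be resolvable (see
    :data:`MIN_CLASSIFIABLE_CC_FACES`)."""
    lens = [
        len(itf)
        for pair, itf in interfaces.items()
        if cell in pair and cell_map.types[itf.other(cell)] == "CC"
    ]
    return bool(lens) and max(lens) >= MIN_CLASSIFIABLE_CC_FACES


def _cc_scored_coverage(itf: Interface, cell: int, se_px) -> float | None:
    """Coverage of a CC-facing interface as used for class assignment.

    A deposition pad that entirely covers the SE interface fuses with the
    SE/CC wall junction and unavoidably reads as covered for a short
    stretch of the CC interface next to that junction; whether deposition
    *extends along* the CC interface is therefore scored on the faces
    beyond a junction exclusion zone of :data:`CC_JUNCTION_SKIP` faces.
    Interfaces with fewer than :data:`MIN_CC_FACES` scorable faces carry no
    usable partial-coverage signal and return ``None`` (excluded).
    """
    mask = itf.ingrowth_mask
    if se_px is not None and len(itf) > CC_JUNCTION_SKIP:
        side = itf.side_pixels(cell)
        d_first = float(np.linalg.norm(se_px - side[0], axis=1).min())
        d_last = float(np.linalg.norm(se_px - side[-1], axis=1).min())
        mask = mask[CC_JUNCTION_SKIP:] if d_first <= d_last else mask[:-CC_JUNCTION_SKIP]
    if len(mask) < MIN_CC_FACES:
        return None
    return float(mask.sum()) / len(mask)
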
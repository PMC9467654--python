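"""Fluorescence quantification: 8-bit conversion, default thresholding, ROI
sums, and the two ratio statistics F and FC.

The calibrated relative intensity of a membrane marker in a test region
versus a reference region is

    F = (S2 * C1) / (S1 * C2)

where S is the marker signal and C the general wall stain measured over the
same region-of-interest, subscript 1 the reference region (a PP transfer
cell) and 2 the test region.  Because the wall stain acts as an internal
standard, any multiplicative factor applied to both channels of one region
— such as depth-dependent attenuation of excitation and emission — cancels;
the reference region's own F is 1 by construction.

The membrane-enrichment factor compares marker accumulation per unit
primary-wall length between an ingrowth-bearing site and the opposite
ingrowth-free site of the same cell:

    FC = (A1 * L2) / (A2 * L1)

with A the summed marker fluorescence and L the primary-wall length of each
site (1 = ingrowth side, 2 = opposite side).  For a membrane amplified
k-fold by ingrowth deposition, FC recovers k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, UndefinedStatisticError
from .geometry import Interface
from .image import CellMap, VeinImage

#: Half-width (pixels) of the membrane region-of-interest around a cell
#: boundary.
RIBBON_PX = 2


@dataclass
class CalibrationReads:
    """The four reads of the calibrated relative-intensity statistic:
    marker (S) and wall stain (C) in the reference (1) and test (2)
    regions."""

    S1: float
    S2: float
    C1: float
    C2: float

    def __post_init__(self) -> None:
        if min(self.S1, self.S2, self.C1, self.C2) < 0:
            raise ValueError("intensity reads must be >= 0")


@dataclass
class EnrichmentReads:
    """The four reads of the enrichment factor: summed marker fluorescence
    (A) and primary-wall length in µm (L) at the ingrowth site (1) and the
    ingrowth-free site (2)."""

    A1: float
    A2: float
    L1: float
    L2: float

    def __post_init__(self) -> None:
        if min(self.A1, self.A2, self.L1, self.L2) < 0:
            raise ValueError("reads must be >= 0")


def to_8bit(channel: np.ndarray) -> np.ndarray:
    """Linear min–max rescale of a frame to 0..255, rounded half-up.

    A constant frame maps to all zeros (no contrast to stretch).
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.size == 0:
        raise EmptyInputError("empty channel")
    lo, hi = channel.min(), channel.max()
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    scaled = (channel - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


def default_threshold(channel_8bit: np.ndarray) -> int:
    """Iterative intermeans (IsoData-variant) threshold on an 8-bit frame.

    Starting from the frame mean, iterate t <- round((mean of pixels <= t +
    mean of pixels > t) / 2) to convergence; pixels strictly above the
    returned threshold count as signal.  This mirrors the common default
    auto-threshold of interactive image software.
    """
    ch = np.asarray(channel_8bit)
    if ch.size == 0:
        raise EmptyInputError("empty image")
    if ch.dtype != np.uint8:
        if ch.min() < 0 or ch.max() > 255:
            raise ValueError("default_threshold expects 8-bit data")
        ch = ch.astype(np.uint8)
    hist = np.bincount(ch.ravel(), minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    if np.count_nonzero(hist) == 1:
        return int(np.nonzero(hist)[0][0])
    t = int(np.floor((hist * levels).sum() / hist.sum()))
    for _ in range(256):
        below = hist[: t + 1]
        above = hist[t + 1 :]
        wb, wa = below.sum(), above.sum()
        if wb == 0:
            t += 1
            continue
        if wa == 0:
            t -= 1
            continue
        mb = (below * levels[: t + 1]).sum() / wb
        ma = (above * levels[t + 1 :]).sum() / wa
        t_new = int(np.floor((mb + ma) / 2.0 + 0.5))
        if t_new == t:
            break
        t = t_new
    return int(t)


def roi_intensity(
    channel: np.ndarray, roi_mask: np.ndarray, threshold: float
) -> float:
    """Summed intensity of above-threshold pixels inside the ROI.

    The comparison is strict: a pixel exactly at the threshold does not
    count as signal.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != channel.shape:
        raise EmptyInputError("ROI shape differs from channel shape")
    if not roi_mask.any():
        raise EmptyInputError("empty ROI")
    vals = np.asarray(channel, dtype=np.float64)[roi_mask]
    return float(vals[vals > threshold].sum())


def relative_intensity(reads: CalibrationReads) -> float:
    """F = (S2 * C1) / (S1 * C2); undefined when S1 or C2 is zero."""
    if reads.S1 <= 0 or reads.C2 <= 0:
        raise UndefinedStatisticError("F undefined: S1 and C2 must be positive")
    return (reads.S2 * reads.C1) / (reads.S1 * reads.C2)


def enrichment(reads: EnrichmentReads) -> float:
    """FC = (A1 * L2) / (A2 * L1); undefined when A2 or L1 is zero."""
    if reads.A2 <= 0 or reads.L1 <= 0:
        raise UndefinedStatisticError("FC undefined: A2 and L1 must be positive")
    return (reads.A1 * reads.L2) / (reads.A2 * reads.L1)


_SQUARE5 = np.ones((2 * RIBBON_PX + 1, 2 * RIBBON_PX + 1), dtype=bool)


def boundary_ribbon(cmap: CellMap, cell: int, width: int = RIBBON_PX) -> np.ndarray:
    """Membrane ROI of a cell: its boundary pixels dilated by ``width``,
    restricted to the cell's own label (so the ROI never leaks into a
    neighbouring cell's membrane)."""
    mask = cmap.mask(cell)
    if not mask.any():
        raise EmptyInputError(f"cell {cell} not in label map")
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    boundary = mask & ~eroded
    struct = np.ones((2 * width + 1, 2 * width + 1), dtype=bool)
    return ndimage.binary_dilation(boundary, structure=struct) & mask


def face_ribbon(
    cmap: CellMap, cell: int, side_pixels: np.ndarray, width: int = RIBBON_PX
) -> np.ndarray:
    """ROI around a subset of a cell's boundary (given as side pixels),
    dilated by ``width`` and restricted to the cell."""
    side_pixels = np.asarray(side_pixels).reshape(-1, 2)
    if len(side_pixels) == 0:
        raise EmptyInputError("no boundary pixels given")
    seed = np.zeros(cmap.labels.shape, dtype=bool)
    seed[side_pixels[:, 0], side_pixels[:, 1]] = True
    struct = np.ones((2 * width + 1, 2 * width + 1), dtype=bool)
    return ndimage.binary_dilation(seed, structure=struct) & cmap.mask(cell)


def measure_cell_pair(
    image: VeinImage,
    cmap: CellMap,
    ref_cell: int,
    test_cell: int,
    raw: bool = False,
    width: int = RIBBON_PX,
) -> tuple[CalibrationReads, dict]:
    """Measure the four calibration reads for a reference / test cell pair.

    Both cells must be PP-typed.  Each cell's ROI is its membrane ribbon
    (boundary ± ``width`` px within the cell).  By default each channel is
    converted to 8-bit, auto-thresholded, and summed above threshold inside
    the ROI, as in the interactive workflow the statistic comes from; with
    ``raw=True`` the original intensities are summed without conversion or
    thresholding (the exact-arithmetic route used for closed-form checks).

    Returns the reads and a metadata dict (thresholds, ROI areas).
    """
    for c in (ref_cell, test_cell):
        if cmap.types.get(c) != "PP":
            raise ValueError(f"cell {c} is not PP-typed")
    if image.shape != cmap.labels.shape:
        raise EmptyInputError("image and label map are not registered")
    roi_ref = boundary_ribbon(cmap, ref_cell, width)
    roi_test = boundary_ribbon(cmap, test_cell, width)
    meta: dict = {
        "roi_px_ref": int(roi_ref.sum()),
        "roi_px_test": int(roi_test.sum()),
        "raw": raw,
    }
    if raw:
        s1 = float(image.marker[roi_ref].sum())
        s2 = float(image.marker[roi_test].sum())
        c1 = float(image.wall[roi_ref].sum())
        c2 = float(image.wall[roi_test].sum())
    else:
        marker8 = to_8bit(image.marker)
        wall8 = to_8bit(image.wall)
        thr_s = default_threshold(marker8)
        thr_c = default_threshold(wall8)
        meta["threshold_marker"] = thr_s
        meta["threshold_wall"] = thr_c
        s1 = roi_intensity(marker8, roi_ref, thr_s)
        s2 = roi_intensity(marker8, roi_test, thr_s)
        c1 = roi_intensity(wall8, roi_ref, thr_c)
        c2 = roi_intensity(wall8, roi_test, thr_c)
    return CalibrationReads(S1=s1, S2=s2, C1=c1, C2=c2), meta


def measure_enrichment(
    image: VeinImage,
    cmap: CellMap,
    cell: int,
    ingrowth_side: tuple[np.ndarray, float],
    clear_side: tuple[np.ndarray, float],
    raw: bool = False,
    width: int = RIBBON_PX,
    exclude: np.ndarray | None = None,
) -> tuple[EnrichmentReads, dict]:
    """Measure the four enrichment reads for one cell.

    ``ingrowth_side`` and ``clear_side`` are ``(side_pixels, length_um)``
    tuples — the boundary pixels (on the cell's side) and primary-wall
    length of the ingrowth-bearing and ingrowth-free sites, as selected by
    the analyst or taken from detection / generator truth (see
    :func:`side_from_interfaces`).  ``exclude`` may list boundary pixels of
    the cell's *remaining* membrane (interfaces in neither site): ROI
    pixels nearer to that membrane than to their own site are dropped, so
    fluorescence from stretches outside a site's length denominator does
    not inflate its read.
    """
    if image.shape != cmap.labels.shape:
        raise EmptyInputError("image and label map are not registered")
    px1, l1 = ingrowth_side
    px2, l2 = clear_side
    roi1 = face_ribbon(cmap, cell, px1, width)
    roi2 = face_ribbon(cmap, cell, px2, width)
    if exclude is not None and len(exclude):
        from scipy.spatial import cKDTree

        tree_ex = cKDTree(np.asarray(exclude).reshape(-1, 2))
        for roi, own in ((roi1, px1), (roi2, px2)):
            rr, cc = np.nonzero(roi)
            if rr.size == 0:
                continue
            pts = np.stack([rr, cc], axis=1)
            d_own, _ = cKDTree(np.asarray(own).reshape(-1, 2)).query(pts)
            d_ex, _ = tree_ex.query(pts)
            drop = d_ex < d_own
            roi[rr[drop], cc[drop]] = False
    # contested pixels near the junction of the two sites are assigned to
    # the side whose boundary is nearer, so amplified membrane does not
    # bleed into the clear-side read (or vice versa) and neither site loses
    # its share of the junction zone
    overlap = roi1 & roi2
    if overlap.any():
        from scipy.spatial import cKDTree

        rr, cc = np.nonzero(overlap)
        pts = np.stack([rr, cc], axis=1)
        d1, _ = cKDTree(np.asarray(px1).reshape(-1, 2)).query(pts)
        d2, _ = cKDTree(np.asarray(px2).reshape(-1, 2)).query(pts)
        to_1 = d1 <= d2
        roi1[rr[~to_1], cc[~to_1]] = False
        roi2[rr[to_1], cc[to_1]] = False
    meta: dict = {"raw": raw, "roi_px_1": int(roi1.sum()), "roi_px_2": int(roi2.sum())}
    if raw:
        a1 = float(image.marker[roi1].sum())
        a2 = float(image.marker[roi2].sum())
    else:
        marker8 = to_8bit(image.marker)
        thr = default_threshold(marker8)
        meta["threshold_marker"] = thr
        a1 = roi_intensity(marker8, roi1, thr)
        a2 = roi_intensity(marker8, roi2, thr)
    return EnrichmentReads(A1=a1, A2=a2, L1=float(l1), L2=float(l2)), meta


def side_from_interfaces(
    cell: int, pairs, pixel_size: float
) -> tuple[np.ndarray, float]:
    """Build a ``(side_pixels, length_um)`` site from ``(interface, mask)``
    pairs; ``mask=None`` takes the whole interface."""
    px = []
    n_faces = 0
    for itf, mask in pairs:
        if not isinstance(itf, Interface):
            raise TypeError("expected (Interface, mask) pairs")
        sel = np.ones(len(itf), dtype=bool) if mask is None else np.asarray(mask, bool)
        px.append(itf.side_pixels(cell)[sel])
        n_faces += int(sel.sum())
    if n_faces == 0:
        raise EmptyInputError("site contains no faces")
    return np.vstack(px), n_faces * pixel_size
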
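"""Seeded synthetic vein cross-sections with full ground truth.

The generator emulates the anatomy of an Arabidopsis leaf minor vein as a
seeded Voronoi tessellation of hand-placed generator points: xylem (XY)
adaxial, the phloem (SE / CC / PP) abaxial, and a bundle-sheath (BS) ring
enclosing the bundle.  Image row index increases abaxially, i.e. the bottom
image edge is the abaxial side (the side the microscope images from).

Two channels are rendered.  Channel 0 (wall stain) draws every cell/cell
boundary as a band of fixed primary-wall half-width; wall-ingrowth deposition
is rendered as a local thickening of that band by a factor ``k`` on the PP
side of the covered arc.  Channel 1 (membrane marker) deposits fluorescence
only on PP-cell boundary ribbons, with per-unit-length density scaled by the
local membrane amplification ``k`` where ingrowths are present — mimicking a
plasma-membrane sucrose-transporter fusion whose surface area is amplified by
the ingrowth.

A depth-dependent multiplicative attenuation ``exp(-coef * depth)`` (depth
measured adaxially from the abaxial image edge) is applied identically to
both channels; this is precisely the nuisance the calibrated relative
intensity F is designed to cancel.  Noise is additive Gaussian, clipped at
zero; Poisson shot noise is deliberately omitted (a documented
simplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.spatial import cKDTree

from . import geometry
from .errors import ConfigError, GeometryError, EmptyInputError
from .image import CellMap, VeinImage

#: Primary-wall half-width in pixels (per side of a boundary face).
WALL_HALF_PX = 3

#: Fraction of the frame's short edge used as the vein (BS ring) outer radius.
_VEIN_RADIUS_FRAC = 0.46

_POSITIONS = ("abaxial", "middle", "adaxial")


@dataclass(frozen=True)
class IngrowthSpec:
    """Target deposition for one PP cell.

    ``se`` / ``cc``: target coverage fraction (0–1) applied to each SE-facing
    / CC-facing interface of the cell.  ``k``: wall-thickness and membrane
    amplification factor over the covered arc (>= 1; 1 = no deposition).
    """

    se: float = 0.0
    cc: float = 0.0
    k: float = 1.0


#: Generator presets mirroring the five canonical deposition classes:
#: I no ingrowths; II partial SE coverage; III full SE coverage with a small
#: CC portion; IV full SE plus considerable CC coverage; V full SE and full
#: CC coverage.
CLASS_PRESETS = {
    "I": IngrowthSpec(0.0, 0.0, 1.0),
    "II": IngrowthSpec(0.5, 0.0, 3.0),
    "III": IngrowthSpec(1.0, 0.0, 3.0),
    "IV": IngrowthSpec(1.0, 0.5, 3.0),
    "V": IngrowthSpec(1.0, 1.0, 3.0),
}


@dataclass
class VeinConfig:
    """Generator configuration.

    Defaults describe a typical mature minor vein: ~5 companion cells, ~4
    sieve elements, 3 xylem vessels, a 6-cell bundle-sheath ring and two
    abaxially positioned PP transfer cells bearing full SE-interface
    coverage with a small CC portion (a Class III morphology).

    Intensity scales are arbitrary units on a 16-bit range; the membrane
    marker density (AU per µm of membrane) and the additive noise sigma are
    chosen so the dimmest membrane of interest stays an order of magnitude
    above the noise floor, as in a well-exposed confocal frame.
    """

    n_xy: int = 3
    n_se: int = 4
    n_cc: int = 5
    n_bs: int = 6
    n_other: int = 0
    pp_positions: tuple[str, ...] = ("abaxial", "abaxial")
    ingrowth_specs: tuple[IngrowthSpec, ...] | None = None
    pp_marker_factors: tuple[float, ...] | None = None
    marker_density: float = 5000.0  # AU per µm of membrane
    attenuation_coef: float = 0.004  # per µm of depth
    pixel_size: float = 0.2  # µm per pixel
    noise_sd: float = 20.0  # additive Gaussian sigma, AU
    wall_intensity: float = 3000.0  # AU of the wall stain band
    shape: tuple[int, int] = (512, 512)
    seed: int = 0

    def __post_init__(self) -> None:
        self.pp_positions = tuple(self.pp_positions)
        n_pp = len(self.pp_positions)
        if self.ingrowth_specs is None:
            self.ingrowth_specs = tuple(CLASS_PRESETS["III"] for _ in range(n_pp))
        self.ingrowth_specs = tuple(
            IngrowthSpec(**s) if isinstance(s, dict) else s for s in self.ingrowth_specs
        )
        if self.pp_marker_factors is None:
            self.pp_marker_factors = tuple(1.0 for _ in range(n_pp))
        self.pp_marker_factors = tuple(float(f) for f in self.pp_marker_factors)
        self.validate()

    @property
    def n_pp(self) -> int:
        return len(self.pp_positions)

    def validate(self) -> None:
        if min(self.n_xy, self.n_se, self.n_cc, self.n_bs, self.n_other) < 0:
            raise ConfigError("cell counts must be >= 0")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.attenuation_coef < 0:
            raise ConfigError("attenuation_coef must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for p in self.pp_positions:
            if p not in _POSITIONS:
                raise ConfigError(f"unknown PP position {p!r}")
        if len(self.ingrowth_specs) != self.n_pp:
            raise ConfigError("one ingrowth spec required per PP cell")
        if len(self.pp_marker_factors) != self.n_pp:
            raise ConfigError("one marker factor required per PP cell")
        for s in self.ingrowth_specs:
            if not (0.0 <= s.se <= 1.0 and 0.0 <= s.cc <= 1.0):
                raise ConfigError("coverage fractions must lie in [0, 1]")
            if s.k < 1.0:
                raise ConfigError("thickness amplification k must be >= 1")
        if any(s.se > 0 for s in self.ingrowth_specs) and self.n_se < 1:
            raise ConfigError("SE-interface coverage requested but no SE cells")
        if any(s.cc > 0 for s in self.ingrowth_specs) and self.n_cc < 1:
            raise ConfigError("CC-interface coverage requested but no CC cells")
        if any(f <= 0 for f in self.pp_marker_factors):
            raise ConfigError("marker factors must be positive")

    # ------------------------------------------------------------------ I/O
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["ingrowth_specs"] = [asdict(s) for s in self.ingrowth_specs]
        d["pp_positions"] = list(self.pp_positions)
        d["pp_marker_factors"] = list(self.pp_marker_factors)
        d["shape"] = list(self.shape)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VeinConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["shape"] = tuple(d["shape"])
        d["ingrowth_specs"] = tuple(IngrowthSpec(**s) for s in d["ingrowth_specs"])
        return cls(**d)


def class_preset_config(cls_name: str, seed: int = 0, **overrides) -> VeinConfig:
    """A vein whose PP cells all carry the canonical deposition preset
    for class ``cls_name`` in {'I'..'V'}."""
    if cls_name not in CLASS_PRESETS:
        raise ConfigError(f"unknown class preset {cls_name!r}")
    spec = CLASS_PRESETS[cls_name]
    positions = overrides.pop("pp_positions", ("abaxial", "abaxial"))
    return VeinConfig(
        pp_positions=positions,
        ingrowth_specs=tuple(spec for _ in positions),
        seed=seed,
        **overrides,
    )


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated vein image."""

    cell_map: CellMap
    interfaces: dict  # (a, b) -> geometry.Interface with truth ingrowth_mask
    covered_k: dict  # (a, b) -> amplification k of the covered arc
    marker_factors: dict  # PP label -> relative marker density factor
    positions: dict  # PP label -> configured position class
    attenuation_map: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    config: VeinConfig | None = None

    def true_F(self, ref_cell: int, test_cell: int) -> float:
        """Intended relative marker density of test vs reference cell."""
        return self.marker_factors[test_cell] / self.marker_factors[ref_cell]

    @property
    def pp_cells(self) -> list[int]:
        return sorted(self.marker_factors)

    def interfaces_of(self, cell: int, *types: str) -> list:
        """Truth interfaces of ``cell``, optionally restricted to neighbour
        types."""
        out = []
        for (a, b), itf in sorted(self.interfaces.items()):
            if cell not in (a, b):
                continue
            if types and self.cell_map.types[itf.other(cell)] not in types:
                continue
            out.append(itf)
        return out

    def cells_table(self) -> pd.DataFrame:
        cm = self.cell_map
        rows = []
        for c in cm.cell_ids:
            rows.append(
                {
                    "label": c,
                    "type": cm.types[c],
                    "position": self.positions.get(c, ""),
                    "marker_factor": self.marker_factors.get(c, np.nan),
                    "area_um2": float((cm.labels == c).sum()) * cm.pixel_size**2,
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# seed-point layout
# --------------------------------------------------------------------------


def _seed_points(config: VeinConfig, rng: np.random.Generator):
    """Generator points (px coords) and their cell types.

    Angle 0 points abaxially (+row); angle pi adaxially.  Radii are fractions
    of the vein radius R.  Layout: BS ring at 0.78 R; xylem cluster around the
    adaxial pole; sieve elements in the abaxial mid-region; companion cells
    flanking them; PP cells at the abaxial rim ("abaxial"), the vein centre
    ("middle") or between xylem and lateral sheath ("adaxial").
    """
    h, w = config.shape
    centre = np.array([h / 2.0, w / 2.0])
    r_vein = _VEIN_RADIUS_FRAC * min(h, w)

    def polar(r_frac: float, theta: float) -> np.ndarray:
        return centre + r_frac * r_vein * np.array([np.cos(theta), np.sin(theta)])

    pts: list[np.ndarray] = []
    types: list[str] = []

    def add(p: np.ndarray, t: str) -> None:
        pts.append(p + rng.normal(0.0, 0.015 * r_vein, 2))
        types.append(t)

    # xylem: one row for small counts, two rows (inner pair shielding the
    # centre) for larger clusters
    if config.n_xy >= 5:
        for th in (np.pi - 0.28, np.pi + 0.28):
            add(polar(0.30, th), "XY")
        n_out = config.n_xy - 2
        for th in np.pi + _spread(n_out, 0.65):
            add(polar(0.54, th), "XY")
    else:
        for th in np.pi + _spread(config.n_xy, 0.55):
            add(polar(0.36, th), "XY")

    for th in _spread(config.n_se, 0.55):
        add(polar(0.30, th), "SE")

    if config.n_cc >= 6:
        # two flanking rings: an inner arc continuing the SE layer laterally
        # and an outer arc between it and the sheath
        for i in range(min(4, config.n_cc)):
            side = 1 if i % 2 == 0 else -1
            mag = 0.95 + 0.65 * (i // 2)
            add(polar(0.30, side * mag), "CC")
        for i in range(config.n_cc - 4):
            side = 1 if i % 2 == 0 else -1
            mag = 0.75 + 0.55 * (i // 2)
            add(polar(0.55, side * mag), "CC")
    else:
        for i in range(config.n_cc):
            side = 1 if i % 2 == 0 else -1
            mag = 0.75 + 0.40 * (i // 2)
            add(polar(0.45, side * mag), "CC")

    # vascular parenchyma filler (OTHER): outer lateral arc inside the sheath
    for i in range(config.n_other):
        side = 1 if i % 2 == 0 else -1
        mag = 1.0 + 0.6 * (i // 2)
        add(polar(0.56, side * mag), "OTHER")

    n_abx = sum(p == "abaxial" for p in config.pp_positions)
    n_mid = sum(p == "middle" for p in config.pp_positions)
    n_adx = sum(p == "adaxial" for p in config.pp_positions)
    abx_angles = iter(_spread(n_abx, 0.20))
    mid_angles = iter(np.linspace(0, 2 * np.pi, n_mid, endpoint=False))
    adx_sides = iter([1, -1] * (n_adx // 2 + 1))
    for pos in config.pp_positions:
        if pos == "abaxial":
            add(polar(0.58, next(abx_angles)), "PP")
        elif pos == "middle":
            add(polar(0.08, next(mid_angles)), "PP")
        else:
            add(polar(0.34, np.pi - 1.15 * next(adx_sides)), "PP")

    for i in range(config.n_bs):
        th = np.pi / config.n_bs + 2 * np.pi * i / config.n_bs
        add(polar(0.78, th), "BS")

    return np.array(pts), types, centre, r_vein


def _spread(n: int, half_width: float) -> np.ndarray:
    """n angles spread symmetrically about 0 with the given half-width."""
    if n <= 0:
        return np.array([])
    if n == 1:
        return np.array([0.0])
    return np.linspace(-half_width, half_width, n)


def _tessellate(
    points: np.ndarray,
    centre: np.ndarray,
    r_vein: float,
    shape: tuple[int, int],
    rim_idx: np.ndarray | None = None,
    r_rim: float | None = None,
) -> np.ndarray:
    """Assign every pixel inside the vein disc to its nearest generator
    point (labels 1..n, 0 outside).

    When ``rim_idx`` / ``r_rim`` are given, pixels beyond ``r_rim`` are
    assigned only among the rim (bundle-sheath) seeds, so the sheath ring
    always encloses the inner tissue.
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2
    inside = d2 <= r_vein**2
    if not inside.any():
        raise GeometryError("vein disc does not intersect the frame")
    labels = np.zeros(shape, dtype=np.int64)
    if rim_idx is not None and r_rim is not None and len(rim_idx):
        outer = inside & (d2 > r_rim**2)
        inner = inside & ~outer
        if outer.any():
            coords = np.stack([rr[outer], cc[outer]], axis=1)
            _, idx = cKDTree(points[rim_idx]).query(coords)
            labels[outer] = rim_idx[idx] + 1
    else:
        inner = inside
    if inner.any():
        coords = np.stack([rr[inner], cc[inner]], axis=1)
        _, idx = cKDTree(points).query(coords)
        labels[inner] = idx + 1
    return labels


def _lloyd_relax(
    points: np.ndarray,
    centre: np.ndarray,
    r_vein: float,
    shape: tuple[int, int],
    rim_idx: np.ndarray | None = None,
    r_rim: float | None = None,
    n_iter: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Tessellate with a few Lloyd iterations (seeds move to their cells'
    centroids).  Relaxation rounds off the thin slivers and acute wedge tips
    raw Voronoi cells develop, giving compact cell shapes like those in real
    vein cross-sections.  Rim (bundle-sheath) seeds keep exclusive claim to
    the outer annulus throughout."""
    labels = _tessellate(points, centre, r_vein, shape, rim_idx, r_rim)
    for _ in range(n_iter):
        sums_r = ndimage.sum_labels(
            np.indices(shape)[0], labels, index=np.arange(1, len(points) + 1)
        )
        sums_c = ndimage.sum_labels(
            np.indices(shape)[1], labels, index=np.arange(1, len(points) + 1)
        )
        counts = ndimage.sum_labels(
            np.ones(shape), labels, index=np.arange(1, len(points) + 1)
        )
        nonempty = counts > 0
        points = points.copy()
        points[nonempty, 0] = sums_r[nonempty] / counts[nonempty]
        points[nonempty, 1] = sums_c[nonempty] / counts[nonempty]
        labels = _tessellate(points, centre, r_vein, shape, rim_idx, r_rim)
    return labels, points


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _enforce_connectivity(labels: np.ndarray) -> np.ndarray:
    """Keep each label's largest 4-connected component; stray pixels are
    reassigned to their most frequent 4-neighbour label."""
    labels = labels.copy()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        comp, n = ndimage.label(labels == lab, structure=_STRUCT4)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        stray = (comp > 0) & (comp != keep)
        rs, cs = np.nonzero(stray)
        for r, c in zip(rs, cs):
            nbr = []
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < labels.shape[0] and 0 <= c2 < labels.shape[1]:
                    v = labels[r2, c2]
                    if v != 0 and v != lab:
                        nbr.append(v)
            labels[r, c] = min(nbr, key=lambda v: (-nbr.count(v), v)) if nbr else 0
    return labels


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------


def _stamp(channel: np.ndarray, coords: np.ndarray, value: float) -> None:
    """Set ``value`` at integer (row, col) coords, ignoring out-of-bounds."""
    if len(coords) == 0:
        return
    h, w = channel.shape
    ok = (coords[:, 0] >= 0) & (coords[:, 0] < h) & (coords[:, 1] >= 0) & (coords[:, 1] < w)
    channel[coords[ok, 0], coords[ok, 1]] = value


def _deposit(channel: np.ndarray, coords: np.ndarray, amounts: np.ndarray) -> None:
    """Accumulate ``amounts`` at integer coords, ignoring out-of-bounds."""
    if len(coords) == 0:
        return
    h, w = channel.shape
    ok = (coords[:, 0] >= 0) & (coords[:, 0] < h) & (coords[:, 1] >= 0) & (coords[:, 1] < w)
    np.add.at(channel, (coords[ok, 0], coords[ok, 1]), amounts[ok])


def _background_faces(labels: np.ndarray, cell: int | None = None) -> np.ndarray:
    """Faces between foreground (or one cell) and background, as (n, 4)
    rows (inner pixel, outer pixel)."""
    fg = labels == cell if cell is not None else labels > 0
    rows = []
    for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
        shifted = np.roll(np.roll(fg, -dr, axis=0), -dc, axis=1)
        bg = labels == 0
        bg_shift = np.roll(np.roll(bg, -dr, axis=0), -dc, axis=1)
        sel = fg & bg_shift
        # roll wraps around the frame edge; drop wrapped rows/cols
        if dr == -1:
            sel[0, :] = False
        if dr == 1:
            sel[-1, :] = False
        if dc == -1:
            sel[:, 0] = False
        if dc == 1:
            sel[:, -1] = False
        rr, cc = np.nonzero(sel)
        if rr.size:
            inner = np.stack([rr, cc], axis=1)
            outer = inner + (dr, dc)
            rows.append(np.hstack([inner, outer]))
    if not rows:
        return np.empty((0, 4), dtype=np.int64)
    return np.vstack(rows).astype(np.int64)


def attenuation_field(
    shape: tuple[int, int], coef: float, pixel_size: float
) -> np.ndarray:
    """Multiplicative attenuation ``exp(-coef * depth)``; depth in µm is
    measured along the adaxial direction from the abaxial (bottom) image
    edge, mimicking imaging from the lower leaf side."""
    h, w = shape
    depth = (h - 1 - np.arange(h, dtype=np.float64)) * pixel_size
    return np.repeat(np.exp(-coef * depth)[:, None], w, axis=1)


def apply_attenuation(
    image: VeinImage, coef: float | None = None, att_field: np.ndarray | None = None
) -> VeinImage:
    """Multiply both channels pixel-wise by the same attenuation factor.

    Either a coefficient (per µm of depth) or a precomputed field may be
    given.  With ``coef == 0`` the image is returned unchanged (as a copy).
    The per-pixel ratio of the two channels is invariant under this
    operation wherever both are positive — the property the calibrated
    relative-intensity statistic exploits.
    """
    if image.channels.ndim != 3 or image.channels.shape[0] != 2:
        raise EmptyInputError("apply_attenuation expects a 2-channel image")
    if att_field is None:
        if coef is None:
            raise ConfigError("give either coef or att_field")
        if coef < 0:
            raise ConfigError("attenuation_coef must be >= 0")
        att_field = attenuation_field(image.shape, coef, image.pixel_size)
    if att_field.shape != image.shape:
        raise EmptyInputError("attenuation field shape mismatch")
    out = image.copy()
    out.channels *= att_field[None, :, :]
    return out


def _choose_covered(
    n_faces: int, coverage: float, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous covered arc of round(coverage * n) faces at a random
    offset.  The rendered fraction differs from the target by at most half a
    face length."""
    mask = np.zeros(n_faces, dtype=bool)
    n_cov = int(round(coverage * n_faces))
    if n_cov <= 0:
        return mask
    if n_cov >= n_faces:
        mask[:] = True
        return mask
    # partial arcs nucleate away from the interface ends where possible, so
    # that only fully covered interfaces fuse with the wall junctions
    if n_cov <= n_faces - 2:
        start = int(rng.integers(1, n_faces - n_cov))
    else:
        start = int(rng.integers(0, n_faces - n_cov + 1))
    mask[start : start + n_cov] = True
    return mask


def _covered_from_end(
    side: np.ndarray, coverage: float, se_pixels: np.ndarray
) -> np.ndarray:
    """Covered arc growing from the interface end nearest the SE interface."""
    n = len(side)
    mask = np.zeros(n, dtype=bool)
    n_cov = int(round(coverage * n))
    if n_cov <= 0:
        return mask
    d_first = np.linalg.norm(se_pixels - side[0], axis=1).min()
    d_last = np.linalg.norm(se_pixels - side[-1], axis=1).min()
    if d_first <= d_last:
        mask[:n_cov] = True
    else:
        mask[n - n_cov :] = True
    return mask


def generate_vein(config: VeinConfig) -> tuple[VeinImage, SyntheticTruth]:
    """Render a synthetic 2-channel vein cross-section with ground truth.

    Deterministic: identical configs (including seed) yield byte-identical
    images.  Raises :class:`GeometryError` if a required PP/SE or PP/CC
    adjacency cannot be realised.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    points, types, centre, r_vein = _seed_points(config, rng)
    if len(points) == 0:
        raise GeometryError("configuration places no cells")

    # estimated pixels per cell must comfortably exceed the wall footprint
    px_per_cell = np.pi * r_vein**2 / len(points)
    if px_per_cell < (6 * WALL_HALF_PX) ** 2:
        raise GeometryError(
            f"{len(points)} cells do not fit a vein of radius {r_vein:.0f} px"
        )

    pp_idx = [i for i, t in enumerate(types) if t == "PP"]
    se_idx = [i for i, t in enumerate(types) if t == "SE"]
    cc_idx = [i for i, t in enumerate(types) if t == "CC"]

    # tessellate; nudge SE/CC seeds toward PP cells whose configured
    # deposition requires the adjacency
    bs_idx = np.array([i for i, t in enumerate(types) if t == "BS"], dtype=np.int64)
    r_rim = 0.86 * r_vein if len(bs_idx) else None
    for attempt in range(5):
        labels, relaxed = _lloyd_relax(
            points, centre, r_vein, config.shape, bs_idx if len(bs_idx) else None, r_rim
        )
        labels = _enforce_connectivity(labels)
        cmap = CellMap(labels, config.pixel_size, dict(zip(range(1, len(types) + 1), types)))
        graph = geometry.build_adjacency(cmap)
        ok = True
        for j, (i_pt, spec) in enumerate(zip(pp_idx, config.ingrowth_specs)):
            pp_lab = i_pt + 1
            nbr_types = {cmap.types[n] for n in graph.neighbors(pp_lab)}
            for need, pool in (("SE", se_idx), ("CC", cc_idx)):
                cov = spec.se if need == "SE" else spec.cc
                if cov > 0 and need not in nbr_types:
                    ok = False
                    if not pool:
                        raise GeometryError(f"no {need} cells to neighbour PP {pp_lab}")
                    d = np.linalg.norm(points[pool] - points[i_pt], axis=1)
                    nearest = pool[int(np.argmin(d))]
                    points[nearest] += 0.35 * (points[i_pt] - points[nearest])
        if ok:
            break
    else:
        raise GeometryError("could not realise required PP/SE/CC adjacencies")

    interfaces = geometry.extract_all_interfaces(cmap, graph)

    # ground-truth covered arcs.  SE arcs nucleate mid-interface; CC arcs
    # grow contiguously from the end adjacent to the SE interface, matching
    # the observed progression of deposition from the SE interface onto the
    # neighbouring CC interfaces.
    covered_k: dict[tuple[int, int], float] = {}
    for j, (i_pt, spec) in enumerate(zip(pp_idx, config.ingrowth_specs)):
        pp_lab = i_pt + 1
        se_px = [
            itf.side_pixels(pp_lab)
            for pair, itf in sorted(interfaces.items())
            if pp_lab in pair and cmap.types[itf.other(pp_lab)] == "SE"
        ]
        se_px = np.vstack(se_px) if se_px else None
        for pair, itf in sorted(interfaces.items()):
            if pp_lab not in pair:
                continue
            other_type = cmap.types[itf.other(pp_lab)]
            cov = {"SE": spec.se, "CC": spec.cc}.get(other_type, 0.0)
            if cov <= 0:
                continue
            if other_type == "CC" and se_px is not None:
                itf.ingrowth_mask = _covered_from_end(
                    itf.side_pixels(pp_lab), cov, se_px
                )
            else:
                itf.ingrowth_mask = _choose_covered(len(itf), cov, rng)
            if itf.ingrowth_mask.any():
                covered_k[pair] = spec.k

    wall = np.zeros(config.shape, dtype=np.float64)
    marker = np.zeros(config.shape, dtype=np.float64)

    # primary wall: an isotropic band of half-width WALL_HALF_PX on each side
    # of every boundary (cell/cell and cell/background)
    seed_mask = np.zeros(config.shape, dtype=bool)
    for pair, itf in sorted(interfaces.items()):
        for px in (itf.faces[:, :2], itf.faces[:, 2:]):
            seed_mask[px[:, 0], px[:, 1]] = True
    bg = _background_faces(labels)
    if len(bg):
        seed_mask[bg[:, 0], bg[:, 1]] = True
    dist_to_wall = ndimage.distance_transform_edt(~seed_mask)
    wall[dist_to_wall <= WALL_HALF_PX - 1] = config.wall_intensity

    # ingrowth: thicken the wall to k times its half-width on the PP side of
    # each covered arc.  A pixel of the PP cell joins the pad iff it lies
    # within the pad depth of the covered arc and is no closer to an
    # uncovered stretch of the same interface (partial arcs end in a clean
    # perpendicular cut).  A fully covered interface's pad therefore fills
    # the wall-junction nooks at its ends, the way real deposition wraps a
    # junction and spills a short way onto the neighbouring interface.
    for pair, k in sorted(covered_k.items()):
        itf = interfaces[pair]
        pp_lab = pair[0] if cmap.types[pair[0]] == "PP" else pair[1]
        side = itf.side_pixels(pp_lab)
        cov_px = side[itf.ingrowth_mask]
        unc_px = side[~itf.ingrowth_mask]
        rr, cc = np.nonzero(labels == pp_lab)
        pix = np.stack([rr, cc], axis=1)
        d_cov, _ = cKDTree(cov_px).query(pix)
        k_px = int(round(k * WALL_HALF_PX))
        sel = d_cov <= k_px - 1
        if len(unc_px):
            d_unc, _ = cKDTree(unc_px).query(pix)
            sel &= d_cov < d_unc
        if not (itf.ingrowth_mask[0] or itf.ingrowth_mask[-1]):
            # interior arc: a short uncovered stub cannot shield the wall
            # junction, so also keep the pad on this interface's own side
            # of the cell's other boundaries
            other = [
                interfaces[p].side_pixels(pp_lab)
                for p in sorted(interfaces)
                if pp_lab in p and p != pair
            ]
            bgf = _background_faces(labels, pp_lab)
            if len(bgf):
                other.append(bgf[:, :2])
            if other:
                d_oth, _ = cKDTree(np.vstack(other)).query(pix)
                sel &= d_cov <= d_oth
        wall[rr[sel], cc[sel]] = config.wall_intensity

    # membrane marker on PP boundary ribbons; density scaled by local k
    marker_factors: dict[int, float] = {}
    positions: dict[int, str] = {}
    for j, i_pt in enumerate(pp_idx):
        pp_lab = i_pt + 1
        factor = config.pp_marker_factors[j]
        marker_factors[pp_lab] = factor
        positions[pp_lab] = config.pp_positions[j]
        base_amt = config.marker_density * config.pixel_size * factor
        for pair, itf in sorted(interfaces.items()):
            if pp_lab not in pair:
                continue
            side = itf.side_pixels(pp_lab)
            step = itf.inward_normals(pp_lab)
            amt = np.full(len(itf), base_amt)
            if pair in covered_k:
                amt[itf.ingrowth_mask] *= covered_k[pair]
            _deposit(marker, side, amt / 2.0)
            _deposit(marker, side + step, amt / 2.0)
        bgf = _background_faces(labels, pp_lab)
        if len(bgf):
            inner, outer = bgf[:, :2], bgf[:, 2:]
            d = inner - outer
            amt = np.full(len(bgf), base_amt)
            _deposit(marker, inner, amt / 2.0)
            _deposit(marker, inner + d, amt / 2.0)

    channels = np.stack([wall, marker])
    att = attenuation_field(config.shape, config.attenuation_coef, config.pixel_size)
    channels = channels * att[None, :, :]
    if config.noise_sd > 0:
        channels = channels + rng.normal(0.0, config.noise_sd, channels.shape)
        channels = np.clip(channels, 0.0, None)

    image = VeinImage(channels, config.pixel_size, meta={"seed": config.seed})
    truth = SyntheticTruth(
        cell_map=cmap,
        interfaces=interfaces,
        covered_k=covered_k,
        marker_factors=marker_factors,
        positions=positions,
        attenuation_map=att,
        config=config,
    )
    return image, truth


# --------------------------------------------------------------------------
# twin-cell fixture: exact-cancellation geometry
# --------------------------------------------------------------------------


def twin_cell_image(
    density_ratio: float = 1.0,
    attenuation_coef: float = 0.0,
    cell_px: int = 40,
    gap_px: int = 12,
    pixel_size: float = 0.2,
    marker_density: float = 5000.0,
    wall_intensity: float = 3000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[VeinImage, CellMap]:
    """Two congruent square PP cells stacked in depth (synthetic fixture).

    Cell 1 sits abaxially (shallow), cell 2 adaxially (deep); cell 2's
    membrane-marker density is ``density_ratio`` times cell 1's.  Because the
    cells are exact translates of each other, the per-pixel exponential
    attenuation factors over corresponding pixels differ by a single
    constant, so the wall-calibrated intensity ratio recovers
    ``density_ratio`` exactly — the closed-form cancellation oracle for the
    F statistic.
    """
    margin = 8
    h = 2 * cell_px + gap_px + 2 * margin
    w = cell_px + 2 * margin
    labels = np.zeros((h, w), dtype=np.int64)
    r2 = margin  # deep (adaxial, top) cell: label 2
    r1 = margin + cell_px + gap_px  # shallow (abaxial, bottom) cell: label 1
    labels[r2 : r2 + cell_px, margin : margin + cell_px] = 2
    labels[r1 : r1 + cell_px, margin : margin + cell_px] = 1
    cmap = CellMap(labels, pixel_size, {1: "PP", 2: "PP"})

    wall = np.zeros((h, w))
    marker = np.zeros((h, w))
    for lab, factor in ((1, 1.0), (2, density_ratio)):
        faces = _background_faces(labels, lab)
        inner, outer = faces[:, :2], faces[:, 2:]
        d = inner - outer
        for m in range(WALL_HALF_PX):
            _stamp(wall, inner + m * d, wall_intensity)
        amt = np.full(len(faces), marker_density * pixel_size * factor)
        _deposit(marker, inner, amt / 2.0)
        _deposit(marker, inner + d, amt / 2.0)

    channels = np.stack([wall, marker])
    att = attenuation_field((h, w), attenuation_coef, pixel_size)
    channels = channels * att[None, :, :]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        channels = np.clip(channels + rng.normal(0, noise_sd, channels.shape), 0, None)
    return VeinImage(channels, pixel_size), cmap


# --------------------------------------------------------------------------
# cohort sampling (summary level)
# --------------------------------------------------------------------------

#: Probability of a PP transfer cell occupying the abaxial position, taken
#: from the printed 156-vein survey (200 abaxial of 339 PP TCs).
P_ABAXIAL = 200.0 / 339.0

#: Distribution of PP-TC counts per vein.  Chosen to match the surveyed mean
#: of ~2.17 PP TCs per vein (339 / 156); veins typically carry a pair, with
#: a substantial minority carrying more.
PP_COUNT_PROBS = {1: 0.28, 2: 0.37, 3: 0.25, 4: 0.10}

#: Per-position deposition-score distributions (score 0-4 = class - 1),
#: emulating the reported abaxial-to-adaxial gradient of wall-ingrowth
#: deposition.
SCORE_P = {"abaxial": 0.75, "middle": 0.5, "adaxial": 0.3}


def sample_cohort(
    n_veins: int = 156,
    p_abaxial: float = P_ABAXIAL,
    rng: np.random.Generator | int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort of minor veins at the summary level.

    Returns ``(veins, pps)``: one row per vein (cell counts) and one row per
    PP transfer cell (vein id, position, deposition score).  Cell-count
    distributions centre on the surveyed per-vein means (~5 CC, ~4 SE, ~2 PP
    TCs); each PP is abaxial with probability ``p_abaxial``, otherwise
    middle or adaxial with equal probability.  Deposition scores follow a
    binomial whose mean decreases from the abaxial to the adaxial position.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = list(PP_COUNT_PROBS)
    probs = np.array([PP_COUNT_PROBS[c] for c in counts])
    probs = probs / probs.sum()
    vein_rows = []
    pp_rows = []
    for v in range(n_veins):
        n_pp = int(rng.choice(counts, p=probs))
        n_cc = 1 + int(rng.poisson(4.0))
        n_se = 1 + int(rng.poisson(3.0))
        n_xy = 1 + int(rng.poisson(2.0))
        vein_rows.append(
            {"vein_id": v, "n_pp_tc": n_pp, "n_cc": n_cc, "n_se": n_se, "n_xy": n_xy}
        )
        for i in range(n_pp):
            if rng.random() < p_abaxial:
                pos = "abaxial"
            else:
                pos = "middle" if rng.random() < 0.5 else "adaxial"
            score = int(rng.binomial(4, SCORE_P[pos]))
            pp_rows.append(
                {"vein_id": v, "pp_index": i, "position": pos, "cell_score": score}
            )
    return pd.DataFrame(vein_rows), pd.DataFrame(pp_rows)
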
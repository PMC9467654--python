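"""Reproduction protocols: the simulation experiments that validate the
pipeline's statistics against generator ground truth.

Each function runs one self-contained study design — calibrated-intensity
recovery, enrichment-factor recovery, deposition-class recovery, cohort
position recovery, t-test calibration — and returns plain numbers.  They
are the package's executable methods section: the same protocols back the
acceptance tests and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import fluorquant as fq
from . import geometry, ingrowth
from .image import VeinImage
from .stats_report import two_sample_t
from .synthetic import (
    CLASS_PRESETS,
    IngrowthSpec,
    SyntheticTruth,
    VeinConfig,
    class_preset_config,
    generate_vein,
    sample_cohort,
    twin_cell_image,
)


def twin_cell_relative_intensity(
    density_ratio: float, attenuation_coef: float
) -> tuple[float, float]:
    """F on the exact-cancellation twin-cell geometry (raw sums, noise-free).

    Returns ``(F, raw_marker_ratio)``: the calibrated statistic recovers the
    true density ratio even while the raw marker ratio is crushed by depth
    attenuation — the closed-form cancellation the statistic exists for.
    """
    img, cmap = twin_cell_image(
        density_ratio=density_ratio, attenuation_coef=attenuation_coef
    )
    reads, _ = fq.measure_cell_pair(img, cmap, 1, 2, raw=True)
    return fq.relative_intensity(reads), reads.S2 / reads.S1


def vein_relative_intensity(seed: int, density_ratio: float = 0.84) -> float:
    """F between two morphologically symmetric PP cells in a rendered vein
    (8-bit thresholded pipeline, default noise and attenuation); the test
    cell's membrane-marker density is ``density_ratio`` times the
    reference's."""
    cfg = VeinConfig(
        seed=seed,
        pp_marker_factors=(1.0, density_ratio),
        ingrowth_specs=(IngrowthSpec(0, 0, 1.0),) * 2,
    )
    img, truth = generate_vein(cfg)
    ref, test = truth.pp_cells
    reads, _ = fq.measure_cell_pair(img, truth.cell_map, ref, test)
    return fq.relative_intensity(reads)


def enrichment_from_truth(
    image: VeinImage, truth: SyntheticTruth, cell: int, raw: bool = False
) -> float:
    """FC for one PP cell with the ingrowth / clear sites designated from
    generator truth (as an analyst would designate them visually), the
    remaining membrane excluded from both reads."""
    cm = truth.cell_map
    se_itfs = truth.interfaces_of(cell, "SE")
    cc_itfs = truth.interfaces_of(cell, "CC")
    cov = [(i, i.ingrowth_mask) for i in se_itfs if i.ingrowth_mask.any()]
    if cov:
        clear = [(i, ~i.ingrowth_mask) for i in se_itfs] + [(i, None) for i in cc_itfs]
    else:
        # no deposition (k = 1): designate the first SE interface as the
        # nominal "ingrowth" site; FC should recover 1
        cov = [(se_itfs[0], None)]
        clear = [(i, None) for i in se_itfs[1:]] + [(i, None) for i in cc_itfs]
    if not clear:
        raise ValueError(f"cell {cell}: no clear-side membrane to compare against")
    used = {i.pair for i in se_itfs} | {i.pair for i in cc_itfs}
    excl = [
        i.side_pixels(cell)
        for p, i in truth.interfaces.items()
        if cell in p and i.pair not in used
    ]
    reads, _ = fq.measure_enrichment(
        image,
        cm,
        cell,
        fq.side_from_interfaces(cell, cov, cm.pixel_size),
        fq.side_from_interfaces(cell, clear, cm.pixel_size),
        raw=raw,
        exclude=np.vstack(excl) if excl else None,
    )
    return fq.enrichment(reads)


def enrichment_recovery(
    k: float, n_seeds: int = 50, seed_base: int = 0, **config_overrides
) -> list:
    """FC of the first PP cell over ``n_seeds`` veins rendered with
    membrane amplification ``k`` on half of each SE interface."""
    out = []
    for seed in range(seed_base, seed_base + n_seeds):
        cfg = VeinConfig(
            seed=seed,
            ingrowth_specs=(IngrowthSpec(0.5, 0, k), IngrowthSpec(0.5, 0, k)),
            **config_overrides,
        )
        img, truth = generate_vein(cfg)
        try:
            out.append(enrichment_from_truth(img, truth, truth.pp_cells[0]))
        except ValueError:
            continue
    return out


def class_recovery(
    seeds, noise_sd: float | None = None, classes=("I", "II", "III", "IV", "V")
) -> tuple[int, int]:
    """Classify PP cells of preset veins; returns (correct, total).

    ``noise_sd=None`` keeps the generator default.  Cells whose CC
    interfaces are too short to resolve the IV/V distinction are excluded
    (see :func:`veinquant.ingrowth.cc_classifiable`).
    """
    kw = {} if noise_sd is None else {"noise_sd": noise_sd}
    ok = tot = 0
    for cls in classes:
        for seed in seeds:
            cfg = class_preset_config(cls, seed=seed, **kw)
            img, truth = generate_vein(cfg)
            cm = truth.cell_map
            wall_mask = ingrowth.binarize_wall(img.wall)
            for pp in truth.pp_cells:
                if cls in ("IV", "V") and not ingrowth.cc_classifiable(
                    truth.interfaces, cm, pp
                ):
                    continue
                dep = ingrowth.classify_cell(
                    img.wall, cm, pp, truth.interfaces, wall_mask=wall_mask
                )
                tot += 1
                ok += dep.value == cls
    return ok, tot


def cohort_abaxial_coverage(
    n_replicates: int = 100,
    n_veins: int = 156,
    p_abaxial: float = 200.0 / 339.0,
    seed: int = 0,
) -> tuple[int, list]:
    """Draw cohorts at the surveyed abaxial probability and count how many
    reproduce the abaxial count within the central 95% binomial interval.

    Returns ``(n_inside, pct_values)``.
    """
    rng = np.random.default_rng(seed)
    inside = 0
    pcts = []
    for _ in range(n_replicates):
        _, pps = sample_cohort(n_veins, p_abaxial, rng=int(rng.integers(2**31)))
        n = len(pps)
        k = int((pps.position == "abaxial").sum())
        lo = sps.binom.ppf(0.025, n, p_abaxial)
        hi = sps.binom.ppf(0.975, n, p_abaxial)
        inside += bool(lo <= k <= hi)
        pcts.append(100.0 * k / n)
    return inside, pcts


def ttest_type1_error(
    n_reps: int = 10_000, n_per_group: int = 10, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of the pooled t test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(0, 1, n_per_group)
        y = rng.normal(0, 1, n_per_group)
        _, _, p = two_sample_t(x, y)
        rejections += p < alpha
    return rejections / n_reps
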
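"""Generator contracts: determinism, counts, coverage fidelity, wall and
marker rendering, attenuation physics, cohort sampling."""

import numpy as np
import pytest

from veinquant import geometry, ingrowth
from veinquant.errors import ConfigError, GeometryError, EmptyInputError
from veinquant.synthetic import (
    IngrowthSpec,
    VeinConfig,
    apply_attenuation,
    attenuation_field,
    generate_vein,
    sample_cohort,
    twin_cell_image,
)

from conftest import cached_vein


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"pixel_size": 0.0},
            {"noise_sd": -1.0},
            {"n_se": -1},
            {"pp_positions": ("sideways",)},
            {"ingrowth_specs": (IngrowthSpec(se=1.2),) * 2},
            {"ingrowth_specs": (IngrowthSpec(k=0.5),) * 2},
            {"ingrowth_specs": (IngrowthSpec(se=0.5),) * 2, "n_se": 0},
            {"pp_marker_factors": (1.0,)},
        ],
    )
    def test_invalid_configs_raise(self, kw):
        with pytest.raises(ConfigError):
            VeinConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = VeinConfig(seed=7, pp_positions=("abaxial", "adaxial"), noise_sd=5.0)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = VeinConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg

    def test_infeasible_geometry_raises(self):
        with pytest.raises(GeometryError):
            generate_vein(VeinConfig(shape=(48, 48), n_bs=12, n_cc=12, n_se=8))


class TestGenerate:
    def test_determinism_bit_identical(self):
        a, _ = generate_vein(VeinConfig(seed=11, shape=(256, 256)))
        b, _ = generate_vein(VeinConfig(seed=11, shape=(256, 256)))
        assert np.array_equal(a.channels, b.channels)

    def test_different_seeds_differ(self):
        a, _ = generate_vein(VeinConfig(seed=11, shape=(256, 256)))
        b, _ = generate_vein(VeinConfig(seed=12, shape=(256, 256)))
        assert not np.array_equal(a.channels, b.channels)

    def test_cell_counts_match_config(self, default_vein):
        img, truth = default_vein
        cm = truth.cell_map
        cfg = truth.config
        assert len(cm.cells_of_type("XY")) == cfg.n_xy
        assert len(cm.cells_of_type("SE")) == cfg.n_se
        assert len(cm.cells_of_type("CC")) == cfg.n_cc
        assert len(cm.cells_of_type("BS")) == cfg.n_bs
        assert len(cm.cells_of_type("PP")) == cfg.n_pp

    def test_zero_coverage_means_uniform_wall(self):
        img, truth = cached_vein(
            VeinConfig(
                seed=2,
                noise_sd=0.0,
                attenuation_coef=0.0,
                ingrowth_specs=(IngrowthSpec(0, 0, 1.0),) * 2,
            )
        )
        cm = truth.cell_map
        wm = ingrowth.binarize_wall(img.wall)
        for pp in truth.pp_cells:
            profs = ingrowth.cell_profiles(img.wall, cm, pp, truth.interfaces, wall_mask=wm)
            base = ingrowth.cell_baseline(profs)
            for prof in profs.values():
                prof.baseline = base
                assert not ingrowth.detect_ingrowth(prof).any()

    def test_coverage_fidelity_rendered_vs_configured(self):
        """Rendered covered fraction is within half a face of the target."""
        rng = np.random.default_rng(0)
        for trial in range(12):
            cov_se = float(rng.uniform(0.1, 0.9))
            cov_cc = float(rng.uniform(0.0, 0.9))
            cfg = VeinConfig(
                seed=int(rng.integers(2**31)),
                noise_sd=0.0,
                ingrowth_specs=(IngrowthSpec(cov_se, cov_cc, 2.0),) * 2,
            )
            img, truth = generate_vein(cfg)
            cm = truth.cell_map
            for pp in truth.pp_cells:
                for itf in truth.interfaces_of(pp, "SE"):
                    got = itf.ingrowth_mask.sum() / len(itf)
                    assert abs(got - cov_se) <= 0.5 / len(itf) + 1e-9
                for itf in truth.interfaces_of(pp, "CC"):
                    got = itf.ingrowth_mask.sum() / len(itf)
                    assert abs(got - cov_cc) <= 0.5 / len(itf) + 1e-9

    def test_ingrowth_only_on_pp_boundaries(self, default_vein):
        _, truth = default_vein
        cm = truth.cell_map
        for pair in truth.covered_k:
            assert any(cm.types[c] == "PP" for c in pair)

    def test_marker_scales_with_amplification(self):
        """Full SE coverage at k=3: per-length marker on that interface is
        3x an uncovered interface's, within 2% (noise-free, interior
        faces)."""
        cfg = VeinConfig(
            seed=4,
            noise_sd=0.0,
            attenuation_coef=0.0,
            ingrowth_specs=(IngrowthSpec(1.0, 0.0, 3.0), IngrowthSpec(0, 0, 1.0)),
        )
        img, truth = generate_vein(cfg)
        cm = truth.cell_map
        pp = truth.pp_cells[0]

        def per_length(itf, interior=4):
            side = itf.side_pixels(pp)[interior:-interior]
            steps = itf.inward_normals(pp)[interior:-interior]
            s = img.marker[side[:, 0], side[:, 1]].sum()
            inner = side + steps
            s += img.marker[inner[:, 0], inner[:, 1]].sum()
            return s / (len(side) * cm.pixel_size)

        covered = [i for i in truth.interfaces_of(pp, "SE") if i.ingrowth_mask.all()]
        plain = [
            i
            for i in truth.interfaces_of(pp)
            if not i.ingrowth_mask.any() and len(i) > 12
        ]
        assert covered and plain
        ratio = per_length(covered[0]) / per_length(plain[0])
        assert ratio == pytest.approx(3.0, rel=0.02)

    def test_attenuation_in_unit_interval(self, default_vein):
        _, truth = default_vein
        att = truth.attenuation_map
        assert (att > 0).all() and (att <= 1).all()


class TestAttenuation:
    def test_zero_coef_is_identity(self, default_vein):
        img, _ = default_vein
        out = apply_attenuation(img, coef=0.0)
        assert np.array_equal(out.channels, img.channels)

    def test_channel_ratio_invariant(self):
        img, truth = cached_vein(VeinConfig(seed=5, noise_sd=0.0, attenuation_coef=0.0))
        out = apply_attenuation(img, coef=0.02)
        both = (img.wall > 0) & (img.marker > 0)
        ratio_before = img.wall[both] / img.marker[both]
        ratio_after = out.wall[both] / out.marker[both]
        np.testing.assert_allclose(ratio_after, ratio_before, rtol=1e-9)

    def test_exponential_depth_halving(self):
        """Two identical cells 10 µm apart in depth, coef = ln2/10:
        the deeper cell's mean intensity is half the shallower one's."""
        # 40 px cell + 10 px gap = 50 px = 10 µm at 0.2 µm/px
        img, cmap = twin_cell_image(
            density_ratio=1.0,
            attenuation_coef=np.log(2) / 10.0,
            cell_px=40,
            gap_px=10,
        )
        shallow = img.marker[cmap.mask(1)].mean()
        deep = img.marker[cmap.mask(2)].mean()
        assert deep / shallow == pytest.approx(0.5, rel=0.01)

    def test_attenuation_neutrality_per_cell(self):
        """(marker sum)/(wall sum) per cell is invariant to 6 significant
        digits under any per-cell multiplicative attenuation (noise-free) —
        the cancellation the calibrated intensity statistic relies on."""
        img, truth = cached_vein(VeinConfig(seed=6, noise_sd=0.0, attenuation_coef=0.0))
        cm = truth.cell_map
        rng = np.random.default_rng(0)
        factors = {c: float(rng.uniform(0.2, 1.0)) for c in cm.cell_ids}
        field = np.ones(cm.labels.shape)
        for c, f in factors.items():
            field[cm.labels == c] = f
        out = apply_attenuation(img, att_field=field)
        for pp in truth.pp_cells:
            m = cm.mask(pp)
            before = img.marker[m].sum() / img.wall[m].sum()
            after = out.marker[m].sum() / out.wall[m].sum()
            assert after == pytest.approx(before, rel=1e-6)

    def test_depthwise_attenuation_near_neutral(self):
        """With the smooth depth-dependent field, per-cell sum ratios move
        by well under 1% — the residual the calibration absorbs."""
        img, truth = cached_vein(VeinConfig(seed=6, noise_sd=0.0, attenuation_coef=0.0))
        out = apply_attenuation(img, coef=0.01)
        cm = truth.cell_map
        for pp in truth.pp_cells:
            m = cm.mask(pp)
            before = img.marker[m].sum() / img.wall[m].sum()
            after = out.marker[m].sum() / out.wall[m].sum()
            assert after == pytest.approx(before, rel=0.01)

    def test_wrong_channel_count_raises(self):
        from veinquant.image import VeinImage

        with pytest.raises(EmptyInputError):
            VeinImage(np.zeros((3, 8, 8)), 0.2)

    def test_field_shape_and_edge(self):
        f = attenuation_field((10, 4), coef=0.1, pixel_size=1.0)
        assert f.shape == (10, 4)
        assert f[-1, 0] == pytest.approx(1.0)  # abaxial edge: depth 0
        assert f[0, 0] == pytest.approx(np.exp(-0.9))


class TestCohortSampling:
    def test_deterministic(self):
        v1, p1 = sample_cohort(50, rng=9)
        v2, p2 = sample_cohort(50, rng=9)
        assert v1.equals(v2) and p1.equals(p2)

    def test_shapes_and_ranges(self):
        veins, pps = sample_cohort(200, rng=1)
        assert len(veins) == 200
        assert set(pps["position"]) <= {"abaxial", "middle", "adaxial"}
        assert pps["cell_score"].between(0, 4).all()
        assert veins["n_pp_tc"].between(1, 4).all()
        # surveyed means: ~5 CC, ~4 SE, ~2.2 PP TCs per vein
        assert veins["n_cc"].mean() == pytest.approx(5.0, abs=0.7)
        assert veins["n_se"].mean() == pytest.approx(4.0, abs=0.7)
        assert veins["n_pp_tc"].mean() == pytest.approx(2.17, abs=0.3)

    def test_score_gradient(self):
        _, pps = sample_cohort(400, rng=2)
        by_pos = pps.groupby("position")["cell_score"].mean()
        assert by_pos["abaxial"] > by_pos["middle"] > by_pos["adaxial"]


class TestImageIO:
    def test_ome_tiff_round_trip(self, tmp_path, default_vein):
        img, truth = default_vein
        path = tmp_path / "vein.ome.tif"
        img.save(path)
        from veinquant.image import VeinImage

        back = VeinImage.load(path)
        assert back.pixel_size == pytest.approx(img.pixel_size)
        np.testing.assert_allclose(
            back.channels, np.clip(np.rint(img.channels), 0, 65535), atol=0
        )

    def test_label_map_round_trip(self, tmp_path, default_vein):
        _, truth = default_vein
        cm = truth.cell_map
        cm.save(tmp_path / "l.tif", tmp_path / "t.csv")
        from veinquant.image import CellMap

        back = CellMap.load(tmp_path / "l.tif", tmp_path / "t.csv", cm.pixel_size)
        assert np.array_equal(back.labels, cm.labels)
        assert back.types == cm.types
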
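"""Adjacency graphs, interfaces, positions and vein size against
brute-force oracles and hand-computable fixtures."""

import networkx as nx
import numpy as np
import pytest

from veinquant import geometry
from veinquant.errors import (
    AdjacencyError,
    AxisInferenceError,
    ClassificationError,
    EmptyInputError,
)
from veinquant.image import CellMap
from veinquant.synthetic import VeinConfig

from conftest import cached_vein, random_label_map


def brute_force_edges(cmap: CellMap) -> set:
    """Oracle: exhaustive per-pixel 4-neighbour scan."""
    lab = cmap.labels
    edges = set()
    h, w = lab.shape
    for r in range(h):
        for c in range(w):
            a = lab[r, c]
            if a == 0:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w:
                    b = lab[r2, c2]
                    if b != 0 and b != a:
                        edges.add((min(a, b), max(a, b)))
    return edges


def brute_force_faces(cmap: CellMap, a: int, b: int) -> int:
    """Oracle: count shared pixel faces between two labels."""
    lab = cmap.labels
    n = 0
    h, w = lab.shape
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 < h and c2 < w:
                    pair = {lab[r, c], lab[r2, c2]}
                    if pair == {a, b}:
                        n += 1
    return n


class TestAdjacency:
    def test_stripes(self, stripes_map):
        g = geometry.build_adjacency(stripes_map)
        assert set(map(tuple, map(sorted, g.edges))) == {(1, 2), (2, 3)}

    def test_corner_touch_is_not_adjacent(self, corner_touch_map):
        g = geometry.build_adjacency(corner_touch_map)
        assert g.number_of_edges() == 0
        assert set(g.nodes) == {1, 2}

    def test_empty_map_raises(self):
        with pytest.raises(EmptyInputError):
            geometry.build_adjacency(CellMap(np.zeros((4, 4), dtype=int), 0.2, {}))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        cmap = random_label_map(np.random.default_rng(seed))
        g = geometry.build_adjacency(cmap)
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == brute_force_edges(cmap)


class TestInterface:
    def test_square_pair_length(self):
        labels = np.zeros((10, 20), dtype=np.int64)
        labels[:, :10] = 1
        labels[:, 10:] = 2
        cmap = CellMap(labels, 0.2, {1: "PP", 2: "SE"})
        itf = geometry.extract_interface(cmap, 1, 2)
        assert len(itf) == 10
        assert itf.length == pytest.approx(2.0)

    def test_l_shaped_boundary(self):
        # 7 shared faces along an L-shaped boundary, 0.5 µm pixels
        labels = np.ones((6, 6), dtype=np.int64)
        labels[:4, :3] = 2  # upper-left block: 4 bottom faces + 3 side faces...
        cmap = CellMap(labels, 0.5, {1: "CC", 2: "PP"})
        itf = geometry.extract_interface(cmap, 1, 2)
        assert len(itf) == brute_force_faces(cmap, 1, 2) == 7
        assert itf.length == pytest.approx(3.5)

    def test_symmetry(self, stripes_map):
        a = geometry.extract_interface(stripes_map, 1, 2)
        b = geometry.extract_interface(stripes_map, 2, 1)
        assert np.array_equal(a.faces, b.faces)
        assert a.length == b.length

    def test_non_adjacent_raises(self, stripes_map):
        with pytest.raises(AdjacencyError):
            geometry.extract_interface(stripes_map, 1, 3)

    @pytest.mark.parametrize("seed", range(8))
    def test_length_matches_face_count_oracle(self, seed):
        cmap = random_label_map(np.random.default_rng(100 + seed))
        g = geometry.build_adjacency(cmap)
        for a, b in g.edges:
            itf = geometry.extract_interface(cmap, a, b)
            assert len(itf) == brute_force_faces(cmap, *sorted((a, b)))
            assert itf.length == pytest.approx(len(itf) * cmap.pixel_size)

    @pytest.mark.parametrize("seed", range(5))
    def test_length_additivity_equals_internal_perimeter(self, seed):
        # no-background map: each cell's interface lengths sum to its
        # internal 4-connected perimeter
        cmap = random_label_map(np.random.default_rng(200 + seed))
        g = geometry.build_adjacency(cmap)
        interfaces = geometry.extract_all_interfaces(cmap, g)
        lab = cmap.labels
        for cell in cmap.cell_ids:
            perim = 0
            mask = lab == cell
            rr, cc = np.nonzero(mask)
            for r, c in zip(rr, cc):
                for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < lab.shape[0] and 0 <= c2 < lab.shape[1]:
                        if lab[r2, c2] != cell and lab[r2, c2] != 0:
                            perim += 1
            total = sum(len(i) for p, i in interfaces.items() if cell in p)
            assert total == perim

    def test_face_ordering_is_chain(self):
        labels = np.zeros((10, 20), dtype=np.int64)
        labels[:, :10] = 1
        labels[:, 10:] = 2
        cmap = CellMap(labels, 0.2, {1: "PP", 2: "SE"})
        itf = geometry.extract_interface(cmap, 1, 2)
        mid = (itf.faces[:, :2] + itf.faces[:, 2:]) / 2
        gaps = np.linalg.norm(np.diff(mid, axis=0), axis=1)
        assert (gaps <= 1.01).all()


class TestAxis:
    def test_centroid_difference(self):
        labels = np.zeros((60, 100), dtype=np.int64)
        labels[5:16, 45:56] = 1  # XY centroid at (10, 50)
        labels[35:46, 45:56] = 2  # SE centroid at (40, 50)
        cmap = CellMap(labels, 0.2, {1: "XY", 2: "SE"})
        assert geometry.abaxial_axis(cmap) == pytest.approx([1.0, 0.0])

    def test_missing_tissue_raises(self, corner_touch_map):
        labels = np.zeros((4, 4), dtype=np.int64)
        labels[:2] = 1
        with pytest.raises(AxisInferenceError):
            geometry.abaxial_axis(CellMap(labels, 0.2, {1: "XY"}))

    @pytest.mark.parametrize("seed", range(10))
    def test_synthetic_axis_within_15_degrees(self, seed):
        img, truth = cached_vein(VeinConfig(seed=seed, noise_sd=0.0))
        axis = geometry.abaxial_axis(truth.cell_map)
        cosang = float(np.clip(axis @ truth.axis, -1, 1))
        assert np.degrees(np.arccos(cosang)) < 15.0


class TestPosition:
    def _ladder_map(self):
        # column of cells: BS(1) - A(2) - B(3) - C(4) - BS(5); abaxial = +row
        labels = np.zeros((50, 10), dtype=np.int64)
        for i in range(5):
            labels[i * 10 : (i + 1) * 10] = i + 1
        types = {1: "BS", 2: "PP", 3: "PP", 4: "PP", 5: "BS"}
        return CellMap(labels, 0.2, types)

    def test_hop_rules(self):
        cmap = self._ladder_map()
        g = geometry.build_adjacency(cmap)
        axis = np.array([1.0, 0.0])  # +row is abaxial; BS 5 is abaxial half
        # cell 4 is 1 hop from abaxial BS -> abaxial
        assert geometry.classify_position(4, g, cmap, axis).value == "abaxial"
        # cell 3 is 2 hops from both halves -> resolved by own centroid (middle row)
        pc = geometry.classify_position(3, g, cmap, axis)
        assert pc.hops_to_abaxial_BS == 2 and pc.hops_to_adaxial_BS == 2
        # cell 2 is adjacent to the adaxial BS -> adaxial
        assert geometry.classify_position(2, g, cmap, axis).value == "adaxial"

    def test_middle_at_three_hops(self):
        labels = np.zeros((70, 10), dtype=np.int64)
        for i in range(7):
            labels[i * 10 : (i + 1) * 10] = i + 1
        types = {1: "BS", 2: "CC", 3: "SE", 4: "PP", 5: "SE", 6: "CC", 7: "BS"}
        cmap = CellMap(labels, 0.2, types)
        g = geometry.build_adjacency(cmap)
        pc = geometry.classify_position(4, g, cmap, np.array([1.0, 0.0]))
        assert pc.value == "middle"
        assert pc.hops_to_abaxial_BS == 3 and pc.hops_to_adaxial_BS == 3

    def test_no_bs_raises(self, stripes_map):
        g = geometry.build_adjacency(stripes_map)
        with pytest.raises(ClassificationError):
            geometry.classify_position(2, g, stripes_map, np.array([1.0, 0.0]))

    @pytest.mark.parametrize(
        "kw",
        [
            {"pp_positions": ("abaxial", "abaxial")},
            {"pp_positions": ("abaxial", "adaxial")},
            {
                "pp_positions": ("middle", "abaxial", "abaxial"),
                "n_cc": 8,
                "n_xy": 5,
                "n_se": 4,
                "n_bs": 8,
                "n_other": 6,
            },
        ],
        ids=["abaxial-pair", "abaxial-adaxial", "shielded-middle"],
    )
    def test_synthetic_position_recovery(self, kw):
        """Configured PP positions are recovered exactly on noise-free
        synthetic veins."""
        from veinquant.synthetic import generate_vein

        for seed in range(12):
            img, truth = cached_vein(VeinConfig(seed=seed, noise_sd=0.0, **kw))
            cmap = truth.cell_map
            g = geometry.build_adjacency(cmap)
            axis = geometry.abaxial_axis(cmap)
            for pp in truth.pp_cells:
                got = geometry.classify_position(pp, g, cmap, axis).value
                assert got == truth.positions[pp], (kw, seed, pp)


class TestVeinSize:
    def test_single_cell(self):
        labels = np.zeros((20, 20), dtype=np.int64)
        labels[:10, :10] = 1  # 100 px
        cmap = CellMap(labels, 0.2, {1: "XY"})
        assert geometry.vein_size(cmap) == pytest.approx(4.0)

    def test_bs_only_is_zero(self):
        labels = np.ones((5, 5), dtype=np.int64)
        assert geometry.vein_size(CellMap(labels, 0.2, {1: "BS"})) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pixel_tally(self, seed):
        cmap = random_label_map(np.random.default_rng(300 + seed))
        expect = 0
        for c in cmap.cell_ids:
            if cmap.types[c] in ("XY", "SE", "CC", "PP"):
                expect += int((cmap.labels == c).sum())
        assert geometry.vein_size(cmap) == pytest.approx(expect * 0.25**2)
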
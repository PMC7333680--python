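"""Reading and writing reconstruction files: SWC, Neurolucida XML/ASC."""

from pathlib import Path

import numpy as np
import pytest

from neurodensity import (
    Morphology,
    Scene,
    detect_format,
    read_asc,
    read_neurolucida_xml,
    read_swc,
    write_swc,
)
from neurodensity import fixtures as fx
from neurodensity.io import MorphologyParseError, UnsupportedFormatError

MINIMAL_SWC = """# comment line
1 1 0 0 0 5 -1
2 3 0 10 0 1 1
3 3 0 20 0 1 2
"""


class TestReadSwc:
    def test_minimal_chain(self, tmp_path):
        p = tmp_path / "chain.swc"
        p.write_text(MINIMAL_SWC)
        m = read_swc(p)
        assert len(m) == 3
        assert len(m.edges) == 2
        assert list(m.compartments) == ["soma", "dendrite", "dendrite"]
        np.testing.assert_allclose(m.positions[0], [0, 0, 0])
        assert m.radii[0] == 5.0

    def test_vertex_count_equals_record_count(self, tmp_path, rng):
        m = fx.make_random_tree(7)
        p = tmp_path / "r.swc"
        write_swc(m, p)
        n_records = sum(
            1 for line in p.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        )
        assert read_swc(p).n_vertices == n_records == len(m)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 zero 10 0 1\n")
        with pytest.raises(MorphologyParseError, match="bad.swc:2"):
            read_swc(p)

    def test_dangling_parent_is_structural_error(self, tmp_path):
        p = tmp_path / "dangling.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 0 1 0 1 99\n")
        with pytest.raises(MorphologyParseError, match="parent 99"):
            read_swc(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.swc"
        p.write_text("# nothing here\n")
        with pytest.raises(MorphologyParseError, match="empty"):
            read_swc(p)


class TestWriteSwc:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_round_trip_preserves_geometry(self, tmp_path, seed):
        m = fx.make_random_tree(seed, depth=3)
        p = tmp_path / "m.swc"
        write_swc(m, p)
        m2 = read_swc(p)
        np.testing.assert_allclose(m2.positions, m.positions, atol=1e-6)
        np.testing.assert_allclose(m2.radii, m.radii, atol=1e-6)
        assert m2.edges == m.edges  # ids are already 1..n topological
        assert list(m2.compartments) == list(m.compartments)

    def test_write_read_write_is_byte_stable(self, tmp_path):
        m = fx.make_y_tree(50, 50, 90)
        p1, p2 = tmp_path / "a.swc", tmp_path / "b.swc"
        write_swc(m, p1)
        write_swc(read_swc(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_chain_has_root_parent_minus_one(self, tmp_path):
        m = fx.make_cable(20, 3)
        p = tmp_path / "c.swc"
        write_swc(m, p)
        data = [l.split() for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(data) == 3
        assert data[0][6] == "-1"

    def test_custom_compartment_round_trips_with_code_ge_5(self, tmp_path):
        m = Morphology(
            ids=[1, 2],
            positions=np.array([[0.0, 0, 0], [0, 1, 0]]),
            radii=[1.0, 0.5],
            compartments=["soma", "custom-7"],
            parent_ids=[-1, 1],
        )
        p = tmp_path / "cust.swc"
        write_swc(m, p)
        codes = [int(l.split()[1]) for l in p.read_text().splitlines() if not l.startswith("#")]
        assert codes[1] == 7 >= 5
        assert list(read_swc(p).compartments) == ["soma", "custom-7"]

    def test_unnamed_custom_compartment_gets_fresh_code(self, tmp_path):
        m = Morphology(
            ids=[1, 2],
            positions=np.array([[0.0, 0, 0], [0, 1, 0]]),
            radii=[1.0, 0.5],
            compartments=["soma", "tuft"],
            parent_ids=[-1, 1],
        )
        p = tmp_path / "tuft.swc"
        write_swc(m, p)
        codes = [int(l.split()[1]) for l in p.read_text().splitlines() if not l.startswith("#")]
        assert codes[1] >= 5


class TestNeurolucidaXml:
    def _write_fixture(self, tmp_path):
        cable = fx.make_cable(30, 4, soma_root=False)
        contour = fx.make_layered_consensus([0, 100], 50).contours[0]
        p = tmp_path / "scene.xml"
        fx.write_xml_scene(Scene([cable], [contour]), p)
        return p, cable

    def test_tree_and_contour(self, tmp_path):
        p, cable = self._write_fixture(tmp_path)
        scene = read_neurolucida_xml(p)
        assert len(scene.morphologies) == 1
        assert len(scene.contours) == 1
        m = scene.morphologies[0]
        assert m.n_vertices == 4 and len(m.edges) == 3
        np.testing.assert_allclose(m.positions, cable.positions)
        assert scene.contours[0].closed

    def test_diameter_halved_to_radius(self, tmp_path):
        p, cable = self._write_fixture(tmp_path)
        m = read_neurolucida_xml(p).morphologies[0]
        np.testing.assert_allclose(m.radii, cable.radii)

    def test_autocorrection_matches_intact_twin(self, tmp_path):
        p, _ = self._write_fixture(tmp_path)
        intact = read_neurolucida_xml(p)
        broken = tmp_path / "broken.xml"
        broken.write_text(p.read_text().split("\n", 1)[1])  # drop <?xml?> line
        repaired = read_neurolucida_xml(broken)
        assert len(repaired.morphologies) == len(intact.morphologies)
        np.testing.assert_array_equal(
            repaired.morphologies[0].positions, intact.morphologies[0].positions
        )
        assert repaired.morphologies[0].edges == intact.morphologies[0].edges

    def test_axon_and_dendrite_trees_get_distinct_labels(self, tmp_path):
        axon = fx.make_cable(10, 3, compartment="axon", soma_root=False)
        dend = fx.make_cable(10, 3, compartment="dendrite", soma_root=False)
        p = tmp_path / "two.xml"
        fx.write_xml_scene(Scene([axon, dend], []), p)
        scene = read_neurolucida_xml(p)
        labels = {str(m.compartments[0]) for m in scene.morphologies}
        assert labels == {"axon", "dendrite"}

    def test_branching_preserved(self, tmp_path):
        y = fx.make_y_tree(50, 50, 90)
        p = tmp_path / "y.xml"
        fx.write_xml_scene(Scene([y], []), p)
        m = read_neurolucida_xml(p).morphologies[0]
        assert m.n_vertices == 4 and len(m.edges) == 3
        # branch point has two children
        parents = [pid for pid in m.parent_ids if pid != -1]
        assert max(parents.count(p) for p in set(parents)) == 2

    def test_unrecoverable_xml_raises(self, tmp_path):
        p = tmp_path / "junk.xml"
        p.write_text("<tree><point x='1' </tree>")
        with pytest.raises(MorphologyParseError):
            read_neurolucida_xml(p)


class TestAsc:
    def test_three_point_dendrite(self, tmp_path):
        p = tmp_path / "d.asc"
        p.write_text(
            "; fixture\n(Dendrite\n  ( 0 0 0 1 )\n  ( 0 10 0 1 )\n  ( 0 20 0 1 )\n)\n"
        )
        scene = read_asc(p)
        m = scene.morphologies[0]
        assert m.n_vertices == 3 and len(m.edges) == 2

    def test_named_closed_contour(self, tmp_path):
        p = tmp_path / "b.asc"
        p.write_text(
            '("Barrel"\n  (Closed)\n  ( 0 0 0 1 )\n  ( 10 0 0 1 )\n  ( 10 10 0 1 )\n)\n'
        )
        scene = read_asc(p)
        assert len(scene.contours) == 1
        assert scene.contours[0].name == "Barrel"
        assert scene.contours[0].closed

    def test_asc_equals_xml_twin(self, tmp_path):
        y = fx.make_y_tree(40, 30, 60, compartment="dendrite")
        xml_p, asc_p = tmp_path / "y.xml", tmp_path / "y.asc"
        fx.write_xml_scene(Scene([y], []), xml_p)
        fx.write_asc_scene(Scene([y], []), asc_p)
        mx = read_neurolucida_xml(xml_p).morphologies[0]
        ma = read_asc(asc_p).morphologies[0]
        np.testing.assert_allclose(ma.positions, mx.positions, atol=1e-6)
        np.testing.assert_allclose(ma.radii, mx.radii, atol=1e-6)
        assert ma.edges == mx.edges

    def test_unbalanced_parens_report_position(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("(Dendrite\n  ( 0 0 0 1 )\n")
        with pytest.raises(MorphologyParseError, match="unbalanced"):
            read_asc(p)


class TestDetectFormat:
    def test_by_extension_and_content(self, tmp_path):
        swc = tmp_path / "cell.swc"
        swc.write_text(MINIMAL_SWC)
        assert detect_format(swc) == "swc"
        noext = tmp_path / "mystery"
        noext.write_text('<?xml version="1.0"?><mbf></mbf>')
        assert detect_format(noext) == "nlx_xml"
        asc = tmp_path / "mystery2"
        asc.write_text("; comment\n(Dendrite ( 0 0 0 1 ))")
        assert detect_format(asc) == "nlx_asc"
        plain = tmp_path / "columns"
        plain.write_text(MINIMAL_SWC)
        assert detect_format(plain) == "swc"

    def test_dat_is_rejected(self, tmp_path):
        p = tmp_path / "cell.dat"
        p.write_bytes(b"\x00\x01binary")
        with pytest.raises(UnsupportedFormatError, match="DAT"):
            detect_format(p)

    def test_undecidable_content_raises(self, tmp_path):
        p = tmp_path / "noise"
        p.write_text("hello world, not a reconstruction")
        with pytest.raises(UnsupportedFormatError):
            detect_format(p)


class TestCrossFormat:
    def test_swc_and_xml_same_structure(self, tmp_path):
        cable = fx.make_cable(100, 11, soma_root=False)
        swc_p, xml_p = tmp_path / "c.swc", tmp_path / "c.xml"
        write_swc(cable, swc_p)
        fx.write_xml_scene(Scene([cable], []), xml_p)
        ms = read_swc(swc_p)
        mx = read_neurolucida_xml(xml_p).morphologies[0]
        np.testing.assert_allclose(ms.positions, mx.positions, atol=1e-6)
        assert ms.edges == mx.edges
        assert list(ms.compartments) == list(mx.compartments)

    def test_fixture_corpus_parses_totally(self, tmp_path):
        from neurodensity.io import read_any

        for spec in ("smoke", "formats", "random"):
            d = tmp_path / spec
            files = fx.write_corpus(spec, d, seed=3)
            for f in files:
                if f.suffix in (".swc", ".xml", ".asc"):
                    scene = read_any(f)
                    assert scene.morphologies or scene.contours
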
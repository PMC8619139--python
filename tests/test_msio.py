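"""Format readers/writers: round-trips and strict validation."""
import numpy as np
import pytest

from photonet import msio
from photonet.exceptions import FormatError, ValidationError
from photonet.types import DADTrace, FeatureTable, FragmentSpectrum, MolecularNetwork, ScoredEdge


class TestMGF:
    def test_single_block_parsed(self, tmp_path):
        path = tmp_path / "one.mgf"
        path.write_text(
            "BEGIN IONS\nPEPMASS=300.05\nSCANS=7\nCHARGE=1-\n"
            "100.0 10.0\n150.0 5.0\n200.0 1.0\nEND IONS\n"
        )
        out = msio.read_mgf(path)
        assert len(out) == 1
        s = out[0]
        assert s.precursor_mz == pytest.approx(300.05)
        assert s.feature_id == "7"
        assert s.charge == -1
        assert s.n_peaks == 3

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("")
        assert msio.read_mgf(path) == []

    def test_block_without_peaks_retained(self, tmp_path):
        path = tmp_path / "nopeaks.mgf"
        path.write_text("BEGIN IONS\nPEPMASS=200.1\nSCANS=1\nEND IONS\n")
        out = msio.read_mgf(path)
        assert len(out) == 1 and out[0].n_peaks == 0

    def test_missing_pepmass_raises_located_error(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text(
            "BEGIN IONS\nPEPMASS=200.1\nSCANS=1\n100.0 1.0\nEND IONS\n\n"
            "BEGIN IONS\nSCANS=2\n100.0 1.0\nEND IONS\n"
        )
        with pytest.raises(FormatError, match="block 1"):
            msio.read_mgf(path)

    def test_round_trip_preserves_peaks(self, spectra, tmp_path):
        path = tmp_path / "rt.mgf"
        msio.write_mgf(spectra, path)
        back = msio.read_mgf(path)
        assert len(back) == len(spectra)
        for s0, s1 in zip(spectra, back):
            assert s0.feature_id == s1.feature_id
            assert s1.precursor_mz == pytest.approx(s0.precursor_mz, abs=1e-6)
            np.testing.assert_allclose(s0.mz, s1.mz, atol=1e-6)
            np.testing.assert_allclose(s0.intensities, s1.intensities, atol=1e-6)


class TestFeatureTable:
    def test_small_table_parsed(self, tmp_path):
        path = tmp_path / "ft.csv"
        path.write_text(
            "id,mz,rt,e1,e2,e3\nf1,300.1,1.5,10,0,5\nf2,400.2,2.5,1,2,3\n"
        )
        t = msio.read_feature_table(path)
        assert t.areas.shape == (2, 3)
        assert t.extracts == ["e1", "e2", "e3"]

    def test_blank_area_cell_reads_zero(self, tmp_path):
        path = tmp_path / "ft.csv"
        path.write_text("id,mz,rt,e1,e2\nf1,300.1,1.5,,4\n")
        t = msio.read_feature_table(path)
        assert t.areas[0, 0] == 0.0

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "ft.csv"
        path.write_text("id,mz,rt,e1\nf1,300.1,1.5,1\nf1,300.2,1.6,2\n")
        with pytest.raises(ValidationError):
            msio.read_feature_table(path)

    def test_negative_area_rejected(self, tmp_path):
        path = tmp_path / "ft.csv"
        path.write_text("id,mz,rt,e1\nf1,300.1,1.5,-2\n")
        with pytest.raises(ValidationError):
            msio.read_feature_table(path)

    def test_round_trip_lossless(self, feature_table, tmp_path):
        path = tmp_path / "rt.csv"
        msio.write_feature_table(feature_table, path)
        back = msio.read_feature_table(path)
        assert back.feature_ids == feature_table.feature_ids
        assert back.extracts == feature_table.extracts
        np.testing.assert_allclose(back.areas, feature_table.areas, rtol=1e-6)


class TestDADTrace:
    def test_three_point_trace(self, tmp_path):
        path = tmp_path / "dad.csv"
        path.write_text(
            "# extract_id=e1\n# wavelength_nm=468\nrt,absorbance\n0.0,1.0\n0.1,2.0\n0.2,1.0\n"
        )
        t = msio.read_dad_trace(path)
        assert t.extract_id == "e1" and t.wavelength == 468.0
        assert t.rt.size == 3

    def test_unsorted_rows_rejected(self, tmp_path):
        path = tmp_path / "dad.csv"
        path.write_text(
            "# extract_id=e1\n# wavelength_nm=468\nrt,absorbance\n0.2,1.0\n0.1,2.0\n"
        )
        with pytest.raises(ValidationError):
            msio.read_dad_trace(path)

    def test_round_trip(self, dad_traces, tmp_path):
        trace = next(iter(dad_traces.values()))
        path = tmp_path / "rt.csv"
        msio.write_dad_trace(trace, path)
        back = msio.read_dad_trace(path)
        assert back.extract_id == trace.extract_id
        np.testing.assert_allclose(back.absorbance, trace.absorbance, atol=1e-6)


class TestAssayTables:
    def test_dma_round_trip(self, bundle_dir, tmp_path):
        wells = msio.read_dma_kinetics(bundle_dir[0] / "dma_kinetics.csv")
        assert wells, "bundle has DMA wells"
        path = tmp_path / "dma.csv"
        msio.write_dma_kinetics(wells, path)
        back = msio.read_dma_kinetics(path)
        assert len(back) == len(wells)
        key = lambda w: (w.extract_id, w.light, w.condition, w.replicate)  # noqa: E731
        for w0, w1 in zip(sorted(wells, key=key), sorted(back, key=key)):
            assert key(w0) == key(w1)
            np.testing.assert_allclose(w0.a377, w1.a377, atol=1e-6)

    def test_dose_response_round_trip(self, bundle_dir, tmp_path):
        doses = msio.read_dose_response(bundle_dir[0] / "dose_response.csv")
        path = tmp_path / "dr.csv"
        msio.write_dose_response(doses, path)
        back = msio.read_dose_response(path)
        assert len(back) == len(doses)
        assert {(d.cell_line, d.extract_id, d.light) for d in doses} == {
            (d.cell_line, d.extract_id, d.light) for d in back
        }


class TestGraphML:
    def _network(self):
        nodes = {
            "a": {"mz": 300.0, "rt": 1.0, "vis_signal": 1},
            "b": {"mz": 314.0, "rt": 1.2, "vis_signal": 0},
            "c": {"mz": 500.0, "rt": 3.0, "vis_signal": 0},
        }
        edges = [ScoredEdge("a", "b", 0.912345678, 7, 14.0157)]
        comps = {"a": 0, "b": 0, "c": 1}
        return MolecularNetwork(nodes, edges, comps, singletons={"c"})

    def test_one_node_network_exports(self, tmp_path):
        net = MolecularNetwork({"a": {"mz": 1.0}}, [], {"a": 0}, {"a"})
        path = tmp_path / "one.graphml"
        msio.write_graphml(net, path)
        back = msio.read_graphml(path)
        assert back.n_nodes == 1 and back.n_edges == 0

    def test_round_trip_recovers_edge_scores(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.graphml"
        msio.write_graphml(net, path)
        back = msio.read_graphml(path)
        assert back.n_nodes == 3
        assert back.edges[0].score == pytest.approx(0.912345678, abs=1e-6)
        assert back.components == net.components
        assert back.singletons == net.singletons

    def test_node_attribute_table_schema(self, tmp_path):
        net = self._network()
        path = tmp_path / "nodes.tsv"
        msio.write_node_attributes(net, path)
        lines = path.read_text().strip().split("\n")
        header = lines[0].split("\t")
        assert header[:3] == ["feature_id", "cluster_id", "singleton"]
        # every row carries exactly the declared number of columns
        assert all(len(line.split("\t")) == len(header) for line in lines[1:])
        assert len(lines) == 1 + 3


class TestLibrary:
    def test_library_round_trip(self, bundle_dir):
        entries = msio.read_library(
            bundle_dir[0] / "library.mgf", bundle_dir[0] / "library_meta.csv"
        )
        assert len(entries) >= 4
        markers = [e for e in entries if e.marker]
        assert len(markers) == 4
        assert all(e.taxonomy for e in markers)
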
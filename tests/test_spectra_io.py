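"""Spectrum/dataset reading, layout handling and CSV round-trips."""

import logging

import numpy as np
import pytest

from maldikd.exceptions import (
    ConflictError,
    EmptySpectrumError,
    ParseError,
    StructureError,
)
from maldikd.matching import build_consensus
from maldikd.spectra_io import (
    Dataset,
    Spectrum,
    load_dataset,
    read_consensus_csv,
    read_peak_matrix_csv,
    read_spectrum,
    write_csv,
)

from conftest import make_matrix, make_peaklist, write_mzml


class TestReadCsvSpectrum:
    def test_direct_parse(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("mz,intensity\n100.0,5.0\n200.0,7.0\n")
        s = read_spectrum(p)
        assert s.mz.tolist() == [100.0, 200.0]
        assert s.intensity.tolist() == [5.0, 7.0]

    def test_unsorted_rows_sorted_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.csv"
        p.write_text("mz,intensity\n200.0,7.0\n100.0,5.0\n")
        with caplog.at_level(logging.WARNING):
            s = read_spectrum(p)
        assert s.mz.tolist() == [100.0, 200.0]
        assert s.intensity.tolist() == [5.0, 7.0]
        assert any("unordered" in r.message for r in caplog.records)

    def test_headerless_two_numeric_columns_accepted(self, tmp_path, caplog):
        p = tmp_path / "a.csv"
        p.write_text("100.0,5.0\n200.0,7.0\n")
        with caplog.at_level(logging.WARNING):
            s = read_spectrum(p)
        assert len(s) == 2
        assert any("no header" in r.message for r in caplog.records)

    def test_duplicate_mz_merged_by_summing(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("mz,intensity\n100.0,5.0\n100.0,2.0\n200.0,1.0\n")
        s = read_spectrum(p)
        assert s.mz.tolist() == [100.0, 200.0]
        assert s.intensity.tolist() == [7.0, 1.0]

    def test_non_numeric_cell_names_line(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("mz,intensity\n100.0,5.0\nxyz,7.0\n")
        with pytest.raises(ParseError, match="line 3"):
            read_spectrum(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("mz,intensity\n")
        with pytest.raises(EmptySpectrumError):
            read_spectrum(p)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(IOError):
            read_spectrum(tmp_path / "nope.csv")


class TestReadMzml:
    def test_roundtrip_three_point_scan(self, tmp_path):
        mz, inten = [100.0, 200.5, 300.25], [1.0, 2.0, 3.0]
        p = write_mzml(tmp_path / "one.mzml", [(mz, inten)])
        s = read_spectrum(p)
        np.testing.assert_allclose(s.mz, mz)
        np.testing.assert_allclose(s.intensity, inten)
        assert s.metadata["spectrum_mode"] == "profile"

    def test_first_ms1_selected_and_index_override(self, tmp_path):
        p = write_mzml(
            tmp_path / "multi.mzml",
            [([9.0, 10.0], [0.0, 1.0]), ([100.0, 200.0], [5.0, 6.0]),
             ([7.0, 8.0], [1.0, 1.0])],
            ms_levels=[2, 1, 1],
        )
        assert read_spectrum(p).mz.tolist() == [100.0, 200.0]
        assert read_spectrum(p, index=1).mz.tolist() == [7.0, 8.0]

    def test_no_ms1_raises(self, tmp_path):
        p = write_mzml(tmp_path / "ms2.mzml", [([1.0], [1.0])], ms_levels=[2])
        with pytest.raises(EmptySpectrumError):
            read_spectrum(p)


def test_read_mzxml(tmp_path):
    import base64
    import struct

    pairs = [100.0, 1.0, 200.0, 2.0]
    b64 = base64.b64encode(struct.pack(f">{len(pairs)}f", *pairs)).decode()
    doc = (
        '<?xml version="1.0"?>\n'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">\n'
        ' <msRun scanCount="1">\n'
        '  <scan num="1" msLevel="1" peaksCount="2">\n'
        '   <peaks compressionType="none" compressedLen="0" precision="32"'
        f' byteOrder="network" contentType="m/z-int">{b64}</peaks>\n'
        "  </scan>\n </msRun>\n</mzXML>"
    )
    p = tmp_path / "a.mzxml"
    p.write_text(doc)
    s = read_spectrum(p)
    np.testing.assert_allclose(s.mz, [100.0, 200.0])
    np.testing.assert_allclose(s.intensity, [1.0, 2.0])


class TestLoadDataset:
    def test_condition_dirs_counts(self, tiny_dataset_dir):
        ds = load_dataset(tiny_dataset_dir, "condition_dirs")
        assert sorted(ds.conditions) == ["A", "B"]
        assert len(ds.samples) == 3
        assert ds.n_spectra == 4
        assert [s.replicate_index for s in ds.samples["s1"]] == [0, 1]

    def test_deterministic_across_runs(self, tiny_dataset_dir):
        d1 = load_dataset(tiny_dataset_dir)
        d2 = load_dataset(tiny_dataset_dir)
        assert d1.conditions == d2.conditions
        assert list(d1.samples) == list(d2.samples)
        for sid in d1.samples:
            for a, b in zip(d1.samples[sid], d2.samples[sid]):
                assert a.id == b.id
                np.testing.assert_array_equal(a.mz, b.mz)

    def test_empty_sample_dir_is_structure_error(self, tmp_path):
        (tmp_path / "A" / "s1").mkdir(parents=True)
        with pytest.raises(StructureError):
            load_dataset(tmp_path)

    def test_manifest_wine_design(self, tmp_path):
        # 5 conditions x 5 samples x 1 replicate = 25 spectra
        rows = ["path,condition,sample"]
        for c in "ABCDE":
            for i in range(1, 6):
                f = tmp_path / f"{c}{i}.csv"
                f.write_text("mz,intensity\n100,1\n")
                rows.append(f"{f.name},{c},{c}{i}")
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("\n".join(rows) + "\n")
        ds = load_dataset(manifest, "manifest")
        assert len(ds.conditions) == 5
        assert len(ds.samples) == 25
        assert ds.n_spectra == 25

    def test_manifest_missing_path_names_row(self, tmp_path):
        f = tmp_path / "a.csv"
        f.write_text("mz,intensity\n100,1\n")
        manifest = tmp_path / "manifest.csv"
        manifest.write_text("path,condition,sample\na.csv,A,s1\ngone.csv,A,s2\n")
        with pytest.raises(StructureError, match="gone.csv"):
            load_dataset(manifest, "manifest")

    def test_duplicate_sample_across_conditions_conflicts(self, tmp_path):
        for c in ("A", "B"):
            d = tmp_path / c / "s1"
            d.mkdir(parents=True)
            (d / "r1.csv").write_text("mz,intensity\n100,1\n")
        with pytest.raises(ConflictError):
            load_dataset(tmp_path)


class TestCsvRoundTrip:
    def test_spectrum_roundtrip_within_1e9(self, tmp_path):
        rng = np.random.default_rng(7)
        mz = np.sort(rng.uniform(1000, 5000, 100))
        s = Spectrum("x", "x", 0, mz, rng.uniform(0, 10, 100))
        path = tmp_path / "s.csv"
        write_csv(s, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.mz, s.mz, atol=1e-9)
        np.testing.assert_allclose(back.intensity, s.intensity, atol=1e-9)

    def test_consensus_pop_column(self, tmp_path):
        # 3 hand-made replicates: 100 in all three, 200 in two of them
        reps = [
            make_peaklist("r1", [100.0, 200.0]),
            make_peaklist("r2", [100.0, 200.0]),
            make_peaklist("r3", [100.0]),
        ]
        cs = build_consensus(reps, "s1", tolerance=0.5, pop_threshold=50)
        path = tmp_path / "c.csv"
        write_csv(cs, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "mz,intensity,pop"
        pops = [float(l.split(",")[2]) for l in lines[1:]]
        assert pops == pytest.approx([100.0, 200.0 / 3], abs=1e-9)
        back = read_consensus_csv(path, "s1")
        np.testing.assert_allclose(back.mz, cs.mz, atol=1e-9)
        np.testing.assert_allclose(back.pop, cs.pop, atol=1e-9)

    def test_binary_matrix_format_and_roundtrip(self, tmp_path):
        m = make_matrix([[1, 0], [0, 1]], conditions=["A", "B"],
                        mz=[100.1234, 200.5])
        path = tmp_path / "m.csv"
        write_csv(m, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 3
        assert lines[0] == "sample,condition,100.1234,200.5000"
        cells = [l.split(",")[2:] for l in lines[1:]]
        assert all(v in ("0", "1") for row in cells for v in row)
        back = read_peak_matrix_csv(path)
        assert back.mode == "binary"
        np.testing.assert_allclose(back.values, m.values)
        np.testing.assert_allclose(back.mz, m.mz, atol=1e-9)
        assert back.sample_ids == m.sample_ids
        assert back.conditions == m.conditions

    def test_intensity_matrix_roundtrip(self, tmp_path):
        m = make_matrix([[0.5, 0.25], [0.125, 2.0]], mode="intensity",
                        mz=[100.0, 200.0])
        path = tmp_path / "m.csv"
        write_csv(m, path)
        back = read_peak_matrix_csv(path)
        np.testing.assert_allclose(back.values, m.values, atol=1e-9)


def test_spectrum_invariants_enforced():
    with pytest.raises(Exception):
        Spectrum("x", "x", 0, [1.0, 1.0], [1.0, 2.0])  # non-increasing mz
    with pytest.raises(Exception):
        Spectrum("x", "x", 0, [1.0, 2.0], [1.0])  # length mismatch
    with pytest.raises(EmptySpectrumError):
        Spectrum("x", "x", 0, [], [])


def test_dataset_rejects_duplicate_sample_ids():
    s = Spectrum("a", "s1", 0, [1.0], [1.0])
    with pytest.raises(ConflictError):
        Dataset(conditions={"A": ["s1"], "B": ["s1"]}, samples={"s1": [s]})
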
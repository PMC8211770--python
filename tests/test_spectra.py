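"""Peak-list I/O, ladder detection, differential analysis and annotation."""

import pytest

from olimp.glycan import Composition, parse_structure, composition_of
from olimp.mass import MONOISOTOPIC, NOMINAL, adduct_mz
from olimp.enzymes import FUCOSIDASE, GALACTOSIDASE
from olimp.spectra import (
    AnnotationConfig,
    PeaklistError,
    Spectrum,
    annotate,
    assignments_to_dataframe,
    assignments_to_json,
    diff_spectra,
    find_series,
    read_peaklist,
    series_steps,
    write_peaklist,
)


def _spec(*mz_intensity, **kw):
    return Spectrum.from_pairs(mz_intensity, **kw)


class TestPeaklistIO:
    def test_bare_two_columns(self, tmp_path):
        f = tmp_path / "peaks.csv"
        f.write_text("1099,50\n1393,120\n")
        spec = read_peaklist(f)
        assert [p.mz for p in spec.peaks] == [1099, 1393]
        assert spec.sample == "peaks"

    def test_header_and_tabs(self, tmp_path):
        f = tmp_path / "peaks.tsv"
        f.write_text("mz\tintensity\n953.3\t10\n1099.4\t20\n1393.4\t5\n")
        assert len(read_peaklist(f)) == 3

    def test_non_numeric_row_reports_line(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("abc,1\n")
        with pytest.raises(PeaklistError, match="line 1"):
            read_peaklist(f)
        f.write_text("mz,intensity\n1099,5\noops,3\n")
        with pytest.raises(PeaklistError, match="line 3"):
            read_peaklist(f)

    def test_empty_rejected(self, tmp_path):
        f = tmp_path / "empty.csv"
        f.write_text("\n")
        with pytest.raises(PeaklistError, match="no peaks"):
            read_peaklist(f)

    def test_duplicates_merged_and_sorted(self, tmp_path):
        spec = _spec((1393.0, 5), (1099.0, 1), (1393.0, 7))
        assert [p.mz for p in spec.peaks] == [1099.0, 1393.0]
        assert spec.peaks[1].intensity == 12

    def test_roundtrip(self, tmp_path):
        spec = _spec((953.296, 10.5), (1099.354, 3.25))
        f = tmp_path / "out.csv"
        write_peaklist(spec, f)
        back = read_peaklist(f)
        for a, b in zip(spec.peaks, back.peaks):
            assert b.mz == pytest.approx(a.mz, abs=1e-4)


class TestFindSeries:
    def test_sparsely_branched_uronic_series(self):
        spec = _spec((1146, 1), (1322, 1), (1440, 1), (1616, 1))
        graph = find_series(spec, series_steps(NOMINAL), tol=0.5)
        edges = {(spec.peaks[e.i].mz, spec.peaks[e.j].mz, e.label) for e in graph.edges}
        assert edges == {
            (1146, 1322, "HexA"),
            (1440, 1616, "HexA"),
            (1146, 1440, "X-unit"),
            (1322, 1616, "X-unit"),
        }
        assert graph.series() == [[0, 1, 2, 3]]

    def test_acetylation_step(self):
        graph = find_series(_spec((1616, 1), (1658, 1)), series_steps(NOMINAL), tol=0.5)
        assert [(e.label, e.observed) for e in graph.edges] == [("Ac", 42)]

    def test_single_peak_empty(self):
        assert find_series(_spec((1099, 1))).edges == []

    def test_planted_ladder_recovered_exactly(self):
        # plant a pure hexose ladder; with tight tolerance only the
        # planted steps (and their not-planted multi-step sums absent from
        # the step table) appear
        base = 527.16
        mz = [base + k * 162.053 for k in range(5)]
        spec = _spec(*[(m, 1.0) for m in mz])
        graph = find_series(spec, {"Hex": 162.053}, tol=0.1)
        edges = {(e.i, e.j) for e in graph.edges}
        assert edges == {(k, k + 1) for k in range(4)}
        assert all(abs(e.error) <= 0.1 for e in graph.edges)


class TestDiffSpectra:
    def test_fucosidase_disappearance_and_partial(self):
        pre = _spec((953, 10), (1099, 30), (1247, 10), (1393, 40), (1409, 10), (1555, 30))
        post = _spec((953, 40), (1247, 50), (1409, 25), (1555, 10))
        result = diff_spectra(pre, post, FUCOSIDASE, NOMINAL, tol=0.5)
        pairs = {(p.precursor.mz, p.product.mz, p.status) for p in result.pairs}
        assert pairs == {
            (1099, 953, "disappeared"),
            (1393, 1247, "disappeared"),
            (1555, 1409, "partial"),
        }
        assert result.unpaired == []

    def test_galactosidase_pairs(self):
        pre = _spec((1129, 10), (1423, 10))
        post = _spec((967, 10), (1261, 10))
        result = diff_spectra(pre, post, GALACTOSIDASE, NOMINAL, tol=0.5)
        assert {(p.precursor.mz, p.product.mz) for p in result.pairs} == {
            (1129, 967),
            (1423, 1261),
        }

    def test_identical_spectra_empty(self):
        s = _spec((1099, 10), (1393, 10))
        result = diff_spectra(s, s, FUCOSIDASE, NOMINAL)
        assert result.pairs == [] and result.unpaired == []

    def test_pair_deltas_match_residue_mass(self):
        pre = _spec((1099.354, 10), (1393.449, 10), (953.296, 5), (1247.391, 5))
        post = _spec((953.296, 25), (1247.391, 25))
        result = diff_spectra(pre, post, FUCOSIDASE, MONOISOTOPIC, tol=0.5)
        for p in result.pairs:
            assert p.delta == pytest.approx(
                p.k * MONOISOTOPIC.residue_masses[p.removed], abs=0.5
            )

    def test_unpaired_loss_reported(self):
        pre = _spec((1099, 10), (500, 10))
        post = _spec((500, 10))
        result = diff_spectra(pre, post, FUCOSIDASE, NOMINAL)
        assert [p.mz for p in result.unpaired] == [1099]


class TestAnnotate:
    def test_empty_spectrum(self):
        assert annotate(Spectrum(())) == []

    def test_contaminant_hexose_flagged(self):
        mz6 = adduct_mz(Composition(Hex=6))  # 1013.317
        spec = _spec((mz6, 10))
        (a,) = annotate(spec, AnnotationConfig())
        assert "contaminant-ladder" in a.evidence
        assert a.best.composition == Composition(Hex=6)

    def test_unassigned_peak(self):
        (a,) = annotate(_spec((777.77, 1)), AnnotationConfig(tolerance=0.05))
        assert a.unassigned

    def test_fucosylated_peak_with_companion(self):
        structures = ["XFG", "XXFG", "XLFG", "XLG", "XXLG", "XLLG"]
        pre_pairs = [(adduct_mz(composition_of(parse_structure(c))), 10.0) for c in structures]
        post_pairs = [
            (adduct_mz(composition_of(parse_structure(c))), 20.0)
            for c in ("XLG", "XXLG", "XLLG")
        ]
        pre, post = _spec(*pre_pairs), _spec(*post_pairs)
        assignments = annotate(pre, AnnotationConfig(companions={"fucosidase": post}))
        by_mz = {round(a.peak.mz): a for a in assignments}
        a = by_mz[1393]
        assert a.best.composition == Composition(Hex=5, Pent=3, dHex=1)
        assert a.best.representative.render() == "XXFG"
        assert "fucosidase" in a.best.enzyme_support
        assert "enzyme-shift-precursor" in a.evidence
        assert "enzyme-shift-product" in by_mz[1247].evidence

    def test_series_evidence(self):
        spec = _spec((1085.338, 5), (1379.434, 5))  # XXXG and +X-unit
        (a, b) = annotate(spec, AnnotationConfig())
        assert "series-member" in a.evidence and "series-member" in b.evidence

    def test_candidates_sorted_by_abs_error_clusters(self):
        (a,) = annotate(_spec((1423.42, 5)), AnnotationConfig())
        errs = [abs(c.error) for c in a.candidates]
        # monotone up to the tie quantum used for evidence resolution
        for e1, e2 in zip(errs, errs[1:]):
            assert e2 >= e1 - 0.05


class TestReports:
    def test_dataframe_and_json(self):
        spec = _spec((1085.338, 5), (1099.354, 7))
        assignments = annotate(spec, AnnotationConfig())
        df = assignments_to_dataframe(assignments)
        assert list(df["mz"]) == [1085.338, 1099.354]
        assert df.loc[0, "structure1"] == "XXXG"
        import json

        payload = json.loads(assignments_to_json(assignments, top=2))
        assert payload[0]["candidates"][0]["composition"] == {"Hex": 4, "Pent": 3}
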
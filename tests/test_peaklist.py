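"""Peak-list and intensity-table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrbind.exceptions import DataError
from nmrbind.peaklist import (
    AmidePeak,
    IntensityTable,
    PeakList,
    TitrationSeries,
    read_intensity_table,
    read_peaklist,
    write_peaklist,
)

SPARKY_3LINE = """\
      Assignment         w1         w2
        K169N-H   118.1230     8.1230
        A170N-H   120.4560     7.8900
        R174N-H   122.0010     8.5000
"""


def test_sparky_parse_three_assignments(tmp_path):
    p = tmp_path / "pl.list"
    p.write_text(SPARKY_3LINE)
    pl = read_peaklist(p, dialect="sparky")
    assert pl.residues == {169, 170, 174}
    pk = pl.get(169)
    assert pk.residue_type == "K"
    # w1 is 15N, w2 is 1H by default
    assert pk.delta_N == pytest.approx(118.123)
    assert pk.delta_H == pytest.approx(8.123)


def test_sparky_w1_w2_swap(tmp_path):
    p = tmp_path / "pl.list"
    p.write_text("K169N-H 8.123 118.123\n")
    pl = read_peaklist(p, w1_is_N=False)
    assert pl.get(169).delta_H == pytest.approx(8.123)
    assert pl.get(169).delta_N == pytest.approx(118.123)


def test_duplicate_identical_shifts_deduplicated(tmp_path):
    p = tmp_path / "pl.list"
    p.write_text("K169N-H 118.123 8.123\nK169N-H 118.123 8.123\n")
    with pytest.warns(UserWarning, match="duplicated"):
        pl = read_peaklist(p)
    assert len(pl) == 1


def test_duplicate_conflicting_shifts_error(tmp_path):
    p = tmp_path / "pl.list"
    p.write_text("K169N-H 118.123 8.123\nK169N-H 119.000 8.123\n")
    with pytest.raises(DataError, match="conflicting"):
        read_peaklist(p)


def test_unparseable_rows_skipped_not_silent(tmp_path, caplog):
    p = tmp_path / "pl.list"
    p.write_text("K169N-H 118.1 8.1\ngarbage row here\nA170N-H 120.0 7.9\n")
    with caplog.at_level("WARNING"):
        pl = read_peaklist(p)
    assert len(pl) == 2
    assert any("skip" in rec.message.lower() for rec in caplog.records)


def test_missing_file_and_empty_list_errors(tmp_path):
    with pytest.raises(DataError, match="not found"):
        read_peaklist(tmp_path / "nope.list")
    p = tmp_path / "empty.list"
    p.write_text("only garbage\n")
    with pytest.raises(DataError, match="no parseable"):
        read_peaklist(p)
    with pytest.raises(DataError, match="empty"):
        write_peaklist(PeakList("x", []), tmp_path / "out.list")


@pytest.mark.parametrize("dialect", ["sparky", "tsv"])
def test_roundtrip_100_peak_list(tmp_path, dialect):
    rng = np.random.default_rng(42)
    peaks = [
        AmidePeak(i, "ACDEFGHIKLMNQRSTVWY"[i % 19],
                  round(float(rng.uniform(6, 10)), 4),
                  round(float(rng.uniform(105, 135)), 4))
        for i in range(1, 101)
    ]
    pl = PeakList("round", peaks)
    path = tmp_path / f"rt.{dialect}"
    write_peaklist(pl, path, dialect=dialect)
    back = read_peaklist(path, dialect=dialect)
    assert back.residues == pl.residues
    for p in peaks:
        q = back.get(p.residue_number)
        assert q.delta_H == pytest.approx(p.delta_H, abs=5e-5)
        assert q.delta_N == pytest.approx(p.delta_N, abs=5e-5)
        assert q.residue_type == p.residue_type


@settings(derandomize=True, max_examples=25)
@given(
    st.lists(
        st.tuples(
            st.integers(1, 300),
            st.floats(5.0, 13.0),
            st.floats(100.0, 140.0),
        ),
        min_size=1,
        max_size=30,
        unique_by=lambda t: t[0],
    )
)
def test_roundtrip_is_identity_property(tmp_path_factory, rows):
    """read∘write is the identity on shifts at the printed precision."""
    tmp = tmp_path_factory.mktemp("rt")
    peaks = [
        AmidePeak(r, "G", round(h, 4), round(n, 4)) for r, h, n in rows
    ]
    pl = PeakList("prop", peaks)
    path = tmp / "x.list"
    write_peaklist(pl, path, dialect="sparky")
    back = read_peaklist(path, dialect="sparky")
    for p in peaks:
        q = back.get(p.residue_number)
        assert abs(q.delta_H - p.delta_H) < 1e-4 + 1e-9
        assert abs(q.delta_N - p.delta_N) < 1e-4 + 1e-9


def test_titration_series_invariants():
    pl = PeakList("a", [AmidePeak(1, "G", 8.0, 120.0)])
    with pytest.raises(DataError, match="free form"):
        TitrationSeries(100.0, [10.0, 20.0], [pl, pl])
    with pytest.raises(DataError, match="nondecreasing"):
        TitrationSeries(100.0, [0.0, 50.0, 20.0], [pl, pl, pl])
    with pytest.raises(DataError):
        TitrationSeries(100.0, [0.0, 50.0], [pl])


def test_intensity_table_duplicate_detection(tmp_path):
    """The CPMG schedule's two redundant delays are found automatically."""
    delays_ms = [10, 30, 50, 50, 70, 90, 110, 110, 130, 150]
    rows = ["residue\tdelay_ms\tintensity"]
    rows += [f"7\t{d}\t{100 - i}" for i, d in enumerate(delays_ms)]
    p = tmp_path / "r2.tsv"
    p.write_text("\n".join(rows) + "\n")
    tables = read_intensity_table(p)
    assert len(tables) == 1
    t = tables[0]
    dup_delays = sorted(t.delays[i] for i, _ in t.duplicate_pairs)
    assert dup_delays == pytest.approx([0.050, 0.110])
    assert len(t.duplicate_pairs) == 2


def test_intensity_table_errors(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("residue\tdelay_s\tintensity\n1\t-0.005\t10\n")
    with pytest.raises(DataError, match="negative delays"):
        read_intensity_table(p)
    single = tmp_path / "single.tsv"
    single.write_text("residue\tdelay_s\tintensity\n1\t0.01\t10\n")
    t = read_intensity_table(single)[0]
    assert t.duplicate_pairs == []
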
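"""Feature-encoding layer: FASTA/labels/PSSM input and the three descriptors."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mitoloc as ml
from mitoloc.encoding import AMINO_ACIDS, KIDERA_FACTORS, PSSM_FILE_ORDER

CANONICAL = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40)


# ---------------------------------------------------------------- FASTA
def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "one.fasta"
    p.write_text(">P1\nMKV\n")
    recs = ml.read_fasta(p)
    assert len(recs) == 1 and recs[0].id == "P1" and recs[0].sequence == "MKV"


def test_read_fasta_duplicate_id_rejected(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(">P1\nMKV\n>P1\nACD\n")
    with pytest.raises(ValueError, match="P1"):
        ml.read_fasta(p)


def test_read_fasta_order_matches_line_reference(tmp_path):
    """A three-entry file parses in file order, same as a line-by-line scan."""
    text = ">A1 desc\nMKVL\nACDE\n>B2\nWYW\n>C3\nFFKK\n"
    p = tmp_path / "three.fasta"
    p.write_text(text)
    # Reference: manual line scan.
    ref = {}
    order = []
    for line in text.splitlines():
        if line.startswith(">"):
            cur = line[1:].split()[0]
            order.append(cur)
            ref[cur] = ""
        else:
            ref[cur] += line.strip()
    recs = ml.read_fasta(p)
    assert [r.id for r in recs] == order
    assert all(r.sequence == ref[r.id] for r in recs)


def test_read_fasta_malformed_names_line(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text("MKV\n>P1\nACD\n")
    with pytest.raises(ValueError, match="line 1"):
        ml.read_fasta(p)


def test_read_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    assert ml.read_fasta(p) == []


# -------------------------------------------------------------- one-hot
def test_onehot_single_residue():
    fm = ml.encode_onehot(ml.ProteinRecord("x", "A"))
    assert fm.values.shape == (1, 20)
    assert fm.values[0, AMINO_ACIDS.index("A")] == 1.0
    assert fm.values.sum() == 1.0


def test_onehot_positional_independence():
    one = ml.encode_onehot(ml.ProteinRecord("x", "A")).values
    two = ml.encode_onehot(ml.ProteinRecord("x", "AA")).values
    assert np.array_equal(two, np.vstack([one, one]))


@pytest.mark.parametrize("letter", sorted(set("XBZUOJ")))
def test_noncanonical_letters_encode_as_zero_rows(letter):
    assert ml.encode_onehot(ml.ProteinRecord("x", letter)).values.sum() == 0
    assert ml.encode_prop(ml.ProteinRecord("x", letter)).values.sum() == 0


@given(seq=CANONICAL)
@settings(max_examples=50, derandomize=True)
def test_onehot_row_and_column_sums(seq):
    """Rows sum to 1; column sums equal per-residue counts."""
    fm = ml.encode_onehot(ml.ProteinRecord("x", seq))
    assert np.array_equal(fm.values.sum(axis=1), np.ones(len(seq)))
    for j, aa in enumerate(AMINO_ACIDS):
        assert fm.values[:, j].sum() == seq.count(aa)


# ------------------------------------------------------------ properties
# Independent re-transcription of the 10-factor table, formatted per
# factor (KF1..KF10) over the source's A R N D ... residue order.
_FACTOR_ROWS = {
    1: [-1.56, 0.22, 1.14, 0.58, 0.12, -0.47, -1.45, 1.46, -0.41, -0.73,
        -1.04, -0.34, -1.40, -0.21, 2.06, 0.81, 0.26, 0.30, 1.38, -0.74],
    5: [-0.93, -1.70, 0.18, -0.92, -0.71, 1.10, -1.31, 0.10, 1.61, -0.54,
        -0.55, 1.54, 2.00, 0.22, 0.88, -0.21, -0.10, -1.16, 0.00, 0.50],
    10: [-0.48, 0.93, -1.73, 0.70, 1.10, -2.33, -0.12, 0.46, 1.63, -1.78,
         0.93, 0.60, 0.27, -0.44, -0.28, -0.23, 0.19, -0.60, 0.53, 0.65],
}


@pytest.mark.parametrize("factor", sorted(_FACTOR_ROWS))
def test_property_table_matches_independent_transcription(factor):
    for aa, expected in zip("ARNDCQEGHILKMFPSTWYV", _FACTOR_ROWS[factor]):
        assert KIDERA_FACTORS[aa][factor - 1] == expected


def test_prop_rows_equal_bundled_table():
    seq = "".join(AMINO_ACIDS)
    fm = ml.encode_prop(ml.ProteinRecord("x", seq))
    for i, aa in enumerate(seq):
        assert np.array_equal(fm.values[i], np.array(KIDERA_FACTORS[aa]))


def test_prop_repeated_residue_identical_rows():
    fm = ml.encode_prop(ml.ProteinRecord("x", "WWWW"))
    assert np.all(fm.values == fm.values[0])


# ------------------------------------------------------------------ PSSM
_PSSM_FIXTURE = """
Last position-specific scoring matrix computed, weighted observed percentages rounded down, information per position, and relative weight of gapless real matches to pseudocounts
             A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V   A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V
    1 M     -1  -2  -3   1   0   5  -4   2   0   0   1  -1   7  -2  -3   0   1  -4  -2   0    0   0   0   0   0   0   0   0   0   0   0   0 100   0   0   0   0   0   0   0
    2 K      0   2  -2  -1  -3   1   1  -2  -1  -3  -2   6  -1  -3  -1   0  -1  -3  -2  -2    0   0   0   0   0   0   0   0   0   0   0  90   0   0   0   0   0   0   0   0
    3 V     -1  -3  -3  -3  -1  -2  -2  -3  -3   2   1  -2   1  -1  -2  -2   0  -3  -1   4    0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0   0  80

                      K         Lambda
Standard Ungapped    0.1337     0.3176
"""


def test_parse_pssm_reads_fixture_values(tmp_path):
    p = tmp_path / "q.pssm"
    p.write_text(_PSSM_FIXTURE)
    raw = ml.parse_pssm(p)
    assert raw.query_sequence == "MKV"
    assert raw.values.shape == (3, 20)
    # Spot values, remembering the remap to alphabetical column order.
    assert raw.values[0, AMINO_ACIDS.index("M")] == 7
    assert raw.values[0, AMINO_ACIDS.index("A")] == -1
    assert raw.values[1, AMINO_ACIDS.index("K")] == 6
    assert raw.values[2, AMINO_ACIDS.index("V")] == 4
    # Full first row against the printed integers (file order).
    printed = [-1, -2, -3, 1, 0, 5, -4, 2, 0, 0, 1, -1, 7, -2, -3, 0, 1, -4, -2, 0]
    for aa, val in zip(PSSM_FILE_ORDER, printed):
        assert raw.values[0, AMINO_ACIDS.index(aa)] == val


def test_parse_pssm_query_mismatch(tmp_path):
    p = tmp_path / "q.pssm"
    p.write_text(_PSSM_FIXTURE)
    with pytest.raises(ValueError, match="does not match"):
        ml.parse_pssm(p, expected_query="MKW")


def test_parse_pssm_empty_matrix_section(tmp_path):
    p = tmp_path / "empty.pssm"
    header = " ".join(PSSM_FILE_ORDER)
    p.write_text(f"\nmatrix\n  {header}  {header}\n\n")
    with pytest.raises(ValueError, match="empty"):
        ml.parse_pssm(p)


def test_parse_pssm_non_numeric_cell(tmp_path):
    p = tmp_path / "bad.pssm"
    bad = _PSSM_FIXTURE.replace("    2 K      0   2", "    2 K      0   ?", 1)
    p.write_text(bad)
    with pytest.raises(ValueError, match="row 2"):
        ml.parse_pssm(p)


def test_pssm_writer_roundtrip(small_dataset, tmp_path):
    for pid in list(small_dataset.pssms)[:3]:
        raw = small_dataset.pssms[pid]
        ml.write_pssm(raw, tmp_path / "x.pssm")
        back = ml.parse_pssm(tmp_path / "x.pssm", expected_query=raw.query_sequence)
        assert np.array_equal(back.values, raw.values)


# --------------------------------------------------------------- sigmoid
def test_squash_fixed_point_and_saturation():
    raw = ml.RawPSSM(np.zeros((1, 20)), "A")
    assert np.all(ml.squash_pssm(raw).values == 0.5)
    raw = ml.RawPSSM(np.full((1, 20), 50.0), "A")
    assert np.all(np.abs(ml.squash_pssm(raw).values - 1.0) < 1e-9)


def test_squash_matches_scalar_loop(rng):
    vals = rng.normal(0, 4, size=(7, 20))
    raw = ml.RawPSSM(vals, "M" * 7)
    out = ml.squash_pssm(raw).values
    for i in range(7):
        for j in range(20):
            assert out[i, j] == pytest.approx(1 / (1 + np.exp(-vals[i, j])), abs=1e-15)


@given(
    x=st.floats(-30, 20, allow_nan=False),
    delta=st.floats(1e-6, 10, allow_nan=False),
)
@settings(max_examples=100, derandomize=True)
def test_squash_strictly_increasing_and_bounded(x, delta):
    """Strictly increasing and open-bounded within float64's resolvable range.

    (Real profile log-odds are small integers, far from the ~|x| > 36
    regime where the sigmoid saturates to exactly 0.0/1.0 in float64.)
    """
    raw = ml.RawPSSM(np.array([[x] * 19 + [x + delta]]), "A")
    out = ml.squash_pssm(raw).values
    assert np.all((out > 0) & (out < 1))
    assert out[0, 19] > out[0, 0]


def test_squash_saturates_within_closed_bounds_for_extreme_inputs():
    raw = ml.RawPSSM(np.array([[-700.0] * 10 + [700.0] * 10]), "A")
    out = ml.squash_pssm(raw).values
    assert np.all((out >= 0) & (out <= 1))


# ---------------------------------------------------------------- concat
def test_concat_pssm_prop_is_30_channels(small_dataset):
    rec = small_dataset.records[0]
    fm = ml.encode_features(rec, "PSSM+PROP", small_dataset.pssms[rec.id])
    assert fm.values.shape == (len(rec.sequence), 30)
    assert fm.feature_set == "PSSM+PROP"


def test_concat_single_part_identity():
    fm = ml.encode_onehot(ml.ProteinRecord("x", "MKV"))
    assert ml.concat_features([fm]) is fm


def test_concat_three_parts_column_order():
    rec = ml.ProteinRecord("x", "MKV")
    a, b = ml.encode_onehot(rec), ml.encode_prop(rec)
    out = ml.concat_features([a, b, a])
    assert out.values.shape == (3, 50)
    assert np.array_equal(out.values[:, :20], a.values)
    assert np.array_equal(out.values[:, 20:30], b.values)
    assert np.array_equal(out.values[:, 30:], a.values)


def test_concat_mismatched_lengths_error():
    a = ml.encode_onehot(ml.ProteinRecord("x", "MKV"))
    b = ml.encode_prop(ml.ProteinRecord("y", "MK"))
    with pytest.raises(ValueError, match="length"):
        ml.concat_features([a, b])
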
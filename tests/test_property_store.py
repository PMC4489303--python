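"""Built-in index tables, standardization and user-defined index files."""

import math

import numpy as np
import pytest

from pseqfeat import Alphabet, PropertyIndex, load_builtin, normalize_index
from pseqfeat.property_store import (
    DegeneratePropertyError,
    IndexParseError,
    UnknownPropertyError,
    oligomers,
    parse_user_index,
    resolve_properties,
    write_user_index,
)


def _mono_index(vals):
    # mononucleotide-style analog realised as a protein index is clumsy;
    # use a dinucleotide index with the 4 distinct values cycled instead
    oset = oligomers(Alphabet.DNA, 2)
    return PropertyIndex(
        "probe", Alphabet.DNA, 2, {o: float(vals[i % len(vals)]) for i, o in enumerate(oset)}
    )


class TestNormalizeIndex:
    def test_zscore_matches_direct_arithmetic(self):
        # oracle: mean/SD computed by plain arithmetic on {1,2,3,4} repeated
        p = _mono_index([1, 2, 3, 4])
        raw = [1.0, 2.0, 3.0, 4.0] * 4
        mean = sum(raw) / 16
        sd = math.sqrt(sum((v - mean) ** 2 for v in raw) / 16)
        expected = {o: (p.values[o] - mean) / sd for o in p.values}
        z = normalize_index(p)
        for o, v in expected.items():
            assert z.values[o] == pytest.approx(v, abs=1e-12)
        arr = z.array()
        assert abs(arr.mean()) < 1e-9
        assert abs(arr.std() - 1.0) < 1e-9

    def test_symmetric_values_symmetric_zscores(self):
        z = normalize_index(_mono_index([1, 2, 3, 4])).array()
        assert np.allclose(sorted(z), -np.array(sorted(z))[::-1])

    def test_idempotent_on_normalized(self):
        z = normalize_index(_mono_index([5, 1, 2, 9]))
        again = normalize_index(z)
        assert np.allclose(z.array(), again.array(), atol=1e-12)

    def test_constant_index_is_degenerate(self):
        with pytest.raises(DegeneratePropertyError):
            normalize_index(_mono_index([5.0]))

    def test_rank_order_preserved(self):
        p = _mono_index([10, -3, 7, 0.5])
        z = normalize_index(p)
        raw, zs = p.array(), z.array()
        assert np.array_equal(np.argsort(raw, kind="stable"), np.argsort(zs, kind="stable"))


class TestBuiltins:
    @pytest.mark.parametrize(
        "alphabet,g,count",
        [
            (Alphabet.DNA, 2, 148),
            (Alphabet.DNA, 3, 12),
            (Alphabet.RNA, 2, 22),
            (Alphabet.PROTEIN, 1, 547),
        ],
    )
    def test_catalogue_sizes_and_uniqueness(self, alphabet, g, count):
        table = load_builtin(alphabet, g)
        assert len(table) == count
        names = [p.name for p in table]
        assert len(set(names)) == count
        for p in table:
            assert set(p.values) == set(oligomers(alphabet, g))

    def test_deterministic_across_calls(self):
        a = load_builtin(Alphabet.RNA, 2)
        b = load_builtin(Alphabet.RNA, 2)
        assert [p.name for p in a] == [p.name for p in b]
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.array(), pb.array())

    def test_every_builtin_normalizes(self):
        for alphabet, g in [(Alphabet.DNA, 2), (Alphabet.DNA, 3),
                            (Alphabet.RNA, 2), (Alphabet.PROTEIN, 1)]:
            for p in load_builtin(alphabet, g):
                z = normalize_index(p)
                assert abs(z.array().mean()) < 1e-9
                assert abs(z.array().std() - 1.0) < 1e-9

    def test_unsupported_slot_rejected(self):
        with pytest.raises(ValueError, match="no built-in"):
            load_builtin(Alphabet.RNA, 3)

    def test_curated_tables_lead_the_catalogue(self):
        di = [p.name for p in load_builtin(Alphabet.DNA, 2)]
        assert di[:6] == ["Twist", "Tilt", "Roll", "Shift", "Slide", "Rise"]
        aa = [p.name for p in load_builtin(Alphabet.PROTEIN, 1)]
        assert aa[:3] == ["Hydrophobicity", "Hydrophilicity", "SideChainMass"]


class TestUserIndexFiles:
    HEADER = "\t".join(["oligomer"] + list(oligomers(Alphabet.DNA, 2)))

    def test_minimal_valid_file(self):
        row = "MyProp\t" + "\t".join(str(i) for i in range(16))
        (p,) = parse_user_index(self.HEADER + "\n" + row, Alphabet.DNA, 2)
        assert p.name == "MyProp"
        assert p.values["AA"] == 0.0 and p.values["TT"] == 15.0

    def test_comma_delimited_accepted(self):
        header = ",".join(["oligomer"] + list(oligomers(Alphabet.DNA, 2)))
        row = "P1," + ",".join("1" for _ in range(16))
        (p,) = parse_user_index(header + "\n" + row, Alphabet.DNA, 2)
        assert len(p.values) == 16

    def test_short_row_is_error(self):
        row = "P1\t" + "\t".join("1" for _ in range(15))
        with pytest.raises(IndexParseError, match="row 2.*expected 16 values, got 15"):
            parse_user_index(self.HEADER + "\n" + row, Alphabet.DNA, 2)

    def test_duplicate_name_is_error(self):
        rows = "\n".join("Same\t" + "\t".join("1" if i else "2" for i in range(16))
                         for _ in range(2))
        with pytest.raises(IndexParseError, match="duplicate property name"):
            parse_user_index(self.HEADER + "\n" + rows, Alphabet.DNA, 2)

    def test_non_numeric_cell_has_coordinates(self):
        cells = ["1"] * 16
        cells[4] = "oops"
        row = "P1\t" + "\t".join(cells)
        with pytest.raises(IndexParseError, match="row 2, column 6"):
            parse_user_index(self.HEADER + "\n" + row, Alphabet.DNA, 2)

    def test_wrong_header_order_is_error(self):
        bad = "\t".join(["oligomer"] + list(reversed(oligomers(Alphabet.DNA, 2))))
        with pytest.raises(IndexParseError, match="row 1"):
            parse_user_index(bad + "\nP\t" + "\t".join(["1"] * 16), Alphabet.DNA, 2)

    def test_write_parse_round_trip(self):
        table = load_builtin(Alphabet.DNA, 2)[:5]
        text = write_user_index(table, precision=10)
        back = parse_user_index(text, Alphabet.DNA, 2)
        assert [p.name for p in back] == [p.name for p in table]
        for pa, pb in zip(table, back):
            assert np.allclose(pa.array(), pb.array(), rtol=1e-9)


class TestResolveProperties:
    def test_unknown_name_lists_near_matches(self):
        with pytest.raises(UnknownPropertyError, match="twist"):
            resolve_properties(["twist"], Alphabet.DNA, 2)

    def test_user_index_shadows_builtin(self):
        oset = oligomers(Alphabet.DNA, 2)
        mine = PropertyIndex("Twist", Alphabet.DNA, 2, {o: float(i) for i, o in enumerate(oset)})
        (got,) = resolve_properties(["Twist"], Alphabet.DNA, 2, user_indices=[mine])
        assert got.values["TT"] == 15.0
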
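"""Grammar, composition arithmetic and canonicalization."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from olimp.glycan import (
    Composition,
    DEFAULT_REGISTRY,
    GrammarError,
    ResidueClass,
    SidechainDef,
    SidechainRegistry,
    XGOStructure,
    canonical_representative,
    composition_of,
    parse_structure,
)

CODES = DEFAULT_REGISTRY.codes


class TestComposition:
    def test_mapping_and_arithmetic(self):
        c = Composition(Hex=5, Pent=3, dHex=1)
        assert c[ResidueClass.HEX] == 5 and c["Pent"] == 3 and c["Ac"] == 0
        assert (c + Composition(Hex=1)).nonzero()[ResidueClass.HEX] == 6
        assert c - Composition(dHex=1) == Composition(Hex=5, Pent=3)
        with pytest.raises(ValueError):
            c - Composition(HexA=1)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            Composition(Hex=-1)

    def test_hashable_and_pure_hexose_flag(self):
        assert Composition(Hex=6) == Composition({ResidueClass.HEX: 6})
        assert Composition(Hex=6).is_pure_hexose
        assert not Composition(Hex=6, Pent=1).is_pure_hexose
        assert len({Composition(Hex=1), Composition(Hex=1)}) == 1


class TestParseRender:
    @pytest.mark.parametrize(
        "text, codes, nac",
        [
            ("XXFG", ("X", "X", "F", "G"), 0),
            ("G", ("G",), 0),
            ("LPGGG+1Ac", ("L", "P", "G", "G", "G"), 1),
        ],
    )
    def test_parse(self, text, codes, nac):
        s = parse_structure(text)
        assert s.codes == codes and s.acetyl_count == nac

    @pytest.mark.parametrize("bad", ["", "   ", "XZG", "xxfg", "X+Ac"])
    def test_rejections(self, bad):
        with pytest.raises(GrammarError):
            parse_structure(bad)

    def test_unknown_letter_names_position(self):
        with pytest.raises(GrammarError, match="'Z' at position 2"):
            parse_structure("XZG")

    def test_roundtrip_exhaustive_short(self):
        # every registry string up to length 3, with and without acetyls
        for n in (1, 2, 3):
            for codes in itertools.product(CODES, repeat=n):
                for nac in (0, 2):
                    s = XGOStructure(codes, nac)
                    assert parse_structure(s.render()) == s

    @given(
        codes=st.lists(st.sampled_from(CODES), min_size=1, max_size=8),
        nac=st.integers(min_value=0, max_value=3),
    )
    @settings(derandomize=True, max_examples=200)
    def test_roundtrip_property(self, codes, nac):
        s = XGOStructure(tuple(codes), nac)
        assert parse_structure(s.render()) == s


class TestCompositionOf:
    @pytest.mark.parametrize(
        "code, expected",
        [
            ("XXFG", Composition(Hex=5, Pent=3, dHex=1)),
            ("G", Composition(Hex=1)),
            ("LPGGG", Composition(Hex=7, Pent=2, HexA=1)),
            ("XXXG", Composition(Hex=4, Pent=3)),
            ("LPGGG+1Ac", Composition(Hex=7, Pent=2, HexA=1, Ac=1)),
        ],
    )
    def test_examples(self, code, expected):
        assert composition_of(parse_structure(code)) == expected

    @given(
        a=st.lists(st.sampled_from(CODES), min_size=1, max_size=5),
        b=st.lists(st.sampled_from(CODES), min_size=1, max_size=5),
    )
    @settings(derandomize=True, max_examples=200)
    def test_additive_under_concatenation(self, a, b):
        sa, sb = XGOStructure(tuple(a)), XGOStructure(tuple(b))
        cat = XGOStructure(tuple(a) + tuple(b))
        assert composition_of(cat) == composition_of(sa) + composition_of(sb)


class TestCanonicalRepresentative:
    @pytest.mark.parametrize(
        "candidates, winner",
        [
            ({"XFG", "FXG"}, "XFG"),
            ({"XXFG", "XFXG", "FXXG"}, "XXFG"),
            ({"G"}, "G"),
        ],
    )
    def test_most_decorated_toward_reducing_end(self, candidates, winner):
        structs = {parse_structure(c) for c in candidates}
        assert canonical_representative(structs).render() == winner

    def test_idempotent_and_member(self):
        structs = {parse_structure(c) for c in ("XXPG", "XPXG", "PXXG")}
        rep = canonical_representative(structs)
        assert rep in structs
        assert canonical_representative({rep}) == rep

    def test_rejects_empty_and_mixed(self):
        with pytest.raises(ValueError):
            canonical_representative(set())
        with pytest.raises(ValueError):
            canonical_representative({parse_structure("XG"), parse_structure("XXG")})


class TestRegistryInvariants:
    def test_default_alphabet(self, registry):
        assert set(registry.codes) == set("GXLFSDEBYP")
        assert registry["G"].residues.total() == 0
        for code in registry:
            if code != "G":
                assert registry[code].residues[ResidueClass.PENT] >= 1

    def test_trim_pairs(self, registry):
        assert registry["F"].trim_target == "L"
        assert registry["L"].trim_target == "X"
        assert registry["P"].trim_target == "Y"
        assert registry["E"].trim_target == "D"

    def test_inconsistent_trim_rejected(self):
        bad = SidechainDef(
            "Z", Composition(Pent=1, Hex=2), ResidueClass.HEX, "X"
        )  # X has Pent=1, but Z minus one Hex would be Pent=1,Hex=1
        with pytest.raises(GrammarError):
            SidechainRegistry(list(DEFAULT_REGISTRY.values()) + [bad])

    def test_extension(self, registry):
        q = SidechainDef("Q", Composition(Pent=1, Hex=2, HexA=1))
        extended = registry.extended([q])
        assert "Q" in extended and "Q" not in registry
        assert composition_of(parse_structure("QG", extended), extended) == Composition(
            Hex=4, Pent=1, HexA=1
        )
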
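"""Mass arithmetic, adduct m/z and composition/structure enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from olimp.glycan import Composition, DEFAULT_REGISTRY, ResidueClass, parse_structure, composition_of
from olimp.mass import (
    ADDUCTS,
    AVERAGE,
    DEFAULT_BOUNDS,
    MONOISOTOPIC,
    NOMINAL,
    SODIUM,
    adduct_mz,
    enumerate_compositions,
    enumerate_structures,
    neutral_mass,
    structure_mz,
)

CODES = DEFAULT_REGISTRY.codes


class TestNeutralMass:
    @pytest.mark.parametrize(
        "comp, conv, expected",
        [
            (Composition(Hex=1), MONOISOTOPIC, 180.063),
            (Composition(Hex=5, Pent=3, dHex=1), MONOISOTOPIC, 1370.459),
            (Composition(Hex=6, Pent=1), AVERAGE, 1122.973),
        ],
    )
    def test_examples(self, comp, conv, expected):
        assert neutral_mass(comp, conv) == pytest.approx(expected, abs=1e-3)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            neutral_mass(Composition())

    @given(
        counts=st.tuples(*[st.integers(0, 4) for _ in range(5)]),
        cls=st.sampled_from(list(ResidueClass)),
    )
    @settings(derandomize=True, max_examples=150)
    def test_strictly_monotone_in_every_class(self, counts, cls):
        base = Composition(dict(zip(ResidueClass, counts)))
        if base.total() == 0:
            base = base + Composition(Hex=1)
        bigger = base + Composition({cls: 1})
        assert neutral_mass(bigger) > neutral_mass(base)


class TestAdductMz:
    @pytest.mark.parametrize(
        "code, conv, rounding, expected",
        [
            ("XXFG", MONOISOTOPIC, "truncate", 1393),
            ("LGGGG", AVERAGE, "nearest", 1146),
            ("XLFG", MONOISOTOPIC, "truncate", 1555),
        ],
    )
    def test_sodiated_integer_values(self, code, conv, rounding, expected):
        s = parse_structure(code)
        assert structure_mz(s, conv, SODIUM, rounding) == expected

    def test_structure_vs_composition_path_agree(self):
        rng = np.random.default_rng(20260901)
        for _ in range(100):
            codes = tuple(rng.choice(CODES, size=rng.integers(1, 7)))
            s = parse_structure("".join(codes))
            for conv in (MONOISOTOPIC, AVERAGE, NOMINAL):
                for adduct in ADDUCTS.values():
                    via_structure = structure_mz(s, conv, adduct)
                    via_comp = adduct_mz(composition_of(s), conv, adduct)
                    assert abs(via_structure - via_comp) < 1e-9

    def test_disodiated_acid_offset(self):
        # [M+2Na-H]+ sits ~22 Da above [M+Na]+: the 1423/1445 pattern
        comp = Composition(Hex=5, Pent=3, HexA=1)
        mono = adduct_mz(comp, MONOISOTOPIC, SODIUM)
        di = adduct_mz(comp, MONOISOTOPIC, ADDUCTS["+2Na-H"])
        assert di - mono == pytest.approx(21.98194, abs=1e-5)


def _oracle_enumerate(mz, conv, adduct, tol, bounds):
    """Independent brute force: explicit nested loops, no shared helpers."""
    hits = set()
    masses = conv.residue_masses
    for h in range(bounds[ResidueClass.HEX] + 1):
        for p in range(bounds[ResidueClass.PENT] + 1):
            for d in range(bounds[ResidueClass.DHEX] + 1):
                for u in range(bounds[ResidueClass.HEXA] + 1):
                    for a in range(bounds[ResidueClass.AC] + 1):
                        if h + p + d + u + a == 0:
                            continue
                        theo = (
                            h * masses[ResidueClass.HEX]
                            + p * masses[ResidueClass.PENT]
                            + d * masses[ResidueClass.DHEX]
                            + u * masses[ResidueClass.HEXA]
                            + a * masses[ResidueClass.AC]
                            + conv.water
                            + adduct.delta
                        )
                        if abs(mz - theo) <= tol:
                            hits.add((h, p, d, u, a))
    return hits


class TestEnumerateCompositions:
    def test_known_assignments(self):
        res = enumerate_compositions(1085.34, tol=0.3)
        assert Composition(Hex=4, Pent=3) in [m.composition for m in res]
        res = enumerate_compositions(1423.42, tol=0.3)
        assert Composition(Hex=5, Pent=3, HexA=1) in [m.composition for m in res]

    def test_single_hexose(self):
        res = enumerate_compositions(203.05, tol=0.3)
        assert [m.composition for m in res] == [Composition(Hex=1)]

    def test_sorted_by_abs_error_and_signed(self):
        res = enumerate_compositions(1423.45, tol=0.5)
        errs = [abs(m.error) for m in res]
        assert errs == sorted(errs)
        top = res[0]
        assert top.error == pytest.approx(1423.45 - top.theoretical_mz, abs=1e-9)

    def test_out_of_range_warns_but_answers(self):
        with pytest.warns(UserWarning, match="acquisition range"):
            res = enumerate_compositions(150.0, tol=0.5)
        assert res.out_of_range

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(123)
        for mz in rng.uniform(200, 4000, size=100):
            got = {
                tuple(m.composition[c] for c in ResidueClass)
                for m in enumerate_compositions(float(mz), tol=0.5)
            }
            want = _oracle_enumerate(float(mz), MONOISOTOPIC, SODIUM, 0.5, DEFAULT_BOUNDS)
            assert got == want, f"mismatch at m/z {mz}"


class TestEnumerateStructures:
    def test_uronic_tetraose_isomers(self):
        structs = enumerate_structures(
            Composition(Hex=5, Pent=3, HexA=1), backbone_range=(4, 4)
        )
        names = {s.render() for s in structs}
        assert {"XXPG", "XPXG", "PXXG", "BPGG"} <= names

    def test_trivial_g(self):
        structs = enumerate_structures(Composition(Hex=1), backbone_range=(1, 1))
        assert [s.render() for s in structs] == ["G"]

    def test_mixed_backbone_lengths(self):
        names = {s.render() for s in enumerate_structures(
            Composition(Hex=4, Pent=2), backbone_range=(3, 4)
        )}
        assert {"XLG", "LXG", "XXGG"} <= names
        # first entry minimises unsubstituted units: the paper-style XLG
        first = enumerate_structures(Composition(Hex=4, Pent=2), backbone_range=(3, 4))[0]
        assert first.render() == "XLG"

    def test_unachievable_composition_is_empty(self):
        assert enumerate_structures(Composition(dHex=2), backbone_range=(2, 4)) == []

    def test_every_result_matches_composition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            codes = tuple(rng.choice(CODES, size=rng.integers(2, 5)))
            comp = composition_of(parse_structure("".join(codes)))
            for s in enumerate_structures(comp, backbone_range=(2, 5), reducing_end_G=False):
                assert composition_of(s) == comp

    def test_reducing_end_constraint(self):
        for s in enumerate_structures(Composition(Hex=4, Pent=3), backbone_range=(2, 6)):
            assert s.codes[-1] == "G"
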
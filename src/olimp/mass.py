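"""Residue-mass tables, adduct arithmetic and candidate enumeration.

MALDI-ToF of neutral glycans yields almost exclusively singly charged
sodium adducts [M+Na]+, so all m/z here is charge 1.  Residue masses are
*glycosidic* residue masses (monosaccharide minus water); a neutral
oligosaccharide is the sum of its residue masses plus one water.

Three mass conventions are first-class because published integer m/z
values mix them: monoisotopic (most-abundant isotopologue), average
(isotope-abundance weighted) and nominal (integer) masses.  Reports always
state which convention produced a number.

The electron mass is ignored in cation m/z (≈5e-4 Da, far below the
tolerances used anywhere in this package).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from .glycan import (
    DEFAULT_REGISTRY,
    Composition,
    ResidueClass,
    SidechainRegistry,
    XGOStructure,
    composition_of,
    decoration_weights,
)

__all__ = [
    "MassConvention",
    "MONOISOTOPIC",
    "AVERAGE",
    "NOMINAL",
    "CONVENTIONS",
    "Adduct",
    "ADDUCTS",
    "SODIUM",
    "neutral_mass",
    "adduct_mz",
    "structure_mz",
    "CompositionMatch",
    "CompositionMatches",
    "enumerate_compositions",
    "enumerate_structures",
    "DEFAULT_BOUNDS",
    "ACQUISITION_RANGE",
]

#: MALDI acquisition window used as a validity bound for observed m/z.
ACQUISITION_RANGE: tuple[float, float] = (200.0, 4000.0)


@dataclass(frozen=True)
class MassConvention:
    """A named residue-mass table.

    ``rounding`` is how a final m/z is reported under this convention:
    ``"none"`` (full precision), ``"nearest"`` or ``"truncate"``.
    """

    name: str
    residue_masses: Mapping[ResidueClass, float]
    water: float
    rounding: str = "none"

    def __post_init__(self) -> None:
        if self.rounding not in ("none", "nearest", "truncate"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")
        missing = [c for c in ResidueClass if c not in self.residue_masses]
        if missing:
            raise ValueError(f"mass table {self.name!r} missing classes {missing}")

    def mass(self, cls: "ResidueClass | str") -> float:
        if not isinstance(cls, ResidueClass):
            cls = ResidueClass(cls)
        return self.residue_masses[cls]

    def rounded(self, mz: float, rounding: Optional[str] = None) -> float:
        mode = self.rounding if rounding is None else rounding
        if mode == "none":
            return mz
        if mode == "nearest":
            return float(round(mz))
        return float(math.floor(mz))

    def with_rounding(self, rounding: str) -> "MassConvention":
        return replace(self, rounding=rounding)


MONOISOTOPIC = MassConvention(
    "monoisotopic",
    {
        ResidueClass.HEX: 162.05282,
        ResidueClass.PENT: 132.04226,
        ResidueClass.DHEX: 146.05791,
        ResidueClass.HEXA: 176.03209,
        ResidueClass.AC: 42.01057,
    },
    water=18.01056,
)

AVERAGE = MassConvention(
    "average",
    {
        ResidueClass.HEX: 162.1406,
        ResidueClass.PENT: 132.1146,
        ResidueClass.DHEX: 146.1412,
        ResidueClass.HEXA: 176.1241,
        ResidueClass.AC: 42.0373,
    },
    water=18.0153,
)

NOMINAL = MassConvention(
    "nominal",
    {
        ResidueClass.HEX: 162.0,
        ResidueClass.PENT: 132.0,
        ResidueClass.DHEX: 146.0,
        ResidueClass.HEXA: 176.0,
        ResidueClass.AC: 42.0,
    },
    water=18.0,
)

CONVENTIONS: dict[str, MassConvention] = {
    c.name: c for c in (MONOISOTOPIC, AVERAGE, NOMINAL)
}


@dataclass(frozen=True)
class Adduct:
    """A cationizing adduct: label and mass added to the neutral molecule."""

    label: str
    delta: float


SODIUM = Adduct("+Na", 22.98977)

ADDUCTS: dict[str, Adduct] = {
    "+Na": SODIUM,
    "+K": Adduct("+K", 38.96371),
    "+H": Adduct("+H", 1.00783),
    # Acidic XGOs can exchange a carboxyl proton for a second sodium.
    "+2Na-H": Adduct("+2Na-H", 44.97171),
}


def neutral_mass(c: Composition, conv: MassConvention = MONOISOTOPIC) -> float:
    """Neutral mass in Da: Σ count × residue mass, plus one water."""
    if c.total() == 0:
        raise ValueError("cannot take the mass of an empty composition")
    return sum(c[cls] * conv.residue_masses[cls] for cls in ResidueClass) + conv.water


def adduct_mz(
    c: Composition,
    conv: MassConvention = MONOISOTOPIC,
    adduct: Adduct = SODIUM,
    rounding: Optional[str] = None,
) -> float:
    """Singly charged adduct m/z, reported per the convention's rounding.

    ``rounding`` overrides the convention's mode for this one call.
    """
    return conv.rounded(neutral_mass(c, conv) + adduct.delta, rounding)


def structure_mz(
    s: XGOStructure,
    conv: MassConvention = MONOISOTOPIC,
    adduct: Adduct = SODIUM,
    rounding: Optional[str] = None,
    registry: SidechainRegistry = DEFAULT_REGISTRY,
) -> float:
    """Adduct m/z of a structure (composition is derived first)."""
    return adduct_mz(composition_of(s, registry), conv, adduct, rounding)


#: Default enumeration bounds: generous for a 4–6 unit XGO pool while
#: keeping the search space small.
DEFAULT_BOUNDS: dict[ResidueClass, int] = {
    ResidueClass.HEX: 10,
    ResidueClass.PENT: 6,
    ResidueClass.DHEX: 2,
    ResidueClass.HEXA: 3,
    ResidueClass.AC: 2,
}


@dataclass(frozen=True)
class CompositionMatch:
    """One composition consistent with an observed peak.

    ``error`` is signed, observed − theoretical, in Da.
    """

    composition: Composition
    error: float
    theoretical_mz: float


class CompositionMatches(list):
    """List of :class:`CompositionMatch` sorted by |error|.

    ``out_of_range`` flags queries outside the acquisition window; such
    queries are answered anyway (the flag is a warning, not a rejection).
    """

    def __init__(self, matches: Iterable[CompositionMatch] = (), out_of_range: bool = False):
        super().__init__(matches)
        self.out_of_range = out_of_range


def enumerate_compositions(
    mz: float,
    conv: MassConvention = MONOISOTOPIC,
    adduct: Adduct = SODIUM,
    tol: float = 0.5,
    bounds: Optional[Mapping[ResidueClass, int]] = None,
    acquisition_range: tuple[float, float] = ACQUISITION_RANGE,
) -> CompositionMatches:
    """All residue-class count vectors whose [M+adduct]+ lies within ``tol``.

    Exhaustive iteration over every count vector within ``bounds``
    (defaults: Hex ≤ 10, Pent ≤ 6, dHex ≤ 2, HexA ≤ 3, Ac ≤ 2), sorted by
    absolute mass error.  The default ±0.5 Da tolerance suits
    integer-reported MALDI peaks.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    bounds = dict(DEFAULT_BOUNDS) if bounds is None else dict(bounds)
    out_of_range = not (acquisition_range[0] <= mz <= acquisition_range[1])
    if out_of_range:
        warnings.warn(
            f"m/z {mz} outside the acquisition range {acquisition_range}", stacklevel=2
        )

    classes = list(ResidueClass)
    ranges = [range(bounds.get(cls, 0) + 1) for cls in classes]
    matches = []
    for counts in itertools.product(*ranges):
        if not any(counts):
            continue
        c = Composition(dict(zip(classes, counts)))
        theo = neutral_mass(c, conv) + adduct.delta
        err = mz - theo
        if abs(err) <= tol:
            matches.append(CompositionMatch(c, err, theo))
    matches.sort(key=lambda m: abs(m.error))
    return CompositionMatches(matches, out_of_range)


def enumerate_structures(
    c: Composition,
    registry: SidechainRegistry = DEFAULT_REGISTRY,
    backbone_range: tuple[int, int] = (2, 6),
    reducing_end_G: bool = True,
    allowed_codes: Optional[Sequence[str]] = None,
) -> list[XGOStructure]:
    """All code assignments over the backbone range matching composition ``c``.

    The default backbone range 2–6 spans XXG-type cores through the
    five-glucose sparsely branched GGGG-type cores.  With
    ``reducing_end_G`` the last unit is pinned to G, matching
    endo-glucanase products.  Returns an empty list (not an error) for
    unachievable compositions.  Structures are sorted by fewest
    unsubstituted units, then decoration-weight order, so the first entry
    is the display representative (see :func:`canonical_representative`
    for the fixed-backbone rule).
    """
    codes = list(allowed_codes) if allowed_codes is not None else list(registry.codes)
    for code in codes:
        if code not in registry:
            raise KeyError(f"allowed code {code!r} not in registry")
    lo, hi = backbone_range
    results: list[XGOStructure] = []
    n_ac = c[ResidueClass.AC]

    for length in range(max(lo, 1), hi + 1):
        backbone = Composition(Hex=length, Ac=n_ac)
        try:
            budget = c - backbone
        except ValueError:
            continue  # more backbone glucoses than Hex available

        def assign(pos: int, remaining: Composition, acc: list[str]) -> None:
            if pos == length:
                if remaining.total() == 0:
                    results.append(XGOStructure(tuple(acc), n_ac))
                return
            if reducing_end_G and pos == length - 1:
                pool = ["G"] if "G" in codes else []
            else:
                pool = codes
            for code in pool:
                res = registry[code].residues
                try:
                    nxt = remaining - res
                except ValueError:
                    continue
                # prune: remaining residues must be placeable on remaining units
                acc.append(code)
                assign(pos + 1, nxt, acc)
                acc.pop()

        assign(0, budget, [])

    def sort_key(s: XGOStructure):
        return (s.codes.count("G"), decoration_weights(s, registry), s.render())

    results.sort(key=sort_key)
    return results
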
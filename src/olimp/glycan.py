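"""Xyloglucan one-letter sidechain grammar and composition arithmetic.

Xyloglucan (XyG) is a β-1,4-glucan whose backbone glucoses carry α-1,6
sidechains.  Endo-glucanase digestion releases xyloglucan oligosaccharides
(XGOs) that are written in the field's one-letter code: one letter per
backbone glucosyl unit, reducing end last.  ``G`` is an unsubstituted
glucose, ``X`` carries a single xylose, ``L`` adds a galactose on the
xylose, ``F`` adds a fucose on that galactose, ``Y``/``P`` carry uronic
acid decorations, and ``S``/``D``/``B``/``E`` are the pentose–pentose
variants found outside the core set.

This module provides:

* :class:`ResidueClass` — the five mass-bearing residue classes
  (Hex, Pent, dHex, HexA and the O-acetyl substituent Ac);
* :class:`Composition` — residue-class counts, the mass abstraction;
* :class:`SidechainDef` and :class:`SidechainRegistry` — the grammar's
  alphabet, extensible via a plain-text table;
* :class:`XGOStructure` with :func:`parse_structure` /
  :meth:`XGOStructure.render` — the oligosaccharide itself;
* :func:`composition_of` and :func:`canonical_representative`.

Mass-degenerate letters (S, D and B all contain two pentoses) are kept as
distinct grammar symbols; they collapse only at the mass level, so
annotation downstream reports degeneracy groups rather than picking an
epimer.  Hex/HexA epimer identity (Gal vs Glc, GalA vs GlcA) is likewise
not modelled — single-stage MS cannot distinguish them.
"""

from __future__ import annotations

import enum
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from typing import Iterable, Optional

__all__ = [
    "ResidueClass",
    "Composition",
    "SidechainDef",
    "SidechainRegistry",
    "DEFAULT_REGISTRY",
    "XGOStructure",
    "parse_structure",
    "composition_of",
    "canonical_representative",
    "GrammarError",
]


class GrammarError(ValueError):
    """Raised for strings or structures that violate the one-letter grammar."""


class ResidueClass(str, enum.Enum):
    """The five residue classes carried by XGOs.

    ``Ac`` denotes an O-acetyl substituent, not a glycosyl residue; the
    other four are sugar residues counted per glycosidic unit.
    """

    HEX = "Hex"
    PENT = "Pent"
    DHEX = "dHex"
    HEXA = "HexA"
    AC = "Ac"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for composition storage and rendering.
RESIDUE_CLASSES: tuple[ResidueClass, ...] = (
    ResidueClass.HEX,
    ResidueClass.PENT,
    ResidueClass.DHEX,
    ResidueClass.HEXA,
    ResidueClass.AC,
)

_CLASS_INDEX = {cls: i for i, cls in enumerate(RESIDUE_CLASSES)}
_CLASS_BY_NAME = {cls.value: cls for cls in RESIDUE_CLASSES}


def _as_class(key: "ResidueClass | str") -> ResidueClass:
    if isinstance(key, ResidueClass):
        return key
    try:
        return _CLASS_BY_NAME[key]
    except KeyError:
        raise KeyError(f"unknown residue class {key!r}") from None


class Composition(Mapping[ResidueClass, int]):
    """Immutable residue-class count vector.

    Supports ``+`` and ``-`` (the latter raising if any count would go
    negative), hashing, and mapping access by :class:`ResidueClass` or by
    class name string.  ``Hex`` counts include backbone glucoses when the
    composition describes a whole oligosaccharide.

    Examples
    --------
    >>> Composition(Hex=5, Pent=3, dHex=1)["Hex"]
    5
    >>> Composition(Hex=1) + Composition(Pent=2)
    Composition(Hex=1, Pent=2)
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: "Mapping | None" = None, **kwargs: int):
        vec = [0] * len(RESIDUE_CLASSES)
        items: list[tuple[object, object]] = []
        if counts is not None:
            items.extend(counts.items())
        items.extend(kwargs.items())
        for key, value in items:
            cls = _as_class(key)  # type: ignore[arg-type]
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise TypeError(f"count for {cls.value} must be an int, got {value!r}")
            if value < 0:
                raise ValueError(f"negative count for {cls.value}: {value}")
            vec[_CLASS_INDEX[cls]] += value
        self._counts: tuple[int, ...] = tuple(vec)

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, key: "ResidueClass | str") -> int:
        return self._counts[_CLASS_INDEX[_as_class(key)]]

    def __iter__(self) -> Iterator[ResidueClass]:
        return iter(RESIDUE_CLASSES)

    def __len__(self) -> int:
        return len(RESIDUE_CLASSES)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Composition") -> "Composition":
        if not isinstance(other, Composition):
            return NotImplemented
        out = Composition()
        out._counts = tuple(a + b for a, b in zip(self._counts, other._counts))
        return out

    def __sub__(self, other: "Composition") -> "Composition":
        if not isinstance(other, Composition):
            return NotImplemented
        diff = tuple(a - b for a, b in zip(self._counts, other._counts))
        if any(d < 0 for d in diff):
            raise ValueError(f"subtraction would go negative: {self} - {other}")
        out = Composition()
        out._counts = diff
        return out

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Composition):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._counts)

    def __bool__(self) -> bool:
        return any(self._counts)

    def total(self) -> int:
        """Total unit count, acetyls included."""
        return sum(self._counts)

    def n_residues(self) -> int:
        """Glycosyl residue count (acetyls excluded)."""
        return sum(self._counts[:-1])

    def n_classes(self) -> int:
        """Number of distinct classes with a nonzero count."""
        return sum(1 for c in self._counts if c)

    @property
    def is_pure_hexose(self) -> bool:
        """True when only Hex is present — the contaminant-ladder signature."""
        return self._counts[0] > 0 and not any(self._counts[1:])

    def nonzero(self) -> dict[ResidueClass, int]:
        return {cls: n for cls, n in zip(RESIDUE_CLASSES, self._counts) if n}

    def __repr__(self) -> str:
        inner = ", ".join(f"{cls.value}={n}" for cls, n in self.nonzero().items())
        return f"Composition({inner})"


@dataclass(frozen=True)
class SidechainDef:
    """One letter of the XyG alphabet.

    Parameters
    ----------
    code
        Single uppercase letter.
    residues
        Residue content of the sidechain, *excluding* the backbone glucose
        it decorates.  Every substituted sidechain contains at least one
        Pent (the α-1,6 xylose).
    terminal_class, trim_target
        The exo-glycosidase-accessible terminal residue and the code left
        behind when it is removed (``F → L`` for fucosidase, ``L → X`` and
        ``P → Y`` for galactosidase, ``E → D``).  ``None`` when no modelled
        enzyme attacks the sidechain.
    ms_terminals
        All sterically terminal residues and the code each removal leaves —
        a superset of the enzymatic pair, used for tandem-MS neutral-loss
        prediction.  P lists two entries because its galactosyl and
        galacturonosyl both sit on the same xylose.
    """

    code: str
    residues: Composition
    terminal_class: Optional[ResidueClass] = None
    trim_target: Optional[str] = None
    ms_terminals: tuple[tuple[ResidueClass, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.code) != 1 or not self.code.isupper():
            raise GrammarError(f"sidechain code must be one uppercase letter, got {self.code!r}")
        if self.residues[ResidueClass.AC]:
            raise GrammarError("sidechains carry no acetyl counts; use XGOStructure.acetyl_count")
        if self.code == "G":
            if self.residues:
                raise GrammarError("G denotes an unsubstituted glucose: residues must be empty")
        elif self.residues[ResidueClass.PENT] < 1:
            raise GrammarError(
                f"sidechain {self.code} must contain at least one Pent (the alpha-1,6 xylose)"
            )
        if (self.terminal_class is None) != (self.trim_target is None):
            raise GrammarError(f"sidechain {self.code}: terminal_class and trim_target go together")


class SidechainRegistry(Mapping[str, SidechainDef]):
    """The grammar alphabet: code → :class:`SidechainDef`.

    Validates trim consistency on construction: whenever a sidechain names
    a ``trim_target``, that target must exist and its residues must equal
    this sidechain's residues minus one unit of the terminal class (and the
    same for every ``ms_terminals`` entry).
    """

    def __init__(self, defs: Iterable[SidechainDef]):
        self._defs: dict[str, SidechainDef] = {}
        for d in defs:
            if d.code in self._defs:
                raise GrammarError(f"duplicate sidechain code {d.code!r}")
            self._defs[d.code] = d
        self._validate()

    def _validate(self) -> None:
        for d in self._defs.values():
            pairs = list(d.ms_terminals)
            if d.terminal_class is not None:
                pairs.append((d.terminal_class, d.trim_target))  # type: ignore[arg-type]
            for cls, target in pairs:
                if target not in self._defs:
                    raise GrammarError(f"sidechain {d.code}: trim target {target!r} not in registry")
                expected = d.residues - Composition({cls: 1})
                if self._defs[target].residues != expected:
                    raise GrammarError(
                        f"sidechain {d.code}: removing one {cls.value} gives {expected}, "
                        f"but target {target} has {self._defs[target].residues}"
                    )

    def __getitem__(self, code: str) -> SidechainDef:
        return self._defs[code]

    def __iter__(self) -> Iterator[str]:
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._defs)

    def extended(self, defs: Iterable[SidechainDef]) -> "SidechainRegistry":
        """A new registry with ``defs`` added (or replacing same-coded entries)."""
        merged = dict(self._defs)
        for d in defs:
            merged[d.code] = d
        return SidechainRegistry(merged.values())


def _sd(code: str, terminal: Optional[ResidueClass] = None, trim: Optional[str] = None,
        ms: tuple[tuple[ResidueClass, str], ...] = (), **residues: int) -> SidechainDef:
    return SidechainDef(code, Composition(**residues), terminal, trim, ms)


_H, _P, _D, _U = ResidueClass.HEX, ResidueClass.PENT, ResidueClass.DHEX, ResidueClass.HEXA

#: Default alphabet.  The Q sidechain (galactose plus galacturonic acid with
#: additional decoration) is named in the literature without a fully stated
#: residue content, so it is not shipped here; add it via configuration once
#: its content is pinned down.
DEFAULT_REGISTRY = SidechainRegistry([
    _sd("G"),
    _sd("X", ms=((_P, "G"),), Pent=1),
    _sd("L", terminal=_H, trim="X", ms=((_H, "X"),), Pent=1, Hex=1),
    _sd("F", terminal=_D, trim="L", ms=((_D, "L"),), Pent=1, Hex=1, dHex=1),
    _sd("S", ms=((_P, "X"),), Pent=2),
    _sd("D", ms=((_P, "X"),), Pent=2),
    _sd("E", terminal=_D, trim="D", ms=((_D, "D"),), Pent=2, dHex=1),
    _sd("B", ms=((_P, "X"),), Pent=2),
    _sd("Y", ms=((_U, "X"),), Pent=1, HexA=1),
    # P's galactose and galacturonic acid both decorate the xylose, so both
    # are terminal: losing the Hex leaves Y, losing the HexA leaves L.
    _sd("P", terminal=_H, trim="Y", ms=((_H, "Y"), (_U, "L")), Pent=1, Hex=1, HexA=1),
])


_STRUCTURE_RE = re.compile(r"^(?P<codes>[A-Z]+)(?:\+(?P<nac>\d+)Ac)?$")


@dataclass(frozen=True)
class XGOStructure:
    """An XGO: ordered sidechain codes (reducing end last) plus acetyl count.

    O-acetylation is not positionally resolvable by mass, so acetyls are a
    single integer rendered as a ``+nAc`` suffix (``LPGGG+1Ac``).
    """

    codes: tuple[str, ...]
    acetyl_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        if len(self.codes) < 1:
            raise GrammarError("a structure needs at least one backbone unit")
        if self.acetyl_count < 0:
            raise GrammarError("acetyl_count must be non-negative")

    def render(self) -> str:
        suffix = f"+{self.acetyl_count}Ac" if self.acetyl_count else ""
        return "".join(self.codes) + suffix

    def __str__(self) -> str:
        return self.render()

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def backbone_length(self) -> int:
        return len(self.codes)

    def replace(self, index: int, code: str) -> "XGOStructure":
        codes = list(self.codes)
        codes[index] = code
        return XGOStructure(tuple(codes), self.acetyl_count)


def parse_structure(text: str, registry: SidechainRegistry = DEFAULT_REGISTRY) -> XGOStructure:
    """Parse a one-letter-code string such as ``"XXFG"`` or ``"LPGGG+1Ac"``.

    Raises :class:`GrammarError` naming the offending character and its
    1-based position for letters outside the registry, and for empty input.
    """
    if not isinstance(text, str) or not text.strip():
        raise GrammarError("empty structure string")
    text = text.strip()
    m = _STRUCTURE_RE.match(text)
    if m is None:
        raise GrammarError(f"malformed structure string {text!r}")
    codes = m.group("codes")
    for pos, ch in enumerate(codes, start=1):
        if ch not in registry:
            raise GrammarError(f"unknown sidechain code {ch!r} at position {pos} in {text!r}")
    nac = int(m.group("nac")) if m.group("nac") else 0
    return XGOStructure(tuple(codes), nac)


def composition_of(s: XGOStructure, registry: SidechainRegistry = DEFAULT_REGISTRY) -> Composition:
    """Residue-class content of a structure.

    Hex counts the backbone glucoses plus any sidechain hexoses; Ac is the
    structure's acetyl count.  Additive under backbone concatenation.
    """
    total = Composition(Hex=len(s.codes), Ac=s.acetyl_count)
    for code in s.codes:
        try:
            total = total + registry[code].residues
        except KeyError:
            raise GrammarError(f"structure uses code {code!r} absent from registry") from None
    return total


def decoration_weights(s: XGOStructure, registry: SidechainRegistry = DEFAULT_REGISTRY) -> tuple[int, ...]:
    """Per-position sidechain residue counts (0 for G)."""
    return tuple(registry[c].residues.total() for c in s.codes)


def canonical_representative(
    candidates: Iterable[XGOStructure],
    registry: SidechainRegistry = DEFAULT_REGISTRY,
) -> XGOStructure:
    """Pick the display representative of a set of isomeric structures.

    Among candidates sharing one composition and backbone length, returns
    the arrangement with the more decorated sidechains placed nearest the
    reducing-end glucose — the field's drawing convention — i.e. the
    candidate whose decoration-weight tuple is lexicographically smallest;
    ties break lexicographically on the code string.
    """
    cands = list(candidates)
    if not cands:
        raise ValueError("canonical_representative of an empty candidate set")
    lengths = {len(c) for c in cands}
    comps = {composition_of(c, registry) for c in cands}
    if len(lengths) > 1 or len(comps) > 1:
        raise ValueError("candidates must share one composition and backbone length")
    return min(cands, key=lambda c: (decoration_weights(c, registry), c.render()))
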
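"""Tandem-MS fragment prediction and terminal-residue inference.

MALDI tandem MS of sodiated XGOs is read almost entirely through neutral
losses from the parent ion: a fragment at precursor − 132 indicates a
terminal pentose, − 162 a terminal hexose, − 176 a terminal uronic acid,
− 146 a terminal deoxy-hexose.  Cross-ring cleavages appear as the two
characteristic neutral losses of 60 and 120 Da.  Only these loss types
are modelled — B/C/A/X ion taxonomy and charge-retention alternatives
add nothing to the interpretation of sodiated parents and are omitted.

"Terminal" follows glycosidic topology:

* each sidechain exposes the residues listed in its registry
  ``ms_terminals`` entry (e.g. P exposes both its galactose and its
  galacturonic acid, which sit on the same xylose);
* the reducing-end backbone glucose is removable only when unsubstituted;
* the non-reducing-end backbone unit can come off *with* its sidechain as
  a composite loss once its own sidechain depth allows (depth counts
  residues lost, so an X unit is a depth-2 composite).

Because branching order is generally not determinable by mass, fragment
evidence constrains the residue-class ambiguity set rather than fixing
sidechain positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

from .glycan import (
    DEFAULT_REGISTRY,
    ResidueClass,
    SidechainRegistry,
    XGOStructure,
)
from .mass import MONOISOTOPIC, SODIUM, Adduct, MassConvention, structure_mz

__all__ = [
    "CROSS_RING_LOSSES",
    "FragmentIon",
    "fragment_ions",
    "terminal_classes",
    "TerminalEvidence",
    "infer_terminals",
]

#: Cross-ring cleavage neutrals (C2H4O2 and C4H8O4), in Da.
CROSS_RING_LOSSES: tuple[float, float] = (60.02113, 120.04226)


@dataclass(frozen=True)
class FragmentIon:
    """A predicted fragment of the sodiated parent.

    ``lost`` is the multiset of residue classes removed (empty for
    cross-ring ions, whose loss is the small neutral in ``neutral``);
    ``depth`` counts sequentially lost residues (1 for cross-ring ions).
    """

    kind: str  # "terminal-loss" | "cross-ring"
    lost: tuple[ResidueClass, ...]
    mz: float
    depth: int
    neutral: Optional[float] = None  # cross-ring neutral mass


def _removal_moves(
    s: XGOStructure, registry: SidechainRegistry
) -> list[tuple[tuple[ResidueClass, ...], XGOStructure]]:
    """Single loss events available from a structure.

    Returns (classes lost, resulting structure) tuples; composite
    non-reducing-end unit losses report every residue of the unit.
    """
    moves: list[tuple[tuple[ResidueClass, ...], XGOStructure]] = []
    # sidechain terminal residues anywhere on the backbone
    for i, code in enumerate(s.codes):
        for cls, target in registry[code].ms_terminals:
            moves.append(((cls,), s.replace(i, target)))
    if len(s.codes) >= 2:
        # unsubstituted reducing-end glucose
        if s.codes[-1] == "G":
            moves.append(
                ((ResidueClass.HEX,), XGOStructure(s.codes[:-1], s.acetyl_count))
            )
        # non-reducing-end unit leaves with its whole sidechain
        first = registry[s.codes[0]].residues
        unit_lost = [ResidueClass.HEX]  # the backbone glucose itself
        for cls, n in first.nonzero().items():
            unit_lost.extend([cls] * n)
        moves.append((tuple(unit_lost), XGOStructure(s.codes[1:], s.acetyl_count)))
    return moves


def fragment_ions(
    s: XGOStructure,
    conv: MassConvention = MONOISOTOPIC,
    adduct: Adduct = SODIUM,
    max_depth: int = 2,
    registry: SidechainRegistry = DEFAULT_REGISTRY,
) -> list[FragmentIon]:
    """All neutral-loss fragments of the sodiated parent up to ``max_depth``.

    Enumerates every sequence of ≤ ``max_depth`` terminal removals (so the
    output is closed under loss-chain prefixes), de-duplicated by lost
    multiset, plus the two cross-ring losses from the precursor.  All
    fragment m/z are strictly below the precursor m/z.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    precursor = structure_mz(s, conv, adduct, registry=registry)
    ions: dict[tuple[str, tuple[ResidueClass, ...]], FragmentIon] = {}

    frontier: list[tuple[XGOStructure, tuple[ResidueClass, ...]]] = [(s, ())]
    for _ in range(max_depth):
        nxt: list[tuple[XGOStructure, tuple[ResidueClass, ...]]] = []
        for struct, lost in frontier:
            for classes, result in _removal_moves(struct, registry):
                new_lost = tuple(sorted(lost + classes, key=lambda c: c.value))
                depth = len(new_lost)
                if depth > max_depth:
                    continue
                mz = precursor - sum(conv.residue_masses[c] for c in new_lost)
                key = ("terminal-loss", new_lost)
                if key not in ions:
                    ions[key] = FragmentIon("terminal-loss", new_lost, mz, depth)
                nxt.append((result, new_lost))
        frontier = nxt

    out = list(ions.values())
    for neutral in CROSS_RING_LOSSES:
        out.append(FragmentIon("cross-ring", (), precursor - neutral, 1, neutral))
    out.sort(key=lambda f: -f.mz)
    return out


def terminal_classes(
    s: XGOStructure, registry: SidechainRegistry = DEFAULT_REGISTRY
) -> set[ResidueClass]:
    """Residue classes removable from ``s`` in a single loss event."""
    out: set[ResidueClass] = set()
    for code in s.codes:
        for cls, _target in registry[code].ms_terminals:
            out.add(cls)
    if len(s.codes) >= 2:
        # reducing-end glucose is exposed only when unsubstituted, and an
        # unsubstituted non-reducing-end glucose is itself a terminal hexose
        if s.codes[-1] == "G":
            out.add(ResidueClass.HEX)
        if s.codes[0] == "G":
            out.add(ResidueClass.HEX)
    return out


@dataclass
class TerminalEvidence:
    """Residue classes inferred from neutral losses.

    ``depth1`` holds classes seen as single losses; ``depth2`` the
    unordered class pairs seen as double losses (mass alone cannot order
    a chain, so pairs are reported sorted by class name).
    """

    depth1: set[ResidueClass]
    depth2: set[tuple[ResidueClass, ResidueClass]]


def infer_terminals(
    precursor_mz: float,
    fragments: Sequence[float],
    conv: MassConvention = MONOISOTOPIC,
    tol: float = 0.5,
) -> TerminalEvidence:
    """Read terminal residues off observed neutral losses.

    Each fragment whose loss (precursor − fragment) matches one residue
    mass within ``tol`` contributes a depth-1 terminal; losses matching a
    sum of two residue masses are reported as depth-2 pairs.  Requires at
    least one fragment.
    """
    if not fragments:
        raise ValueError("infer_terminals needs at least one fragment m/z")
    depth1: set[ResidueClass] = set()
    depth2: set[tuple[ResidueClass, ResidueClass]] = set()
    glyco = [c for c in ResidueClass if c is not ResidueClass.AC]
    for f in fragments:
        loss = precursor_mz - f
        for cls in glyco:
            if abs(loss - conv.residue_masses[cls]) <= tol:
                depth1.add(cls)
        for a, b in itertools.combinations_with_replacement(glyco, 2):
            if abs(loss - conv.residue_masses[a] - conv.residue_masses[b]) <= tol:
                pair = tuple(sorted((a, b), key=lambda c: c.value))
                depth2.add(pair)  # type: ignore[arg-type]
    return TerminalEvidence(depth1, depth2)
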
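"""In-silico models of the glycosidase treatments used in XyG profiling.

Five treatments are modelled, all as purely structural rewrites (no
kinetics, concentrations or pH — digestion here rationalises observed
oligosaccharide pools, it does not simulate reactors):

* **XEG-type endo-xyloglucanase** — hydrolyses the backbone after an
  unsubstituted glucose, releasing XXXG-type oligomers.
* **XcXGHA-type endo-xyloglucanase** — the complementary specificity:
  cleaves between two *substituted* backbone units.
* **Driselase** — degrades the oligosaccharide to free monosaccharides
  except for the Xyl-α-1,6-Glc disaccharide isoprimeverose, which it
  cannot split; isoprimeverose release is therefore diagnostic of XyG.
* **α-fucosidase** — removes the terminal deoxy-hexose (F → L, E → D).
* **β-galactosidase** — removes terminal hexoses from L and P sidechains
  (L → X, P → Y); F is resistant because its galactose is capped by the
  fucose.

Partial digestion (precursor and product co-present in a spectrum) is a
spectrum-level phenomenon handled in :mod:`olimp.spectra`; here a rewrite
either applies or it does not.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .glycan import (
    DEFAULT_REGISTRY,
    Composition,
    ResidueClass,
    SidechainRegistry,
    XGOStructure,
    composition_of,
)
from .mass import NOMINAL, MassConvention

__all__ = [
    "EndoRule",
    "XEG",
    "XCXGHA",
    "ENDO_RULES",
    "ExoRule",
    "make_exo_rule",
    "FUCOSIDASE",
    "GALACTOSIDASE",
    "EXO_RULES",
    "DigestResult",
    "digest_endo",
    "exo_trim",
    "driselase_digest",
    "predict_shift_pairs",
    "saponify",
]


@dataclass(frozen=True)
class EndoRule:
    """Backbone cleavage specificity of an endo-glucanase.

    ``cleave_between(a, b)`` decides whether the glycosidic bond between
    consecutive backbone units with sidechain codes ``a`` (toward the
    non-reducing end) and ``b`` is hydrolysed.  ``min_product_len`` is a
    crude subsite-occupancy stand-in: cuts producing a shorter fragment
    are skipped (default 1, i.e. every eligible bond is cut).
    """

    name: str
    cleave_between: Callable[[str, str], bool]
    min_product_len: int = 1

    def with_min_product_len(self, n: int) -> "EndoRule":
        return replace(self, min_product_len=n)


XEG = EndoRule("XEG", lambda a, b: a == "G")
XCXGHA = EndoRule("XcXGHA", lambda a, b: a != "G" and b != "G")

ENDO_RULES: dict[str, EndoRule] = {"xeg": XEG, "xcxgha": XCXGHA}


@dataclass(frozen=True)
class ExoRule:
    """Terminal-residue removal by an exo-glycosidase.

    ``trim_map`` sends each susceptible sidechain code to the code left
    after removing one terminal residue of class ``removes``.
    ``max_multiplicity`` caps how many removals one oligosaccharide can
    undergo (fucosidase 1; galactosidase 2, e.g. both galactoses of XLLG).
    """

    name: str
    removes: ResidueClass
    trim_map: dict[str, str] = field(default_factory=dict)
    max_multiplicity: int = 1

    @property
    def applicable(self) -> frozenset[str]:
        return frozenset(self.trim_map)


def make_exo_rule(
    name: str,
    removes: ResidueClass,
    registry: SidechainRegistry = DEFAULT_REGISTRY,
    max_multiplicity: int = 1,
) -> ExoRule:
    """Derive an exo rule from the registry's terminal/trim annotations."""
    trim_map = {
        d.code: d.trim_target
        for d in registry.values()
        if d.terminal_class == removes and d.trim_target is not None
    }
    return ExoRule(name, removes, trim_map, max_multiplicity)


FUCOSIDASE = make_exo_rule("fucosidase", ResidueClass.DHEX, max_multiplicity=1)
GALACTOSIDASE = make_exo_rule("galactosidase", ResidueClass.HEX, max_multiplicity=2)

EXO_RULES: dict[str, ExoRule] = {
    "fucosidase": FUCOSIDASE,
    "galactosidase": GALACTOSIDASE,
}


@dataclass
class DigestResult:
    """Outcome of a digestion.

    ``products`` holds oligosaccharide fragments (endo digests);
    ``released`` counts free monosaccharides by class and ``isoprimeverose``
    the diagnostic disaccharides (Driselase).  ``cuts`` is the number of
    hydrolysed backbone bonds; each cut consumes one water, so for endo
    digests Σ product neutral masses = substrate mass + cuts × water.
    """

    products: list[XGOStructure] = field(default_factory=list)
    cuts: int = 0
    released: Counter = field(default_factory=Counter)
    isoprimeverose: int = 0


def digest_endo(s: XGOStructure, rule: EndoRule) -> DigestResult:
    """Split the backbone at every bond the rule's predicate accepts.

    Bonds are considered left (non-reducing end) to right; a cut is
    skipped when either resulting fragment would fall below the rule's
    minimum product length.  Acetyl groups, whose position is not
    mass-resolvable, travel with the reducing-end product.
    """
    codes = s.codes
    segments: list[list[str]] = []
    current: list[str] = []
    for i, code in enumerate(codes):
        current.append(code)
        last = i == len(codes) - 1
        if last:
            break
        if not rule.cleave_between(code, codes[i + 1]):
            continue
        if len(current) < rule.min_product_len:
            continue
        if len(codes) - (i + 1) < rule.min_product_len:
            continue
        segments.append(current)
        current = []
    segments.append(current)
    products = [XGOStructure(tuple(seg)) for seg in segments]
    if s.acetyl_count:
        products[-1] = XGOStructure(products[-1].codes, s.acetyl_count)
    return DigestResult(products=products, cuts=len(segments) - 1)


def exo_trim(
    s: XGOStructure,
    rule: ExoRule,
    exhaustive: bool = True,
    registry: SidechainRegistry = DEFAULT_REGISTRY,
) -> XGOStructure:
    """Remove terminal residues per the exo rule.

    Exhaustive mode trims every susceptible sidechain to its fixed point
    (idempotent); single-step mode trims only the first susceptible
    sidechain from the non-reducing end.  Structures with no susceptible
    sidechain are returned unchanged; acetyl count is untouched.
    """
    del registry  # trim targets are pre-resolved on the rule
    codes = list(s.codes)
    if exhaustive:
        changed = True
        while changed:
            changed = False
            for i, code in enumerate(codes):
                if code in rule.trim_map:
                    codes[i] = rule.trim_map[code]
                    changed = True
    else:
        for i, code in enumerate(codes):
            if code in rule.trim_map:
                codes[i] = rule.trim_map[code]
                break
    return XGOStructure(tuple(codes), s.acetyl_count)


def driselase_digest(
    s: XGOStructure, registry: SidechainRegistry = DEFAULT_REGISTRY
) -> DigestResult:
    """Degrade to monosaccharides plus one isoprimeverose per substituted unit.

    Each substituted backbone glucose keeps its α-1,6 xylose as an intact
    isoprimeverose disaccharide; every further sidechain residue is
    released as a free monosaccharide of its class, and unsubstituted
    glucoses come off as free Hex.  Residue bookkeeping is exact:
    isoprimeverose × (1 Hex + 1 Pent) + free residues = the substrate's
    composition.
    """
    released: Counter = Counter()
    n_ip = 0
    for code in s.codes:
        sidechain = registry[code].residues
        if sidechain.total() == 0:
            released[ResidueClass.HEX] += 1
            continue
        n_ip += 1
        extra = sidechain - Composition(Pent=1)
        for cls, n in extra.nonzero().items():
            released[cls] += n
    if s.acetyl_count:
        released[ResidueClass.AC] += s.acetyl_count
    # every glycosidic bond is hydrolysed except the one inside each isoprimeverose
    n_bonds = composition_of(s, registry).n_residues() - 1
    return DigestResult(cuts=n_bonds - n_ip, released=released, isoprimeverose=n_ip)


def predict_shift_pairs(
    peaks: Sequence[float],
    rule: ExoRule,
    conv: MassConvention = NOMINAL,
    max_removals: int = 1,
) -> list[tuple[float, float]]:
    """Predicted (precursor, product) m/z pairs under an exo treatment.

    Each product is precursor − k × residue mass for k = 1..``max_removals``
    (capped by the rule's multiplicity); intermediates are reported for
    k > 1.  The nominal convention reproduces the integer shift arithmetic
    used when reading MALDI spectra by eye.
    """
    step = conv.residue_masses[rule.removes]
    kmax = min(max_removals, rule.max_multiplicity)
    pairs: list[tuple[float, float]] = []
    for p in peaks:
        for k in range(1, kmax + 1):
            pairs.append((p, p - k * step))
    return pairs


def saponify(s: XGOStructure) -> XGOStructure:
    """Alkaline de-esterification: strip all O-acetyl groups."""
    if not s.acetyl_count:
        return s
    return XGOStructure(s.codes, 0)
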
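"""Seeded synthetic spectra and digestion experiments.

The generator emulates the statistical structure the annotation pipeline
assumes of a real XGO MALDI acquisition:

* one sodiated (or otherwise cationized) peak per oligosaccharide and
  adduct, at the theoretical m/z plus Gaussian jitter in Da (reflectron
  mass error at this range is approximately mass-independent at the
  integer-reporting scale);
* lognormal multiplicative intensity noise around each structure's
  relative abundance;
* a contaminating hexose-oligomer ladder (Hex_n adduct peaks), as seen in
  untreated algal extracts;
* uniform-random decoy peaks across the acquisition window — deliberately
  adversarial for the composition enumerator, to exercise false-discovery
  behaviour.

Everything is driven by one integer seed through a
:class:`numpy.random.Generator`, so a configuration reproduces its
spectrum exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .glycan import (
    DEFAULT_REGISTRY,
    Composition,
    SidechainRegistry,
    XGOStructure,
    composition_of,
    parse_structure,
)
from .mass import (
    ACQUISITION_RANGE,
    Adduct,
    MONOISOTOPIC,
    MassConvention,
    SODIUM,
    adduct_mz,
)
from .enzymes import ENDO_RULES, EXO_RULES, digest_endo, exo_trim
from .spectra import Spectrum

__all__ = [
    "SimulationConfig",
    "ExperimentTruth",
    "simulate_spectrum",
    "simulate_digestion_experiment",
]

StructureLike = Union[str, XGOStructure]


def _as_structure(s: StructureLike, registry: SidechainRegistry) -> XGOStructure:
    return parse_structure(s, registry) if isinstance(s, str) else s


@dataclass
class SimulationConfig:
    """Everything needed to synthesize one spectrum.

    ``structures`` maps oligosaccharides (codes or parsed structures) to
    relative abundances; ``adducts`` distributes each structure's signal
    over cation forms by fraction (fractions must sum to ≤ 1).
    ``contaminant_hexose_range`` adds a Hex_n ladder at the given
    per-peak abundance; ``decoy_peak_count`` uniform-random peaks are
    sprinkled over the acquisition window.  ``seed`` fixes all randomness.
    """

    structures: Sequence[tuple[StructureLike, float]] = ()
    adducts: Sequence[tuple[Adduct, float]] = ((SODIUM, 1.0),)
    convention: MassConvention = MONOISOTOPIC
    mz_jitter_sd: float = 0.0
    intensity_noise_cv: float = 0.0
    contaminant_hexose_range: Optional[tuple[int, int]] = None
    contaminant_abundance: float = 0.3
    decoy_peak_count: int = 0
    decoy_abundance: float = 0.3
    seed: int = 0
    registry: SidechainRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)
    sample: str = "synthetic"

    def __post_init__(self) -> None:
        for _s, a in self.structures:
            if a <= 0:
                raise ValueError("structure abundances must be positive")
        total = sum(f for _a, f in self.adducts)
        if total > 1 + 1e-9:
            raise ValueError(f"adduct fractions sum to {total} > 1")

    def parsed_structures(self) -> list[tuple[XGOStructure, float]]:
        return [(_as_structure(s, self.registry), a) for s, a in self.structures]


def _noisy_intensity(rng: np.random.Generator, base: float, cv: float) -> float:
    if cv <= 0:
        return base
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return base * float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


def simulate_spectrum(
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    treatment: Sequence[str] = (),
) -> Spectrum:
    """Generate one spectrum from a configuration.

    Peak order of random draws is fixed (structures, then contaminants,
    then decoys), so a given seed always yields the identical spectrum.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    pairs: list[tuple[float, float]] = []
    for struct, abundance in cfg.parsed_structures():
        comp = composition_of(struct, cfg.registry)
        for adduct, fraction in cfg.adducts:
            if fraction <= 0:
                continue
            mz = adduct_mz(comp, cfg.convention, adduct, rounding="none")
            if cfg.mz_jitter_sd > 0:
                mz += float(rng.normal(0.0, cfg.mz_jitter_sd))
            pairs.append((mz, _noisy_intensity(rng, abundance * fraction, cfg.intensity_noise_cv)))
    if cfg.contaminant_hexose_range is not None:
        lo, hi = cfg.contaminant_hexose_range
        adduct = cfg.adducts[0][0] if cfg.adducts else SODIUM
        for n in range(lo, hi + 1):
            mz = adduct_mz(Composition(Hex=n), cfg.convention, adduct, rounding="none")
            if cfg.mz_jitter_sd > 0:
                mz += float(rng.normal(0.0, cfg.mz_jitter_sd))
            pairs.append(
                (mz, _noisy_intensity(rng, cfg.contaminant_abundance, cfg.intensity_noise_cv))
            )
    for _ in range(cfg.decoy_peak_count):
        mz = float(rng.uniform(*ACQUISITION_RANGE))
        pairs.append((mz, _noisy_intensity(rng, cfg.decoy_abundance, cfg.intensity_noise_cv)))
    return Spectrum.from_pairs(pairs, sample=cfg.sample, treatment=treatment)


@dataclass
class ExperimentTruth:
    """Ground truth of a simulated digestion experiment.

    ``pairs`` lists (precursor m/z, product m/z, residues removed) for
    every exo conversion; ``pre_assignments`` / ``post_assignments`` map
    theoretical peak m/z to the generating structure code.
    """

    pairs: list[tuple[float, float, Composition]] = field(default_factory=list)
    pre_assignments: dict[float, str] = field(default_factory=dict)
    post_assignments: dict[float, str] = field(default_factory=dict)


def _pool_mz(
    pool: Sequence[tuple[XGOStructure, float]], cfg: SimulationConfig
) -> dict[float, str]:
    out: dict[float, str] = {}
    adduct = cfg.adducts[0][0] if cfg.adducts else SODIUM
    for struct, _a in pool:
        mz = adduct_mz(composition_of(struct, cfg.registry), cfg.convention, adduct, "none")
        out[mz] = struct.render()
    return out


def simulate_digestion_experiment(
    cfg: SimulationConfig,
    enzymes: Sequence[str],
    completeness: Union[float, Sequence[float]] = 1.0,
) -> tuple[Spectrum, Spectrum, ExperimentTruth]:
    """Simulate a pre/post enzyme-treatment pair of spectra.

    Each enzyme (by registry name: ``"fucosidase"``, ``"galactosidase"``,
    ``"xeg"``, ``"xcxgha"``) transforms the structure pool in order,
    moving ``completeness`` of every susceptible structure's abundance to
    its product(s); completeness < 1 leaves the precursor co-present with
    its product, the signature of partial digestion.  Unknown enzyme
    names are rejected.  Both spectra derive from the same seed and are
    deterministic.
    """
    if isinstance(completeness, (int, float)):
        fractions = [float(completeness)] * len(enzymes)
    else:
        fractions = [float(f) for f in completeness]
        if len(fractions) != len(enzymes):
            raise ValueError("one completeness value per enzyme required")
    for f in fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"completeness must be in [0, 1], got {f}")

    pool: list[tuple[XGOStructure, float]] = cfg.parsed_structures()
    truth = ExperimentTruth(pre_assignments=_pool_mz(pool, cfg))
    adduct = cfg.adducts[0][0] if cfg.adducts else SODIUM

    def mz_of(struct: XGOStructure) -> float:
        return adduct_mz(composition_of(struct, cfg.registry), cfg.convention, adduct, "none")

    for enzyme, frac in zip(enzymes, fractions):
        name = enzyme.lower()
        new_pool: dict[XGOStructure, float] = {}

        def credit(struct: XGOStructure, amount: float) -> None:
            if amount > 0:
                new_pool[struct] = new_pool.get(struct, 0.0) + amount

        for struct, abundance in pool:
            if name in EXO_RULES:
                product = exo_trim(struct, EXO_RULES[name], exhaustive=True)
                products = [product] if product != struct else []
            elif name in ENDO_RULES:
                result = digest_endo(struct, ENDO_RULES[name])
                products = result.products if result.cuts else []
            elif name == "driselase":
                raise ValueError(
                    "driselase releases mono/disaccharides below the acquisition "
                    "range; use driselase_digest directly"
                )
            else:
                raise ValueError(f"unknown enzyme {enzyme!r}")
            if not products:
                credit(struct, abundance)
                continue
            credit(struct, abundance * (1.0 - frac))
            for product in products:
                credit(product, abundance * frac)
                removed_comp = composition_of(struct, cfg.registry) - composition_of(
                    product, cfg.registry
                ) if len(products) == 1 else None
                truth.pairs.append(
                    (
                        mz_of(struct),
                        mz_of(product),
                        removed_comp if removed_comp is not None else Composition(),
                    )
                )
        pool = list(new_pool.items())

    truth.post_assignments = _pool_mz(pool, cfg)

    seeds = np.random.SeedSequence(cfg.seed).spawn(2)
    pre = simulate_spectrum(cfg, rng=np.random.default_rng(seeds[0]))
    post_cfg = replace(cfg, structures=tuple((s.render(), a) for s, a in pool))
    post = simulate_spectrum(
        post_cfg, rng=np.random.default_rng(seeds[1]), treatment=tuple(enzymes)
    )
    return pre, post, truth
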
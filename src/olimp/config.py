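"""Plain-text serialization of the sidechain registry and run settings.

Two formats are supported:

* a TSV *registry table* (one sidechain per row) so the grammar alphabet
  can be extended without touching code — e.g. to add the Q sidechain
  once its residue content is settled;
* a YAML *run configuration* carrying mass tables, adduct set, tolerance,
  enumeration bounds and ranking knobs for :func:`olimp.spectra.annotate`.

The shipped ``data/sidechains.tsv`` is the default registry rendered
through the same writer, so round-tripping is tested rather than assumed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .glycan import (
    Composition,
    GrammarError,
    ResidueClass,
    SidechainDef,
    SidechainRegistry,
)
from .mass import (
    ADDUCTS,
    CONVENTIONS,
    DEFAULT_BOUNDS,
    Adduct,
    MassConvention,
)
from .spectra import AnnotationConfig

__all__ = [
    "write_registry_table",
    "read_registry_table",
    "default_registry_path",
    "load_annotation_config",
    "dump_annotation_config",
]

_COLUMNS = ("code", "Hex", "Pent", "dHex", "HexA", "terminal_class", "trim_target", "ms_terminals")


def _format_ms_terminals(d: SidechainDef) -> str:
    return ";".join(f"{cls.value}>{target}" for cls, target in d.ms_terminals)


def _parse_ms_terminals(text: str) -> tuple[tuple[ResidueClass, str], ...]:
    text = text.strip()
    if not text or text == "-":
        return ()
    out = []
    for item in text.split(";"):
        cls_name, _, target = item.partition(">")
        out.append((ResidueClass(cls_name.strip()), target.strip()))
    return tuple(out)


def write_registry_table(registry: SidechainRegistry, path: Union[str, Path]) -> None:
    """Write the registry as a TSV table (one sidechain per row)."""
    lines = ["\t".join(_COLUMNS)]
    for d in registry.values():
        lines.append(
            "\t".join(
                [
                    d.code,
                    str(d.residues[ResidueClass.HEX]),
                    str(d.residues[ResidueClass.PENT]),
                    str(d.residues[ResidueClass.DHEX]),
                    str(d.residues[ResidueClass.HEXA]),
                    d.terminal_class.value if d.terminal_class else "-",
                    d.trim_target or "-",
                    _format_ms_terminals(d) or "-",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_registry_table(path: Union[str, Path]) -> SidechainRegistry:
    """Read a TSV registry table written by :func:`write_registry_table`."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise GrammarError(f"{path}: empty registry table")
    header = lines[0].split("\t")
    if tuple(header) != _COLUMNS:
        raise GrammarError(f"{path}: expected header {_COLUMNS}, got {tuple(header)}")
    defs = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(_COLUMNS):
            raise GrammarError(f"{path}: malformed row {ln!r}")
        code, n_hex, n_pent, n_dhex, n_hexa, terminal, trim, ms = fields
        residues = Composition(
            Hex=int(n_hex), Pent=int(n_pent), dHex=int(n_dhex), HexA=int(n_hexa)
        )
        defs.append(
            SidechainDef(
                code=code,
                residues=residues,
                terminal_class=None if terminal == "-" else ResidueClass(terminal),
                trim_target=None if trim == "-" else trim,
                ms_terminals=_parse_ms_terminals(ms),
            )
        )
    return SidechainRegistry(defs)


def default_registry_path() -> Path:
    """Path of the shipped default registry table."""
    return Path(str(resources.files("olimp").joinpath("data/sidechains.tsv")))


def load_annotation_config(path: Union[str, Path]) -> AnnotationConfig:
    """Build an :class:`AnnotationConfig` from a YAML file.

    Recognised keys (all optional): ``conventions`` (names or full tables
    with ``residue_masses``/``water``), ``adducts`` (labels or
    label→delta mappings), ``tolerance``, ``bounds`` (class→max count),
    ``backbone_range``, ``reducing_end_G``, ``registry`` (path to a TSV
    table), ``min_ratio``, ``partial_ratio``, ``rank_error_quantum``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}

    if "conventions" in raw:
        convs = []
        for item in raw["conventions"]:
            if isinstance(item, str):
                convs.append(CONVENTIONS[item])
            else:
                convs.append(
                    MassConvention(
                        name=item["name"],
                        residue_masses={
                            ResidueClass(k): float(v)
                            for k, v in item["residue_masses"].items()
                        },
                        water=float(item["water"]),
                        rounding=item.get("rounding", "none"),
                    )
                )
        kwargs["conventions"] = tuple(convs)

    if "adducts" in raw:
        adducts = []
        for item in raw["adducts"]:
            if isinstance(item, str):
                adducts.append(ADDUCTS[item])
            else:
                (label, delta), = item.items()
                adducts.append(Adduct(label, float(delta)))
        kwargs["adducts"] = tuple(adducts)

    if "bounds" in raw:
        bounds = dict(DEFAULT_BOUNDS)
        bounds.update({ResidueClass(k): int(v) for k, v in raw["bounds"].items()})
        kwargs["bounds"] = bounds

    if "registry" in raw:
        reg_path = Path(raw["registry"])
        if not reg_path.is_absolute():
            reg_path = Path(path).parent / reg_path
        kwargs["registry"] = read_registry_table(reg_path)

    for key in ("tolerance", "min_ratio", "partial_ratio", "rank_error_quantum"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "backbone_range" in raw:
        lo, hi = raw["backbone_range"]
        kwargs["backbone_range"] = (int(lo), int(hi))
    if "reducing_end_G" in raw:
        kwargs["reducing_end_G"] = bool(raw["reducing_end_G"])

    return AnnotationConfig(**kwargs)


def dump_annotation_config(config: AnnotationConfig, path: Union[str, Path]) -> None:
    """Serialize a configuration (mass tables inline) to YAML."""
    payload = {
        "conventions": [
            {
                "name": c.name,
                "residue_masses": {cls.value: m for cls, m in c.residue_masses.items()},
                "water": c.water,
                "rounding": c.rounding,
            }
            for c in config.conventions
        ],
        "adducts": [{a.label: a.delta} for a in config.adducts],
        "tolerance": config.tolerance,
        "bounds": {cls.value: n for cls, n in config.bounds.items()},
        "backbone_range": list(config.backbone_range),
        "reducing_end_G": config.reducing_end_G,
        "min_ratio": config.min_ratio,
        "partial_ratio": config.partial_ratio,
        "rank_error_quantum": config.rank_error_quantum,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
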
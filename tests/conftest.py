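import pytest

from olimp.glycan import DEFAULT_REGISTRY, XGOStructure, parse_structure


@pytest.fixture(scope="session")
def registry():
    return DEFAULT_REGISTRY


@pytest.fixture
def xxfg() -> XGOStructure:
    return parse_structure("XXFG")


#: a Mesotaenium-like oligosaccharide pool covering fucosylated,
#: galactosylated and uronic-acid-bearing XGOs
MESO_PANEL = [
    "XXXG", "XXG", "XLG", "XFG", "XXFG", "XLFG",
    "XXLG", "XLLG", "XPG", "XXPG", "LLG", "XYG",
]


@pytest.fixture(scope="session")
def meso_panel():
    return list(MESO_PANEL)
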
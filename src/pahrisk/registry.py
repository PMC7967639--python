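"""Registry of the 16 USEPA priority PAH congeners.

Each congener carries its ring count, the derived molecular-weight class
(LMW = 2-3 rings, HMW = 4-6 rings) and a flag marking the seven congeners
conventionally treated as probable human carcinogens.  Toxicity equivalency
factors (TEFs, Nisbet & LaGoy scheme, relative to benzo(a)pyrene) live here
as well because they are a fixed per-congener property of the risk model.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType


@dataclass(frozen=True)
class Congener:
    """One priority PAH congener.

    Attributes
    ----------
    abbrev : str
        Conventional three-letter abbreviation (e.g. ``"BaP"``).
    name : str
        Full chemical name.
    ring_count : int
        Number of fused aromatic rings (2-6).
    carcinogen : bool
        True for the seven probable-carcinogen congeners
        {BaA, CYR, BbF, BkF, BaP, IcP, DbA}.
    """

    abbrev: str
    name: str
    ring_count: int
    carcinogen: bool

    @property
    def weight_class(self) -> str:
        """``"LMW"`` for 2-3 rings, ``"HMW"`` for 4-6 rings."""
        return "LMW" if self.ring_count <= 3 else "HMW"


_CARCINOGENS = frozenset({"BaA", "CYR", "BbF", "BkF", "BaP", "IcP", "DbA"})

_REGISTRY_SPEC = [
    # abbrev, full name, rings
    ("NAP", "naphthalene", 2),
    ("ACY", "acenaphthylene", 3),
    ("ACP", "acenaphthene", 3),
    ("FLU", "fluorene", 3),
    ("PHE", "phenanthrene", 3),
    ("ANT", "anthracene", 3),
    ("FLA", "fluoranthene", 4),
    ("PYR", "pyrene", 4),
    ("BaA", "benzo(a)anthracene", 4),
    ("CYR", "chrysene", 4),
    ("BbF", "benzo(b)fluoranthene", 5),
    ("BkF", "benzo(k)fluoranthene", 5),
    ("BaP", "benzo(a)pyrene", 5),
    ("IcP", "indeno(1,2,3-cd)pyrene", 6),
    ("DbA", "dibenzo(a,h)anthracene", 5),
    ("BgP", "benzo(ghi)perylene", 6),
]

REGISTRY: MappingProxyType[str, Congener] = MappingProxyType(
    {
        abbrev: Congener(abbrev, name, rings, abbrev in _CARCINOGENS)
        for abbrev, name, rings in _REGISTRY_SPEC
    }
)

#: Canonical congener ordering used by every tabular interface.
CONGENERS: tuple[str, ...] = tuple(c for c, _, _ in _REGISTRY_SPEC)

LMW_CONGENERS: tuple[str, ...] = tuple(
    c for c in CONGENERS if REGISTRY[c].weight_class == "LMW"
)
HMW_CONGENERS: tuple[str, ...] = tuple(
    c for c in CONGENERS if REGISTRY[c].weight_class == "HMW"
)
CARCINOGENIC_CONGENERS: tuple[str, ...] = tuple(
    c for c in CONGENERS if REGISTRY[c].carcinogen
)

# Nisbet-LaGoy toxicity equivalency factors relative to BaP.  FLA is not
# singled out by the grouped published form of the TEQ sum; its standard
# Nisbet-LaGoy value of 0.001 is used and may be overridden per run.
DEFAULT_TEFS: MappingProxyType[str, float] = MappingProxyType(
    {
        "NAP": 0.001, "ACP": 0.001, "ACY": 0.001, "FLU": 0.001,
        "PHE": 0.001, "PYR": 0.001, "FLA": 0.001,
        "ANT": 0.01, "BgP": 0.01, "CYR": 0.01,
        "BaA": 0.1, "BbF": 0.1, "BkF": 0.1, "IcP": 0.1,
        "BaP": 1.0, "DbA": 1.0,
    }
)

assert len(REGISTRY) == 16
assert set(DEFAULT_TEFS) == set(CONGENERS)
assert len(LMW_CONGENERS) == 6 and len(HMW_CONGENERS) == 10
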
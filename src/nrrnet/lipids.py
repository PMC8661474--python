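"""Parsing of shorthand lipid names into class annotations.

Plasma lipidomics platforms report lipids at the sum-composition level
("PC (O-34:3)": a phosphatidylcholine with 34 acyl/alkyl carbons, 3 double
bonds and an O-alkyl ether bond) or at the molecular-species level
("TG (16:0/18:0/18:1)": a triacylglycerol with three specified chains).
This module turns those strings into a structured :class:`LipidAnnotation`.

Parsing is *total*: an unrecognizable name never raises, it yields an
annotation with ``lipid_class='unknown'`` and the raw string preserved, so
a feature catalog can always be built from whatever the upstream platform
emitted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Lipid classes the catalog distinguishes. ``unknown`` is a valid class for
#: features that were quantified but not structurally identified.
LIPID_CLASSES = ("TG", "PC", "LPC", "PE", "LPE", "PI", "Cer", "SM", "ChoE", "unknown")

#: Glycerophospholipid classes for which an ether (O-/P-) prefix is chemically
#: meaningful (alkyl or alkenyl bond at sn-1).
GLYCEROPHOSPHOLIPID_CLASSES = frozenset({"PC", "PE", "LPC", "LPE", "PI"})

_NAME_RE = re.compile(
    r"""^\s*(?P<cls>[A-Za-z]+)\s*\(\s*(?P<ether>[OP]-)?\s*(?P<chains>[A-Za-z]?\d+:\d+(?:\s*/\s*[A-Za-z]?\d+:\d+)*)\s*\)\s*$""",
)

_CHAIN_RE = re.compile(r"^([A-Za-z]?)(\d+):(\d+)$")


@dataclass(frozen=True)
class LipidAnnotation:
    """Structured description of one lipid feature.

    ``total_carbons``/``total_double_bonds`` are the sum composition; when
    the molecular species is fully specified, ``chains`` lists the
    individual (carbons, double_bonds) fatty-acyl chains and the totals are
    their sums. ``ether_flag`` is ``'O'`` (alkyl), ``'P'`` (alkenyl /
    plasmalogen) or ``'none'``.
    """

    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    ether_flag: str = "none"
    chains: tuple[tuple[int, int], ...] | None = None
    raw_name: str = ""

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.ether_flag not in ("none", "O", "P"):
            raise ValueError(f"invalid ether flag {self.ether_flag!r}")
        if self.chains is not None:
            if sum(c for c, _ in self.chains) != self.total_carbons:
                raise ValueError("chain carbons do not sum to total_carbons")
            if sum(d for _, d in self.chains) != self.total_double_bonds:
                raise ValueError("chain double bonds do not sum to total_double_bonds")
        if self.ether_flag != "none" and self.lipid_class not in GLYCEROPHOSPHOLIPID_CLASSES:
            raise ValueError(
                f"ether flag only valid for glycerophospholipids, not {self.lipid_class!r}"
            )


def _unknown(name: str) -> LipidAnnotation:
    return LipidAnnotation("unknown", 0, 0, "none", None, name)


def parse_lipid_name(name: str) -> LipidAnnotation:
    """Parse a shorthand lipid name; never raises.

    Handles sum compositions (``"PC (O-34:3)"``), molecular species
    (``"TG (16:0/18:0/18:1)"``), sphingoid-base prefixes
    (``"Cer (d18:1/23:0)"``) and dual-identity names
    (``"PE (O-38:5) or PE (P-38:4)"`` — parsed from the first alternative,
    full string kept in ``raw_name``). Whitespace is insignificant.
    Anything else comes back with ``lipid_class='unknown'``.
    """
    if not isinstance(name, str) or not name.strip():
        return _unknown(name if isinstance(name, str) else "")
    candidate = name.split(" or ")[0] if " or " in name else name
    m = _NAME_RE.match(candidate)
    if m is None:
        return _unknown(name)
    cls = m.group("cls")
    if cls not in LIPID_CLASSES or cls == "unknown":
        return _unknown(name)
    ether = m.group("ether")[0] if m.group("ether") else "none"
    if ether != "none" and cls not in GLYCEROPHOSPHOLIPID_CLASSES:
        return _unknown(name)
    chain_tokens = [t.strip() for t in m.group("chains").split("/")]
    parsed = []
    for tok in chain_tokens:
        cm = _CHAIN_RE.match(tok)
        if cm is None:  # pragma: no cover - regex already constrains tokens
            return _unknown(name)
        parsed.append((int(cm.group(2)), int(cm.group(3))))
    if len(parsed) == 1:
        total_c, total_d = parsed[0]
        chains: tuple[tuple[int, int], ...] | None = None
    else:
        total_c = sum(c for c, _ in parsed)
        total_d = sum(d for _, d in parsed)
        chains = tuple(parsed)
    return LipidAnnotation(cls, total_c, total_d, ether, chains, name)
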
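"""Gene/protein set containers, GMT I/O, and the bundled signature sets.

Two signatures ship with the package:

* a 20-protein stromal signature (extracellular-matrix and complement
  proteins shared between stroma-rich tumor samples and the ESTIMATE
  stromal signature), used to score the stromal content of a sample;
* a dsDNA-sensing/inflammation (DSI) set of interferon-response,
  cGAS-STING and antigen-presentation proteins.  The full co-expression
  module this score represents contains 52 proteins; only the members
  named in public sources are bundled, so the shipped set is explicitly
  partial.  Two symbols ("PSM8", "PSM9") are kept verbatim as printed at
  the source; ``DSI_ALIASES`` maps them to the conventional HGNC symbols
  PSMB8/PSMB9.  Aliases are never applied silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene/protein identifiers."""

    name: str
    members: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    @classmethod
    def from_iterable(cls, name: str, members: Iterable[str], source: str = "") -> "GeneSet":
        members = list(members)
        if len(members) != len(set(members)):
            raise ValueError(f"gene set {name!r} has duplicate members")
        return cls(name=name, members=frozenset(members), source=source)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


STROMAL_PROTEINS: tuple[str, ...] = (
    "ASPN", "MXRA5", "COL14A1", "COL1A2", "COL6A3", "VSIG4", "COL15A1",
    "COMP", "F13A1", "CILP", "PTGIS", "ITIH3", "LUM", "DCN", "COL3A1",
    "THBS2", "FBLN2", "BGN", "C1QB", "OLFML1",
)

# Interferon / cGAS-STING / MHC members named publicly, plus the DSI members
# recurring in the HR-deficiency differential-abundance overlap.  Partial:
# the underlying co-expression module holds 52 proteins.
DSI_PROTEINS: tuple[str, ...] = (
    "BST2", "CASP1", "CMPK2", "IFI35", "IFIT3", "ISG15", "MX1",
    "PSM8", "PSM9", "TAP1",
    "DDX58", "IL18", "IFI16",
    "HLA-F", "TAPBP", "HLA-DQB1", "HLA-DRB3",
    "CNTRL", "DAPL1", "MUC1", "PFKP",
)

#: Printed symbol -> conventional HGNC symbol.  Applied only on request.
DSI_ALIASES: dict[str, str] = {"PSM8": "PSMB8", "PSM9": "PSMB9"}


def stromal_score_proteins() -> GeneSet:
    """Return the bundled 20-protein stromal signature."""
    return GeneSet.from_iterable("stromal_signature", STROMAL_PROTEINS, source="bundled")


def dsi_proteins(apply_aliases: bool = False) -> GeneSet:
    """Return the bundled (partial) dsDNA-sensing/inflammation set.

    Parameters
    ----------
    apply_aliases
        If True, replace printed non-HGNC symbols by their conventional
        aliases (PSM8 -> PSMB8, PSM9 -> PSMB9).
    """
    members = [DSI_ALIASES.get(m, m) if apply_aliases else m for m in DSI_PROTEINS]
    return GeneSet.from_iterable("dsi", members, source="bundled-partial")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name <tab> description <tab> members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT record needs >=3 tab-separated fields")
            name, source, members = parts[0], parts[1], [m for m in parts[2:] if m]
            # tolerate accidental duplicates in external files, preserve order
            seen: dict[str, None] = dict.fromkeys(members)
            sets.append(GeneSet.from_iterable(name, seen, source=source))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.source}\t{members}\n")
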
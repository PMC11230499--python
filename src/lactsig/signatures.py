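"""Named gene signatures and the signature registry.

The package ships the marker, proliferation and regulon gene lists used to
dissect the mammary epithelium and to call the PPBC-like subpopulation:

* three epithelial marker lists — luminal alveolar (AV), luminal
  hormone-sensing (HS) and myoepithelial (ME) cells;
* a six-gene proliferation (cell-cycle) list;
* a fourteen-transcription-factor regulon associated with post-partum
  breast cancer (PPBC).

Lists are shipped verbatim, including ``Bud1`` in the proliferation list
(possibly intended as ``Bub1``); symbol misses against a matrix are
reported by the scoring layer, never silently dropped or auto-corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError

__all__ = [
    "GeneSignature",
    "normalize_mouse_symbol",
    "PROLIFERATION_GENES",
    "REGULON_GENES",
    "MARKER_GENES",
    "default_registry",
    "load_registry",
    "save_registry",
]

#: Proliferating-cell feature list (combined feature sum), 6 genes.
PROLIFERATION_GENES = ("Cenpe", "Ccna2", "Ccnb2", "Mcm6", "Ccnf", "Bud1")

#: PPBC transcription-factor regulon, 14 genes.
REGULON_GENES = (
    "Bclaf1", "Cux1", "E2f1", "E2f4", "Esr1", "Foxm1", "Gtf2b",
    "Max", "Myc", "Nfya", "Nr4a1", "Nrf1", "Smarca4", "Taf1",
)

#: Epithelial cell-type marker lists.
MARKER_GENES: Mapping[str, tuple[str, ...]] = {
    "AV": ("Mfge8", "Trf", "Csn3", "Wfdc18", "Ltf"),
    "HS": ("Prlr", "Pgr", "Esr1", "Cited1", "Prom1"),
    "ME": ("Krt17", "Krt14", "Krt5"),
}


def normalize_mouse_symbol(symbol: str) -> str:
    """Normalize a gene symbol to the mouse convention.

    Mouse symbols capitalize the first letter and lower-case the rest
    (``E2F1`` -> ``E2f1``). Matching downstream is case-sensitive after
    this normalization.
    """
    s = symbol.strip()
    if not s:
        raise FormatError("empty gene symbol")
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class GeneSignature:
    """A named, ordered list of unique gene symbols."""

    name: str
    genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("signature name must be non-empty")
        genes = tuple(self.genes)
        if not genes:
            raise FormatError(f"signature {self.name!r} has no genes")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise FormatError(
                f"signature {self.name!r} has duplicate symbols: {dupes}"
            )
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSignature":
        """Build a signature, normalizing symbols to the mouse convention."""
        return cls(name, tuple(normalize_mouse_symbol(s) for s in symbols))


def default_registry() -> dict[str, GeneSignature]:
    """The packaged registry: marker, proliferation and regulon lists."""
    reg = {
        "proliferation": GeneSignature("proliferation", PROLIFERATION_GENES),
        "regulon": GeneSignature("regulon", REGULON_GENES),
    }
    for celltype, genes in MARKER_GENES.items():
        reg[celltype] = GeneSignature(celltype, genes)
    return reg


def load_registry(path: str | Path) -> dict[str, GeneSignature]:
    """Load a JSON registry mapping signature name -> list of symbols."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"registry {path}: expected a JSON object")
    reg: dict[str, GeneSignature] = {}
    for name, genes in raw.items():
        if not isinstance(genes, list):
            raise FormatError(f"registry {path}: entry {name!r} is not a list")
        reg[name] = GeneSignature.from_symbols(name, genes)
    return reg


def save_registry(registry: Mapping[str, GeneSignature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {name: list(sig.genes) for name, sig in registry.items()},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
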
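"""Gene panels.

The signature is measured on a fixed Taqman qPCR panel. Two panels ship as
package constants: the full 28-gene discovery panel (27 catalogue assays plus
the custom HNC20 assay) and the reduced 8-gene prediction panel obtained by
backward elimination. Prose spellings that differ from the assay symbol
(e.g. ``DERL-1``) are normalised through one documented alias table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import PanelError

#: Prose spelling -> assay gene symbol. Applied after whitespace trimming;
#: matching is otherwise exact and case-sensitive.
GENE_ALIASES: dict[str, str] = {
    "DERL-1": "DERL1",
}


def normalize_gene_symbol(symbol: str) -> str:
    """Trim whitespace and resolve known prose aliases to the assay symbol."""
    s = symbol.strip()
    return GENE_ALIASES.get(s, s)


@dataclass(frozen=True)
class GenePanel:
    """An ordered, duplicate-free list of gene symbols with optional assay ids.

    Assay identifiers are metadata only; no computation depends on them.
    """

    name: str
    genes: tuple[str, ...]
    assay_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise PanelError(f"panel {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if list(self.genes).count(g) > 1})
            raise PanelError(f"panel {self.name!r} has duplicate genes: {dupes}")
        unknown = set(self.assay_ids) - set(self.genes)
        if unknown:
            raise PanelError(
                f"panel {self.name!r}: assay ids for genes not in panel: {sorted(unknown)}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(self.genes)

    def subset(self, genes, name: str | None = None) -> "GenePanel":
        """Panel restricted to ``genes``, preserving this panel's gene order."""
        keep = set(genes)
        missing = keep - set(self.genes)
        if missing:
            raise PanelError(
                f"genes not in panel {self.name!r}: {sorted(missing)}"
            )
        sub = tuple(g for g in self.genes if g in keep)
        return GenePanel(
            name=name or f"{self.name}_subset",
            genes=sub,
            assay_ids={g: a for g, a in self.assay_ids.items() if g in keep},
        )

    def without(self, gene: str, name: str | None = None) -> "GenePanel":
        """Panel with one gene removed."""
        if gene not in self.genes:
            raise PanelError(f"gene {gene!r} not in panel {self.name!r}")
        return GenePanel(
            name=name or self.name,
            genes=tuple(g for g in self.genes if g != gene),
            assay_ids={g: a for g, a in self.assay_ids.items() if g != gene},
        )


# Full discovery panel: 27 Taqman catalogue assays plus the custom HNC20 assay.
_PANEL28_ASSAYS: tuple[tuple[str, str], ...] = (
    ("PEX19", "Hs00267867"),
    ("PSMD11", "Hs00160660"),
    ("SENP8", "Hs00744981"),
    ("PRKACA", "Hs00427274"),
    ("CTNS", "Hs00191849"),
    ("NFE2L1", "Hs00231457"),
    ("PPP2CA", "Hs00427259"),
    ("SENP7", "Hs00221046"),
    ("SYNCRIP", "Hs03044160"),
    ("CEP89", "Hs01071366"),
    ("SLC30A6", "Hs00215827"),
    ("LAMA3", "Hs00165042"),
    ("STX1A", "Hs00270282"),
    ("GPR22", "Hs01127309"),
    ("GRHL2", "Hs00227745"),
    ("DERL1", "Hs00225583"),
    ("FAM114A2", "Hs03837084"),
    ("PITPNA", "Hs00737576"),
    ("CDC14A", "Hs00185432"),
    ("SLC35A4", "Hs00365408"),
    ("KIAA1549", "Hs00860114"),
    ("LOC158402", "Hs00327489"),
    ("ZNF146", "Hs00173196"),
    ("C5orf3", "Hs00218834"),
    ("WEE1", "Hs01119384"),
    ("P2RX1", "Hs00175686"),
    ("MFSD6", "Hs00214462"),
    ("HNC20", "custom"),
)

PANEL28 = GenePanel(
    name="panel28",
    genes=tuple(g for g, _ in _PANEL28_ASSAYS),
    assay_ids=dict(_PANEL28_ASSAYS),
)

#: The 8 genes whose combined expression predicts response.
PANEL8_GENES = ("CTNS", "DERL1", "FAM114A2", "KIAA1549", "P2RX1", "PITPNA", "PSMD11", "WEE1")

PANEL8 = PANEL28.subset(PANEL8_GENES, name="panel8")

_BUILTINS = {"panel28": PANEL28, "panel8": PANEL8}


def builtin_panel(name: str) -> GenePanel:
    """Return a packaged panel by name (``panel28`` or ``panel8``)."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise PanelError(
            f"unknown panel {name!r}; valid names: {sorted(_BUILTINS)}"
        ) from None
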
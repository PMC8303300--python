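"""Built-in gene panels.

``EMT38`` is the 38-gene epithelial-to-mesenchymal-transition index panel:
the five core EMT transcription factors (TWIST1, SNAI1, SNAI2, ZEB1, ZEB2)
plus 33 EMT-related transcription factors from the TEMTIA consensus
nomenclature.

``HRR30`` is a 30-gene homologous-recombination-repair panel.  Only part of
the original panel is published by name (BRCA1/2, ATR, ATRX, FANCA/C/D2/G,
RAD50, RAD51B, RAD54L); the remainder here are canonical HRR pathway members
(RAD51 paralogs, Fanconi anemia core genes, MRN complex, checkpoint
kinases).  It is a documented, replaceable default — pass your own
:class:`~hgsoctype.expression.GenePanel` to any function that takes one.
"""

from __future__ import annotations

from .expression import GenePanel

__all__ = ["EMT38", "HRR30", "CORE_EMT_TFS", "get_panel"]

CORE_EMT_TFS = ("TWIST1", "SNAI1", "SNAI2", "ZEB1", "ZEB2")

_EMT_RELATED_TFS = (
    "KLF4", "GSC", "TCF7L2", "ALX1", "GATA6", "RUNX2", "TCF3", "SOX4",
    "FOXC2", "NFKB1", "KLF2", "KLF6", "TBX3", "TCF4", "PRRX1", "HOXB7",
    "JUN", "FOS", "TAZ", "TGIF1", "ATF1", "ERG", "ETS1", "ID1", "TEAD1",
    "YAP1", "NFYA", "KLF8", "SOX9", "SIX1", "TBXT", "GATA4", "TWIST2",
)

EMT38 = GenePanel("EMT38", CORE_EMT_TFS + _EMT_RELATED_TFS)

_HRR_GENES = (
    # published members of the original panel
    "BRCA1", "BRCA2", "ATR", "ATRX", "FANCA", "FANCC", "FANCD2", "FANCG",
    "RAD50", "RAD51B", "RAD54L",
    # canonical HRR pathway completion (replaceable default)
    "RAD51", "RAD51C", "RAD51D", "RAD52", "RAD54B", "PALB2", "BARD1",
    "BRIP1", "CHEK1", "CHEK2", "MRE11", "NBN", "RBBP8", "XRCC2", "XRCC3",
    "FANCE", "FANCF", "FANCI", "FANCL",
)

HRR30 = GenePanel("HRR30", _HRR_GENES)

_BUILTIN = {"EMT38": EMT38, "HRR30": HRR30}


def get_panel(name: str) -> GenePanel:
    """Look up a built-in panel by name (``EMT38`` or ``HRR30``)."""
    try:
        return _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown built-in panel {name!r}; available: {sorted(_BUILTIN)}"
        ) from None
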
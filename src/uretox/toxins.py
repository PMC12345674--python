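"""The uremic toxin panel.

Five urinary metabolites are profiled: three gut-microbiota-derived
solutes — indoxyl sulfate (IS, from bacterial tryptophan degradation),
p-cresyl sulfate (PCS, from tyrosine/phenylalanine), trimethylamine
N-oxide (TMAO, hepatic oxidation of microbial trimethylamine) — and two
endogenous methylated arginines, asymmetric and symmetric
dimethylarginine (ADMA, SDMA).

The display order (IS, PCS, TMAO, ADMA, SDMA) is fixed and used by every
table and figure-data export so that outputs are directly comparable
across strata and runs.
"""

from __future__ import annotations

from enum import Enum


class Toxin(str, Enum):
    """One of the five profiled urinary uremic toxins."""

    IS = "IS"
    PCS = "PCS"
    TMAO = "TMAO"
    ADMA = "ADMA"
    SDMA = "SDMA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical panel order for all tabular output.
TOXIN_ORDER: tuple[Toxin, ...] = (
    Toxin.IS,
    Toxin.PCS,
    Toxin.TMAO,
    Toxin.ADMA,
    Toxin.SDMA,
)

#: The four named functional ratios (numerator, denominator).
RATIO_PAIRS: dict[str, tuple[Toxin, Toxin]] = {
    "IS/PCS": (Toxin.IS, Toxin.PCS),
    "PCS/TMAO": (Toxin.PCS, Toxin.TMAO),
    "IS/ADMA": (Toxin.IS, Toxin.ADMA),
    "SDMA/ADMA": (Toxin.SDMA, Toxin.ADMA),
}
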
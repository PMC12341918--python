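"""Catalog of the 23 agro-morphological traits used in 2x-4x banana trials.

Each trait carries its abbreviation, full name, unit, measurement period and
the selection direction used when comparing crosses to the Cavendish
ideotype: ``higher`` / ``lower`` mean the ideotype is a higher / lower value
than the control, ``none`` marks purely descriptive traits (the three leaf
blade traits) that carry no selection direction.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Trait:
    abbrev: str
    name: str
    category: str
    unit: str
    period: str
    direction: str  # "higher" | "lower" | "none"


TRAIT_CATALOG: tuple[Trait, ...] = (
    Trait("PH", "Pseudostem Height", "plant", "cm", "flowering", "lower"),
    Trait("PG", "Pseudostem Girth", "plant", "cm", "flowering", "higher"),
    Trait("RI", "Robustness Index", "plant", "", "flowering", "lower"),
    Trait("LL", "Leaf Length", "plant", "cm", "flowering", "none"),
    Trait("LW", "Leaf Width", "plant", "cm", "flowering", "none"),
    Trait("LI", "Leaf Index", "plant", "", "flowering", "none"),
    Trait("NLF", "Number of Leaves at Flowering", "plant", "", "flowering", "higher"),
    Trait("NLH", "Number of Leaves at Harvesting", "plant", "", "harvest", "higher"),
    Trait("PL", "Peduncle Length", "bunch", "cm", "harvest", "higher"),
    Trait("PD", "Peduncle Diameter", "bunch", "cm", "harvest", "higher"),
    Trait("PI", "Peduncle Index", "bunch", "", "harvest", "lower"),
    Trait("BL", "Bunch Length", "bunch", "cm", "harvest", "higher"),
    Trait("BCI", "Bunch Compactness Index", "bunch", "", "harvest", "higher"),
    Trait("FPL", "Fruit Pedicel Length", "fruit", "mm", "harvest", "higher"),
    Trait("FPD", "Fruit Pedicel Diameter", "fruit", "mm", "harvest", "higher"),
    Trait("FL", "Fruit Length", "fruit", "mm", "harvest", "higher"),
    Trait("FG", "Fruit Grade", "fruit", "mm", "harvest", "higher"),
    Trait("NH", "Number of Hands", "yield", "", "flowering", "higher"),
    Trait("NF", "Number of Fruits", "yield", "", "flowering", "higher"),
    Trait("NFH", "Number of Fruits per Hand", "yield", "", "flowering", "higher"),
    Trait("BW", "Bunch Weight", "yield", "kg", "harvest", "higher"),
    Trait("FW", "Fruit Weight", "yield", "g", "harvest", "higher"),
    Trait("DFM", "Days to Fruit Maturity", "yield", "days", "harvest", "lower"),
)

TRAITS_BY_ABBREV = {t.abbrev: t for t in TRAIT_CATALOG}
TRAITS_BY_NAME = {t.name: t for t in TRAIT_CATALOG}


def trait_direction(trait: str) -> str:
    """Selection direction for a trait given by abbreviation or full name."""
    t = TRAITS_BY_ABBREV.get(trait) or TRAITS_BY_NAME.get(trait)
    if t is None:
        raise KeyError(f"unknown trait: {trait!r}")
    return t.direction
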
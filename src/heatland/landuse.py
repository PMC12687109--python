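"""Land-use reclassification and per-cell habitat-suitable fractions.

The land-use side of the pipeline works with LUH2-style annual *fractional*
compositions: each grid cell holds a fraction of each of the 12 LUH2 state
categories, summing to at most 1 (the remainder is water/ice/non-land).
Those 12 categories are collapsed to five classes shared with the IUCN
habitat classification scheme:

====================  =========================================
class                 LUH2 states
====================  =========================================
forest                primf + secdf
non_forest            primn + secdn
agriculture           c3ann + c4ann + c3per + c4per + c3nfx
managed               pastr + range
urban                 urban
====================  =========================================

IUCN habitat codes (levels 1–2) are mapped onto the same five classes;
'introduced vegetation', 'other' and 'unknown' are dropped, as are caves and
marine/coastal types. The default mapping is a module constant and every
entry point accepts a custom mapping, so a different published table can be
substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grid_ranges import FIVE_CLASSES, SpeciesRecord

logger = logging.getLogger(__name__)

#: LUH2 state categories, in canonical column order.
LUH2_STATES = (
    "primf", "primn", "secdf", "secdn", "urban",
    "c3ann", "c4ann", "c3per", "c4per", "c3nfx",
    "pastr", "range",
)

#: LUH2 state -> five-class mapping.
LUH2_TO_CLASS: dict[str, str] = {
    "primf": "forest", "secdf": "forest",
    "primn": "non_forest", "secdn": "non_forest",
    "c3ann": "agriculture", "c4ann": "agriculture",
    "c3per": "agriculture", "c4per": "agriculture", "c3nfx": "agriculture",
    "pastr": "managed", "range": "managed",
    "urban": "urban",
}

#: Default IUCN habitat-code mapping (keys are habitat-scheme codes as
#: strings; level-2 codes fall back to their level-1 prefix). "drop" removes
#: the code. Natural open habitats parallel LUH2's primn/secdn, hence
#: non_forest; rural gardens (14.4) count as urban; caves (7) and
#: marine/aquatic types (9-13, 15) are non-terrestrial and dropped, as are
#: introduced vegetation (16), other (17) and unknown (18).
DEFAULT_IUCN_MAP: dict[str, str] = {
    "1": "forest",
    "2": "non_forest",   # savanna
    "3": "non_forest",   # shrubland
    "4": "non_forest",   # grassland
    "5": "non_forest",   # wetlands (inland, terrestrial side)
    "6": "non_forest",   # rocky areas
    "7": "drop",         # caves & subterranean
    "8": "non_forest",   # desert
    "9": "drop", "10": "drop", "11": "drop", "12": "drop", "13": "drop",
    "14.1": "agriculture",   # arable land
    "14.2": "managed",       # pastureland
    "14.3": "agriculture",   # plantations
    "14.4": "urban",         # rural gardens
    "14.5": "urban",         # urban areas
    "14.6": "drop",          # degraded former forest: no LUH2 analogue
    "14": "drop",
    "15": "drop", "16": "drop", "17": "drop", "18": "drop",
}

_CLASS_INDEX = {c: i for i, c in enumerate(FIVE_CLASSES)}
_STATE_INDEX = {s: i for i, s in enumerate(LUH2_STATES)}

#: Boolean aggregation matrix, shape (12 states, 5 classes).
_AGG = np.zeros((len(LUH2_STATES), len(FIVE_CLASSES)))
for _state, _cls in LUH2_TO_CLASS.items():
    _AGG[_STATE_INDEX[_state], _CLASS_INDEX[_cls]] = 1.0


class InvalidLandUseError(ValueError):
    """Raised for negative fractions or per-cell sums above 1."""


class UnclassifiableSpeciesError(ValueError):
    """Raised when no IUCN habitat code survives reclassification."""


@dataclass
class LandUseLayer:
    """One year of fractional land use in the 12 LUH2 categories.

    ``fractions`` has shape (n_cells, 12) with columns ordered as
    :data:`LUH2_STATES`.
    """

    year: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or self.fractions.shape[1] != len(LUH2_STATES):
            raise InvalidLandUseError(
                f"fractions must be (n_cells, {len(LUH2_STATES)})")
        if np.any(self.fractions < 0):
            raise InvalidLandUseError("negative land-use fractions")
        sums = self.fractions.sum(axis=1)
        if np.any(sums > 1 + 1e-6):
            raise InvalidLandUseError(
                f"per-cell category sum exceeds 1 (max {sums.max():.8f})")


@dataclass
class FiveClassLayer:
    """One year of fractional land use in the five shared classes.

    ``fractions`` has shape (n_cells, 5) with columns ordered as
    :data:`heatland.grid_ranges.FIVE_CLASSES`.
    """

    year: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 2 or self.fractions.shape[1] != len(FIVE_CLASSES):
            raise InvalidLandUseError(
                f"fractions must be (n_cells, {len(FIVE_CLASSES)})")
        if np.any(self.fractions < 0):
            raise InvalidLandUseError("negative class fractions")


def reclassify_luh2(layer: LandUseLayer) -> FiveClassLayer:
    """Collapse a 12-category layer to the five shared classes.

    Conserves each cell's total land fraction exactly (every LUH2 state maps
    to exactly one class).
    """
    return FiveClassLayer(year=layer.year, fractions=layer.fractions @ _AGG)


def _lookup(code: str, mapping: Mapping[str, str]) -> str | None:
    code = str(code).strip()
    if code in mapping:
        return mapping[code]
    level1 = code.split(".")[0]
    if level1 in mapping:
        return mapping[level1]
    logger.warning("unrecognised IUCN habitat code %r dropped", code)
    return None


def reclassify_iucn_habitats(
    iucn_codes: Iterable[str | float],
    mapping: Mapping[str, str] | None = None,
) -> frozenset[str]:
    """Map IUCN habitat-scheme codes to the set of five shared classes.

    Codes may be strings ("14.4") or numbers (1, 14.4); level-2 codes with
    no explicit entry fall back to their level-1 class. Raises
    :class:`UnclassifiableSpeciesError` when nothing survives (such species
    are excluded from the analysis).
    """
    mapping = DEFAULT_IUCN_MAP if mapping is None else mapping
    classes: set[str] = set()
    codes = list(iucn_codes)
    for code in codes:
        if isinstance(code, float) and code == int(code):
            code = str(int(code))
        cls = _lookup(str(code), mapping)
        if cls is not None and cls != "drop":
            classes.add(cls)
    if not classes:
        raise UnclassifiableSpeciesError(
            f"no terrestrial habitat class left after reclassifying {codes}")
    return frozenset(classes)


def class_fractions(habitat_classes: Iterable[str],
                    layer: FiveClassLayer) -> np.ndarray:
    """Per-cell summed fraction of the given classes, shape (n_cells,).

    Not renormalised: cells with a water/ice remainder keep absolute land
    fraction semantics.
    """
    idx = [_CLASS_INDEX[c] for c in habitat_classes]
    return layer.fractions[:, idx].sum(axis=1)


def habitat_fraction(species: SpeciesRecord, layer: FiveClassLayer,
                     cell: int) -> float:
    """Fraction of one cell covered by the species' preferred classes."""
    if not 0 <= cell < layer.fractions.shape[0]:
        raise KeyError(f"cell {cell} not in layer")
    idx = [_CLASS_INDEX[c] for c in species.habitat_classes]
    return float(layer.fractions[cell, idx].sum())
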
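"""Canonical coral species groups and taxonomic harmonization.

Occurrence records compiled across 131 kyr of surveys use wildly
inconsistent nomenclature (pre-1992 *Montastraea annularis* vs. modern
*Orbicella*, *Diploria* vs. *Pseudodiploria*, undifferentiated branching
*Porites*).  Everything is mapped onto 14 canonical species groups that
were consistently recorded across all time bins; all other taxa are
dropped as NOT_TRACKED.
"""

from __future__ import annotations

import csv
import enum
import re
from importlib import resources
from functools import lru_cache


class SpeciesGroup(str, enum.Enum):
    """The 14 tracked coral species groups."""

    ACER = "ACER"
    APAL = "APAL"
    AGARICIA = "AGARICIA"
    MCAV = "MCAV"
    COLPOPHYLLIA = "COLPOPHYLLIA"
    PSEUDODIPLORIA = "PSEUDODIPLORIA"
    MADRACIS = "MADRACIS"
    MEANDRINA = "MEANDRINA"
    MILLEPORA = "MILLEPORA"
    ORBICELLA = "ORBICELLA"
    PORITES_BRANCHING = "PORITES_BRANCHING"
    PASTREOIDES = "PASTREOIDES"
    SIDERASTREA = "SIDERASTREA"
    STEPHANOCOENIA = "STEPHANOCOENIA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Sentinel returned for taxa outside the 14 tracked groups.
NOT_TRACKED = "NOT_TRACKED"

ALL_SPECIES: tuple[SpeciesGroup, ...] = tuple(SpeciesGroup)


def _normalize(name: str) -> str:
    """Case/punctuation-insensitive key for alias lookup."""
    s = name.strip().lower()
    s = s.replace(".", " ")
    s = re.sub(r"\s+", " ", s).strip()
    # trailing 'spp'/'sp' qualifiers carry no information
    s = re.sub(r"\s+spp?$", "", s)
    return s


@lru_cache(maxsize=1)
def _default_alias_map() -> dict[str, SpeciesGroup]:
    path = resources.files("reefchrono.data").joinpath("aliases.csv")
    with path.open("r", encoding="utf-8") as fh:
        return _parse_alias_rows(csv.DictReader(fh))


def _parse_alias_rows(rows) -> dict[str, SpeciesGroup]:
    amap: dict[str, SpeciesGroup] = {}
    for row in rows:
        group = SpeciesGroup(row["species_group"].strip())
        key = _normalize(row["raw_name"])
        if key in amap and amap[key] is not group:
            raise ValueError(f"alias {row['raw_name']!r} maps to two groups")
        amap[key] = group
    # canonical labels always round-trip
    for sp in SpeciesGroup:
        amap.setdefault(_normalize(sp.value), sp)
    return amap


def load_alias_table(path) -> dict[str, SpeciesGroup]:
    """Load a user-supplied alias CSV (columns raw_name, species_group)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return _parse_alias_rows(csv.DictReader(fh))


def canonicalize_taxon(raw_name: str, alias_map: dict[str, SpeciesGroup] | None = None):
    """Map a raw taxon name to its :class:`SpeciesGroup` or ``NOT_TRACKED``.

    Parameters
    ----------
    raw_name
        Name as recorded in the source survey, e.g. ``"Montastraea annularis"``.
    alias_map
        Optional custom alias table from :func:`load_alias_table`; defaults
        to the shipped table.

    Returns
    -------
    SpeciesGroup or the string ``"NOT_TRACKED"``.
    """
    if not raw_name or not raw_name.strip():
        raise ValueError("empty taxon name")
    amap = alias_map if alias_map is not None else _default_alias_map()
    return amap.get(_normalize(raw_name), NOT_TRACKED)
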
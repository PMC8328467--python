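"""Time bins and reef-zone assignment.

Surveys spanning ~131,000 years before present (Late Pleistocene) to
2011 AD are pooled into 11 ordered time bins; each survey is also
assigned to a forereef depth zone (reef crest, roughly 0-6 m, or
midslope, roughly 6-20 m).  Back-reef, reef-flat and reef-pavement
habitats are excluded outright: they are not preferred Acropora
environments and the zonation scheme is anchored on the historical
A. palmata (crest) / A. cervicornis (midslope) dominance transition.

Fossil ages are years before present with "present" = 1950 AD
(radiocarbon convention).  The printed bin scheme leaves a gap between
the Pleistocene (down to 12,000 ybp) and the Holocene (from 9,100 ybp);
ages inside the gap are flagged unassignable rather than silently
binned.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class TimeBin(enum.IntEnum):
    """Ordered time bins, Late Pleistocene through 2005-2011."""

    PLEISTOCENE = 0
    HOLOCENE = 1
    B1500_1959 = 2
    B1960_1969 = 3
    B1970_1979 = 4
    B1980_1984 = 5
    B1985_1989 = 6
    B1990_1994 = 7
    B1995_2000 = 8
    B2001_2004 = 9
    B2005_2011 = 10

    @property
    def label(self) -> str:
        return _BIN_LABELS[self]

    @property
    def start_year(self) -> float:
        """Representative start of the bin in calendar years AD."""
        return _BIN_START_AD[self]


_BIN_LABELS = {
    TimeBin.PLEISTOCENE: "Pleistocene",
    TimeBin.HOLOCENE: "Holocene",
    TimeBin.B1500_1959: "1500-1959",
    TimeBin.B1960_1969: "1960-1969",
    TimeBin.B1970_1979: "1970-1979",
    TimeBin.B1980_1984: "1980-1984",
    TimeBin.B1985_1989: "1985-1989",
    TimeBin.B1990_1994: "1990-1994",
    TimeBin.B1995_2000: "1995-2000",
    TimeBin.B2001_2004: "2001-2004",
    TimeBin.B2005_2011: "2005-2011",
}

_BIN_START_AD = {
    TimeBin.PLEISTOCENE: 1950 - 131_000,
    TimeBin.HOLOCENE: 1950 - 9_100,
    TimeBin.B1500_1959: 1500,
    TimeBin.B1960_1969: 1960,
    TimeBin.B1970_1979: 1970,
    TimeBin.B1980_1984: 1980,
    TimeBin.B1985_1989: 1985,
    TimeBin.B1990_1994: 1990,
    TimeBin.B1995_2000: 1995,
    TimeBin.B2001_2004: 2001,
    TimeBin.B2005_2011: 2005,
}

# Modern calendar-year bounds, both endpoints inclusive.  The default
# follows the methods text (1995-2000 / 2001-2004); the alternative
# labelling that appears in the trends table (1995-1999 / 2000-2004)
# is available via year2000_with_older=False.
_MODERN_BOUNDS = [
    (TimeBin.B1500_1959, 1500, 1959),
    (TimeBin.B1960_1969, 1960, 1969),
    (TimeBin.B1970_1979, 1970, 1979),
    (TimeBin.B1980_1984, 1980, 1984),
    (TimeBin.B1985_1989, 1985, 1989),
    (TimeBin.B1990_1994, 1990, 1994),
    (TimeBin.B1995_2000, 1995, 2000),
    (TimeBin.B2001_2004, 2001, 2004),
    (TimeBin.B2005_2011, 2005, 2011),
]

PLEISTOCENE_MAX_BP = 131_000
PLEISTOCENE_MIN_BP = 12_000
HOLOCENE_MAX_BP = 9_100
BP_PRESENT_AD = 1950

MODERN_BINS = tuple(b for b, _, _ in _MODERN_BOUNDS)
FOSSIL_BINS = (TimeBin.PLEISTOCENE, TimeBin.HOLOCENE)


class TimeOutOfRangeError(ValueError):
    """Year/age outside the ~131,000 ybp - 2011 AD study window."""


class UnassignableAgeError(ValueError):
    """Fossil age inside the 12,000-9,100 ybp gap between bins."""


def assign_time_bin(value: float, era: str = "ad", *, year2000_with_older: bool = True) -> TimeBin:
    """Assign a calendar year or fossil age to its time bin.

    Parameters
    ----------
    value
        Calendar year AD if ``era == "ad"``, or age in years before
        present (1950 AD) if ``era == "bp"``.
    era
        ``"ad"`` or ``"bp"``.
    year2000_with_older
        If True (default) year 2000 belongs to the 1995-2000 bin; if
        False, to the 2000-2004 bin (alternative printed labelling).

    Raises
    ------
    TimeOutOfRangeError
        year > 2011, age > 131,000 ybp, or pre-1500 AD calendar years
        outside the Holocene span.
    UnassignableAgeError
        ages in the 12,000-9,100 ybp gap between the printed bins.
    """
    era = era.lower()
    if era == "bp":
        if value > PLEISTOCENE_MAX_BP:
            raise TimeOutOfRangeError(f"age {value} ybp predates the Pleistocene bin")
        if value >= PLEISTOCENE_MIN_BP:
            return TimeBin.PLEISTOCENE
        if value > HOLOCENE_MAX_BP:
            raise UnassignableAgeError(
                f"age {value} ybp falls in the 12,000-9,100 ybp gap between bins"
            )
        # Holocene ages younger than 9,100 ybp convert to calendar years
        value = BP_PRESENT_AD - value
        era = "ad"
    if era != "ad":
        raise ValueError(f"unknown era {era!r}")

    if value > 2011:
        raise TimeOutOfRangeError(f"year {value} is beyond the final 2005-2011 bin")
    if value < 1500:
        if value >= BP_PRESENT_AD - HOLOCENE_MAX_BP:
            return TimeBin.HOLOCENE
        raise TimeOutOfRangeError(f"calendar year {value} predates the Holocene span")
    for tb, lo, hi in _MODERN_BOUNDS:
        if lo <= value <= hi:
            if value == 2000 and not year2000_with_older:
                return TimeBin.B2001_2004
            return tb
    raise TimeOutOfRangeError(f"year {value} not covered by any bin")  # pragma: no cover


class ReefZone(str, enum.Enum):
    CREST = "crest"
    MIDSLOPE = "midslope"
    EXCLUDED = "excluded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_EXCLUDED_HABITATS = {"backreef", "reef_flat", "reef_pavement"}

CREST_MAX_DEPTH_M = 6.0
CREST_MAX_DEPTH_OFFSHORE_M = 10.0
MIDSLOPE_MAX_DEPTH_M = 20.0


@dataclass
class ZoneDecision:
    """Zone assignment together with the rule that produced it."""

    zone: ReefZone
    reason: str


def assign_reef_zone(
    depth_m: float | None = None,
    habitat: str = "unknown",
    *,
    offshore_high_clarity: bool = False,
    high_wave_exposure: bool = False,
    palmata_dominant: bool = False,
    cervicornis_dominant: bool = False,
) -> ZoneDecision:
    """Deterministic reef-zone assignment.

    Excluded habitats (backreef/reef flat/reef pavement) always lose,
    regardless of depth.  Otherwise depth decides: <=6 m crest (<=10 m
    for offshore high-clarity sites), 6-20 m midslope, >20 m excluded.
    Without depth, Acropora context or wave exposure substitutes
    (palmata dominance or high wave exposure -> crest; cervicornis
    dominance -> midslope).  A total function: EXCLUDED with a reason
    is the fallback, never a guess.
    """
    if habitat in _EXCLUDED_HABITATS:
        return ZoneDecision(ReefZone.EXCLUDED, f"habitat:{habitat}")
    crest_cut = CREST_MAX_DEPTH_OFFSHORE_M if offshore_high_clarity else CREST_MAX_DEPTH_M
    if depth_m is not None:
        if depth_m < 0:
            raise ValueError(f"negative depth {depth_m}")
        if depth_m <= crest_cut:
            return ZoneDecision(ReefZone.CREST, "depth")
        if depth_m <= MIDSLOPE_MAX_DEPTH_M:
            return ZoneDecision(ReefZone.MIDSLOPE, "depth")
        return ZoneDecision(ReefZone.EXCLUDED, "depth>20m")
    if palmata_dominant or high_wave_exposure:
        return ZoneDecision(ReefZone.CREST, "acropora_or_exposure_context")
    if cervicornis_dominant:
        return ZoneDecision(ReefZone.MIDSLOPE, "acropora_context")
    return ZoneDecision(ReefZone.EXCLUDED, "no_depth_no_context")
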
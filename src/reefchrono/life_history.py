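"""Trait-based life-history guilds for the 14 coral species groups.

Corals are classified into three analyzed guilds following Grime's
triangle as adapted for reef corals: *competitive* (fast-growing,
large branching, disturbance-sensitive — the two Caribbean Acropora,
optionally the hydrozoan Millepora), *stress-tolerant* (slow/moderate
growth, domed colonies, disturbance-resistant) and *weedy* (brooding
opportunistic colonizers).  A fourth, generalist, strategy exists in
the trait scheme but has no consistently-recorded Caribbean members
and carries no model.

Millepora is a hydrozoan, not a scleractinian, and sits outside the
classical quantitative guild analyses; its Acropora-like space
pre-emption (fast growth, fragmentation, high bleaching
susceptibility) motivates optionally placing it in the competitive
guild, controlled by a flag so both variants can be modelled.
"""

from __future__ import annotations

import enum
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .taxa import SpeciesGroup


class LifeHistoryGroup(str, enum.Enum):
    COMPETITIVE = "competitive"
    STRESS_TOLERANT = "stress_tolerant"
    WEEDY = "weedy"
    GENERALIST = "generalist"  # represented but unpopulated and unmodelled

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_COMPETITIVE_CORE = (SpeciesGroup.ACER, SpeciesGroup.APAL)
_STRESS_TOLERANT = (
    SpeciesGroup.COLPOPHYLLIA,
    SpeciesGroup.PSEUDODIPLORIA,
    SpeciesGroup.MEANDRINA,
    SpeciesGroup.MCAV,
    SpeciesGroup.ORBICELLA,
    SpeciesGroup.SIDERASTREA,
    SpeciesGroup.STEPHANOCOENIA,
)
_WEEDY = (
    SpeciesGroup.AGARICIA,
    SpeciesGroup.PORITES_BRANCHING,
    SpeciesGroup.PASTREOIDES,
    SpeciesGroup.MADRACIS,
)

#: Printed growth-class ranges (mm/yr), kept as reference metadata only.
PRINTED_GROWTH_RANGES = {"slow": (1.1, 4.0), "moderate": (5.0, 7.0), "fast": (13.2, 119.5)}


@lru_cache(maxsize=1)
def load_trait_table(path: str | None = None) -> pd.DataFrame:
    """Load the shipped (or a user-supplied) trait table."""
    if path is None:
        src = resources.files("reefchrono.data").joinpath("traits.csv")
        with src.open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    df = df.set_index("species_group")
    if (df["growth_rate_mm_yr"] <= 0).any():
        raise ValueError("growth rates must be positive")
    return df


def assign_group(
    species: SpeciesGroup, millepora_included: bool = True
) -> LifeHistoryGroup | None:
    """Guild for a species group; Millepora's placement is flag-controlled.

    With the flag off Millepora returns ``None``: it is excluded from
    guild-level models but still tracked in species-level trends.
    """
    if species in _COMPETITIVE_CORE:
        return LifeHistoryGroup.COMPETITIVE
    if species is SpeciesGroup.MILLEPORA:
        return LifeHistoryGroup.COMPETITIVE if millepora_included else None
    if species in _STRESS_TOLERANT:
        return LifeHistoryGroup.STRESS_TOLERANT
    if species in _WEEDY:
        return LifeHistoryGroup.WEEDY
    raise ValueError(f"unknown species group {species!r}")  # pragma: no cover


def guild_members(
    group: LifeHistoryGroup, millepora_included: bool = True
) -> tuple[SpeciesGroup, ...]:
    """Member species of a guild, in trait-table order."""
    if group is LifeHistoryGroup.COMPETITIVE:
        return _COMPETITIVE_CORE + ((SpeciesGroup.MILLEPORA,) if millepora_included else ())
    if group is LifeHistoryGroup.STRESS_TOLERANT:
        return _STRESS_TOLERANT
    if group is LifeHistoryGroup.WEEDY:
        return _WEEDY
    if group is LifeHistoryGroup.GENERALIST:
        return ()
    raise ValueError(f"unknown guild {group!r}")  # pragma: no cover


ANALYZED_GUILDS = (
    LifeHistoryGroup.COMPETITIVE,
    LifeHistoryGroup.STRESS_TOLERANT,
    LifeHistoryGroup.WEEDY,
)


def rank_growth(rates: dict[str, float]) -> dict[str, str]:
    """Split species into slow/moderate/fast growth terciles.

    Classes are bottom/middle/top thirds of the rate distribution by
    rank fraction: a species with (minimum) rank ``r`` among ``n``
    rates is slow if ``r/n <= 1/3``, moderate if ``r/n <= 2/3``, else
    fast.  Minimum ranks send boundary ties to the slower class, and
    the classification is invariant to rescaling all rates by a
    positive constant.
    """
    if len(rates) < 3:
        raise ValueError("need at least 3 species to form terciles")
    names = list(rates)
    vals = np.asarray([rates[n] for n in names], dtype=float)
    if (vals <= 0).any():
        raise ValueError("growth rates must be positive")
    frac = rankdata(vals, method="min") / len(vals)
    labels = np.where(frac <= 1 / 3, "slow", np.where(frac <= 2 / 3, "moderate", "fast"))
    return dict(zip(names, labels))
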
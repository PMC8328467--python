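"""Survey records and binned presence/absence matrices.

A *survey* is the observational unit: a unique combination of reef
site, depth zone, and year (or fossil age).  Replicates (transects,
quadrats) within a survey are collapsed to a single record.  Harmonized
surveys are arranged into one presence/absence matrix (surveys x 14
species groups, cells 0/1/missing) per reef zone x time bin, carrying a
country label per row for the downstream random-effect and
within-country dissimilarity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import numpy as np
import pandas as pd

from .binning import (
    ReefZone,
    TimeBin,
    TimeOutOfRangeError,
    UnassignableAgeError,
    assign_reef_zone,
    assign_time_bin,
)
from .taxa import ALL_SPECIES, NOT_TRACKED, SpeciesGroup, canonicalize_taxon

SPECIES_COLUMNS = [sp.value for sp in ALL_SPECIES]


@dataclass
class SurveyRecord:
    """One site x depth-zone x year observation with raw taxon scores.

    ``taxa`` maps raw taxon names to 0/1 presence.  ``era`` is ``"ad"``
    for calendar years and ``"bp"`` for fossil ages (years before 1950).
    """

    survey_id: str
    country: str
    site: str
    year_or_age: float
    era: str = "ad"
    depth_m: float | None = None
    habitat: str = "unknown"
    offshore_high_clarity: bool = False
    high_wave_exposure: bool = False
    palmata_dominant: bool = False
    cervicornis_dominant: bool = False
    replicate_id: str | None = None
    taxa: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_m is not None and self.depth_m < 0:
            raise ValueError(f"{self.survey_id}: negative depth")
        for name, present in self.taxa.items():
            if present not in (0, 1):
                raise ValueError(f"{self.survey_id}: presence for {name!r} must be 0/1")
        if self.era == "ad" and self.year_or_age > 2011:
            raise ValueError(f"{self.survey_id}: modern year beyond 2011")


def aggregate_replicates(records: list[SurveyRecord]) -> SurveyRecord:
    """Collapse replicate records of one survey to a site-level record.

    A species is present if present in any replicate (logical OR),
    absent if scored absent in at least one replicate and present in
    none, and missing if never scored.  Order-invariant.
    """
    if not records:
        raise ValueError("no records to aggregate")
    first = records[0]
    for r in records[1:]:
        if (r.site, r.country) != (first.site, first.country):
            raise ValueError(
                f"conflicting site/country metadata in replicates of {first.survey_id}"
            )
    merged: dict[str, int] = {}
    for r in records:
        for name, present in r.taxa.items():
            merged[name] = max(merged.get(name, 0), int(present))
    out = SurveyRecord(
        survey_id=first.survey_id,
        country=first.country,
        site=first.site,
        year_or_age=first.year_or_age,
        era=first.era,
        depth_m=first.depth_m,
        habitat=first.habitat,
        offshore_high_clarity=first.offshore_high_clarity,
        high_wave_exposure=first.high_wave_exposure,
        palmata_dominant=first.palmata_dominant,
        cervicornis_dominant=first.cervicornis_dominant,
        replicate_id=None,
        taxa=merged,
    )
    return out


@dataclass
class BinnedOccurrenceMatrix:
    """Presence/absence matrix for one reef zone x time bin.

    ``data`` is surveys x 14 species groups with values 0.0/1.0/NaN
    (NaN = not scored); ``country`` aligns with ``data.index``.
    """

    zone: ReefZone
    bin: TimeBin
    data: pd.DataFrame
    country: pd.Series

    def __post_init__(self) -> None:
        if list(self.data.columns) != SPECIES_COLUMNS:
            raise ValueError("matrix columns must be the 14 species groups in order")
        if not self.data.index.equals(self.country.index):
            raise ValueError("country labels must align with survey rows")
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("matrix cells must be 0, 1 or missing")
        if self.country.isna().any() or (self.country == "").any():
            raise ValueError("every survey row needs a country label")

    @property
    def n_surveys(self) -> int:
        return len(self.data)


def filter_full_complement(
    matrix: BinnedOccurrenceMatrix, members: list[SpeciesGroup]
) -> BinnedOccurrenceMatrix:
    """Keep only surveys scoring every member of a life-history group.

    Ensures equal survey sets across a group's member species in the
    occurrence models: a survey missing any member is dropped entirely.
    """
    if not members:
        raise ValueError("life-history group with zero members")
    cols = [m.value for m in members]
    keep = matrix.data[cols].notna().all(axis=1)
    return BinnedOccurrenceMatrix(
        zone=matrix.zone,
        bin=matrix.bin,
        data=matrix.data.loc[keep],
        country=matrix.country.loc[keep],
    )


def harmonize_records(
    records: list[SurveyRecord],
    *,
    alias_map=None,
    year2000_with_older: bool = True,
) -> tuple[dict[tuple[ReefZone, TimeBin], BinnedOccurrenceMatrix], dict]:
    """Apply the full curation pipeline to raw survey records.

    Replicates are collapsed per (site, zone, bin); taxa are mapped to
    the 14 canonical species groups; records landing in excluded zones,
    out-of-range times, or the fossil bin gap are dropped and counted in
    the returned curation log.

    Returns
    -------
    matrices : dict mapping (zone, bin) -> BinnedOccurrenceMatrix
    log : dict of exclusion/aggregation counters
    """
    log = Counter()
    # (zone, bin, site, country) -> replicate list
    grouped: dict[tuple, list[SurveyRecord]] = {}
    for rec in records:
        decision = assign_reef_zone(
            rec.depth_m,
            rec.habitat,
            offshore_high_clarity=rec.offshore_high_clarity,
            high_wave_exposure=rec.high_wave_exposure,
            palmata_dominant=rec.palmata_dominant,
            cervicornis_dominant=rec.cervicornis_dominant,
        )
        if decision.zone is ReefZone.EXCLUDED:
            log[f"excluded_zone_{decision.reason}"] += 1
            continue
        try:
            tb = assign_time_bin(
                rec.year_or_age, rec.era, year2000_with_older=year2000_with_older
            )
        except UnassignableAgeError:
            log["excluded_age_gap"] += 1
            continue
        except TimeOutOfRangeError:
            log["excluded_time_out_of_range"] += 1
            continue
        grouped.setdefault((decision.zone, tb, rec.site, rec.country), []).append(rec)

    by_zone_bin: dict[tuple[ReefZone, TimeBin], list] = {}
    for (zone, tb, site, country), reps in grouped.items():
        if len(reps) > 1:
            log["replicate_sets_aggregated"] += 1
        survey = aggregate_replicates(reps)
        row = {c: np.nan for c in SPECIES_COLUMNS}
        for raw, present in survey.taxa.items():
            group = canonicalize_taxon(raw, alias_map)
            if group == NOT_TRACKED:
                log["taxa_not_tracked"] += 1
                continue
            col = group.value
            row[col] = max(row[col], float(present)) if not np.isnan(row[col]) else float(present)
        by_zone_bin.setdefault((zone, tb), []).append((survey.survey_id, country, row))

    matrices: dict[tuple[ReefZone, TimeBin], BinnedOccurrenceMatrix] = {}
    for key, rows in by_zone_bin.items():
        ids = [r[0] for r in rows]
        countries = pd.Series([r[1] for r in rows], index=ids, name="country")
        data = pd.DataFrame([r[2] for r in rows], index=ids, columns=SPECIES_COLUMNS)
        matrices[key] = BinnedOccurrenceMatrix(zone=key[0], bin=key[1], data=data, country=countries)
        log[f"surveys_{key[0].value}_{key[1].name}"] = len(rows)
    return matrices, dict(log)
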
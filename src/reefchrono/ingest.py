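"""CSV/YAML interfaces for raw survey data and curated matrices.

Two input dialects are supported:

* **long** - one row per record x taxon:
  ``survey_id, country, site, year_or_age, era, depth_m, habitat,
  offshore_high_clarity, high_wave_exposure, palmata_dominant,
  cervicornis_dominant, replicate_id, taxon, present``
* **wide** - one row per record with one 0/1/empty column per raw
  taxon name after the metadata columns.

Output: per zone x bin wide CSV (survey_id, country, 14 species
columns, empty cell = not scored) plus a JSON curation log.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .binning import ReefZone, TimeBin
from .records import SPECIES_COLUMNS, BinnedOccurrenceMatrix, SurveyRecord, harmonize_records
from .taxa import load_alias_table

_META_COLS = [
    "survey_id",
    "country",
    "site",
    "year_or_age",
    "era",
    "depth_m",
    "habitat",
    "offshore_high_clarity",
    "high_wave_exposure",
    "palmata_dominant",
    "cervicornis_dominant",
    "replicate_id",
]

_BOOL_COLS = [
    "offshore_high_clarity",
    "high_wave_exposure",
    "palmata_dominant",
    "cervicornis_dominant",
]


def _record_from_meta(meta: dict, taxa: dict[str, int]) -> SurveyRecord:
    depth = meta.get("depth_m")
    if depth is not None and (pd.isna(depth) or depth == ""):
        depth = None
    rep = meta.get("replicate_id")
    if rep is not None and (pd.isna(rep) or rep == ""):
        rep = None
    return SurveyRecord(
        survey_id=str(meta["survey_id"]),
        country=str(meta["country"]),
        site=str(meta.get("site", meta["survey_id"])),
        year_or_age=float(meta["year_or_age"]),
        era=str(meta.get("era", "ad") or "ad").lower(),
        depth_m=None if depth is None else float(depth),
        habitat=str(meta.get("habitat", "unknown") or "unknown"),
        offshore_high_clarity=_truthy(meta.get("offshore_high_clarity")),
        high_wave_exposure=_truthy(meta.get("high_wave_exposure")),
        palmata_dominant=_truthy(meta.get("palmata_dominant")),
        cervicornis_dominant=_truthy(meta.get("cervicornis_dominant")),
        replicate_id=None if rep is None else str(rep),
        taxa=taxa,
    )


def _truthy(v) -> bool:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return False
    return str(v).strip().lower() in {"1", "true", "yes", "y"}


def read_survey_csv(path, layout: str = "long", sep: str = ",") -> list[SurveyRecord]:
    """Read raw survey records from a long- or wide-layout CSV/TSV."""
    df = pd.read_csv(path, sep=sep)
    if layout == "long":
        required = {"survey_id", "country", "year_or_age", "taxon", "present"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long layout missing columns: {sorted(missing)}")
        records = []
        group_cols = ["survey_id"] + (["replicate_id"] if "replicate_id" in df.columns else [])
        for _, sub in df.groupby(group_cols, dropna=False, sort=False):
            meta = sub.iloc[0].to_dict()
            taxa = {
                str(row["taxon"]): int(row["present"])
                for _, row in sub.iterrows()
                if not pd.isna(row["present"])
            }
            records.append(_record_from_meta(meta, taxa))
        return records
    if layout == "wide":
        if "survey_id" not in df.columns:
            raise ValueError("wide layout requires a survey_id column")
        taxon_cols = [c for c in df.columns if c not in _META_COLS]
        records = []
        for _, row in df.iterrows():
            taxa = {
                c: int(row[c]) for c in taxon_cols if not pd.isna(row[c]) and row[c] != ""
            }
            records.append(_record_from_meta(row.to_dict(), taxa))
        return records
    raise ValueError(f"unknown layout {layout!r}")


def write_matrix_csv(matrix: BinnedOccurrenceMatrix, path) -> None:
    out = matrix.data.copy()
    out.insert(0, "country", matrix.country)
    out.index.name = "survey_id"
    out.to_csv(path)


def read_matrix_csv(path, zone: ReefZone, tb: TimeBin) -> BinnedOccurrenceMatrix:
    df = pd.read_csv(path, index_col="survey_id")
    df.index = df.index.astype(str)
    df.index.name = None
    country = df.pop("country").astype(str)
    return BinnedOccurrenceMatrix(zone=zone, bin=tb, data=df[SPECIES_COLUMNS], country=country)


def load_ingest_config(path) -> dict:
    """YAML config: input path, layout, separator, alias table, bin options."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    cfg.setdefault("layout", "long")
    cfg.setdefault("sep", ",")
    cfg.setdefault("year2000_with_older", True)
    return cfg


def run_ingest(cfg: dict, outdir) -> dict:
    """Read, harmonize and write curated matrices per the config."""
    alias_map = load_alias_table(cfg["alias_table"]) if cfg.get("alias_table") else None
    records = read_survey_csv(cfg["input"], layout=cfg["layout"], sep=cfg["sep"])
    matrices, log = harmonize_records(
        records, alias_map=alias_map, year2000_with_older=cfg["year2000_with_older"]
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (zone, tb), matrix in sorted(matrices.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        write_matrix_csv(matrix, outdir / f"matrix_{zone.value}_{tb.name}.csv")
    with open(outdir / "curation_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
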
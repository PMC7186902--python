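"""CSV input/output for sample metadata, reading series, and reports.

Two input files describe a study:

* samples CSV — ``sample_id, species, tissue, mass_g, method[, chamber_volume_L]``
  (one row per crushed sample; volume blank → the method's default volume);
* readings CSV — ``sample_id, minutes, ppm`` (one row per meter reading).

Field teams produce spreadsheets, so parsing is strict and failures name the
offending row: missing columns, non-numeric fields, non-increasing times,
duplicate (sample_id, minutes) pairs and unmatched sample ids all raise
:class:`ParseError`.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .timeseries import ReadingSeries, SampleRecord
from .units import ChamberSpec

__all__ = [
    "ParseError",
    "read_readings",
    "read_samples",
    "write_samples_csv",
    "write_readings_csv",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

SAMPLES_COLUMNS = ["sample_id", "species", "tissue", "mass_g", "method"]
READINGS_COLUMNS = ["sample_id", "minutes", "ppm"]


class ParseError(ValueError):
    pass


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path, allow_blank: bool = False) -> pd.Series:
    raw = df[col].str.strip()
    blank = raw == ""
    if blank.any() and not allow_blank:
        row = int(df.index[blank][0]) + 2  # header is line 1
        raise ParseError(f"{path}: empty {col!r} at line {row}")
    vals = pd.to_numeric(raw.where(~blank, None), errors="coerce")
    bad = vals.isna() & ~blank
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: non-numeric {col!r} {raw[bad].iloc[0]!r} at line {row}")
    return vals


def read_readings_frame(path: str | Path) -> pd.DataFrame:
    """Validated readings table with numeric minutes/ppm, in file order."""
    df = _read_csv(path, READINGS_COLUMNS)
    df = df.copy()
    df["minutes"] = _numeric(df, "minutes", path)
    df["ppm"] = _numeric(df, "ppm", path)
    dup = df.duplicated(subset=["sample_id", "minutes"], keep=False)
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ParseError(f"{path}: duplicate (sample_id, minutes) at line {row}")
    for sid, grp in df.groupby("sample_id", sort=False):
        t = grp["minutes"].to_numpy()
        if (t[1:] <= t[:-1]).any():
            i = int(grp.index[1:][t[1:] <= t[:-1]][0]) + 2
            raise ParseError(f"{path}: minutes out of order for sample {sid!r} at line {i}")
        if t[0] <= 0:
            raise ParseError(f"{path}: first reading time must be > 0 for sample {sid!r}")
        if (grp["ppm"].to_numpy() < 0).any():
            raise ParseError(f"{path}: negative ppm for sample {sid!r}")
    return df


def read_readings(
    path: str | Path,
    chamber: ChamberSpec | None = None,
    detection_limit_ppm: float = 0.3,
) -> list[ReadingSeries]:
    """Readings CSV → one :class:`ReadingSeries` per sample (default cup chamber)."""
    df = read_readings_frame(path)
    chamber = chamber or ChamberSpec.cup()
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        out.append(
            ReadingSeries(
                sample_id=str(sid),
                times_min=tuple(grp["minutes"]),
                ppm=tuple(grp["ppm"]),
                chamber=chamber,
                detection_limit_ppm=detection_limit_ppm,
            )
        )
    return out


def read_samples(
    samples_path: str | Path,
    readings_path: str | Path,
    config: RunConfig | None = None,
) -> list[SampleRecord]:
    """Join the samples and readings CSVs into validated :class:`SampleRecord`s.

    Every reading must reference a declared sample and every sample must have
    at least one reading; violations raise :class:`ParseError` listing the
    offending ids.
    """
    cfg = config or RunConfig()
    sdf = _read_csv(samples_path, SAMPLES_COLUMNS)
    sdf = sdf.copy()
    sdf["mass_g"] = _numeric(sdf, "mass_g", samples_path)
    if sdf["sample_id"].duplicated().any():
        dups = sorted(sdf["sample_id"][sdf["sample_id"].duplicated()].unique())
        raise ParseError(f"{samples_path}: duplicate sample_id(s) {dups}")
    has_vol = "chamber_volume_L" in sdf.columns
    if has_vol:
        sdf["chamber_volume_L"] = _numeric(sdf, "chamber_volume_L", samples_path, allow_blank=True)
    rdf = read_readings_frame(readings_path)

    declared = set(sdf["sample_id"])
    observed = set(rdf["sample_id"])
    unknown = sorted(observed - declared)
    if unknown:
        raise ParseError(f"{readings_path}: readings for undeclared sample id(s) {unknown}")
    silent = sorted(declared - observed)
    if silent:
        raise ParseError(f"{samples_path}: sample id(s) with no readings {silent}")

    records = []
    grouped = dict(tuple(rdf.groupby("sample_id", sort=False)))
    for _, row in sdf.iterrows():
        method = row["method"].strip()
        try:
            vol = None
            if has_vol and not pd.isna(row["chamber_volume_L"]):
                vol = float(row["chamber_volume_L"])
            chamber = ChamberSpec.for_method(method, vol or cfg.chamber_volume(method))
        except ValueError as exc:
            raise ParseError(f"{samples_path}: sample {row['sample_id']!r}: {exc}") from exc
        grp = grouped[row["sample_id"]]
        series = ReadingSeries(
            sample_id=str(row["sample_id"]),
            times_min=tuple(grp["minutes"]),
            ppm=tuple(grp["ppm"]),
            chamber=chamber,
            detection_limit_ppm=cfg.detection_limit_ppm,
        )
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                species=str(row["species"]),
                tissue=str(row["tissue"]),
                mass_g=float(row["mass_g"]),
                series=series,
            )
        )
    logger.info("loaded %d samples from %s", len(records), samples_path)
    return records


def write_samples_csv(records: list[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "species": r.species,
            "tissue": r.tissue,
            "mass_g": r.mass_g,
            "method": r.series.chamber.method.value,
            "chamber_volume_L": r.series.chamber.volume_l,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=SAMPLES_COLUMNS + ["chamber_volume_L"]).to_csv(path, index=False)


def write_readings_csv(records: list[SampleRecord], path: str | Path) -> None:
    rows = [
        {"sample_id": r.sample_id, "minutes": t, "ppm": p}
        for r in records
        for t, p in zip(r.series.times_min, r.series.ppm)
    ]
    pd.DataFrame(rows, columns=READINGS_COLUMNS).to_csv(path, index=False)


def results_to_frame(results: list) -> pd.DataFrame:
    """Flatten a list of result dataclasses into a DataFrame for CSV reports."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
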
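"""Reduce one sample's meter-reading series to totals, duration and kinetics.

A crushed-tissue sample sits in a sealed chamber; at each reading time the
chamber headspace is pumped through the meter and replaced with HCN-free air,
so each reading stands for the full chamber contents accumulated since the
previous evacuation.  Total release is therefore the sum over readings of the
ppm→μmol conversion; systematic under-recovery of the open protocol is folded
into the empirical calibration factor.

The duration of release is summarised by the ppm-weighted mean reading time

    D = Σ t_n · ppm_n / Σ ppm_n     (over positive readings)

which is scale-free in ppm and distinguishes "fast" (minutes) from "slow"
(hour-scale) cyanogen release.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import CalibrationFactor, ChamberSpec, ppm_to_micromol

__all__ = [
    "ReadingSeries",
    "SampleRecord",
    "ConcentrationResult",
    "DurationResult",
    "DepletionResult",
    "SpeciesSummary",
    "total_release",
    "weighted_mean_duration",
    "classify_kinetics",
    "depletion_time",
    "species_summary",
]

#: Lowest meter reading that can be quantified, ppm.
DEFAULT_DETECTION_LIMIT_PPM = 0.3

TISSUES = {"leaf", "root", "stem", "flower", "fruit", "tendril", "arthropod", "other"}


@dataclass(frozen=True)
class ReadingSeries:
    """Ordered (time, ppm) meter readings for one crushed sample.

    Times are minutes since crushing (t0 = 0); the first reading time is the
    protocol's first sampling point (5 min for the cup protocol, 20 s for
    high-frequency jar series) and comes from the data, not from a constant.
    """

    sample_id: str
    times_min: tuple[float, ...]
    ppm: tuple[float, ...]
    chamber: ChamberSpec
    detection_limit_ppm: float = DEFAULT_DETECTION_LIMIT_PPM

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times_min)
        vals = tuple(float(p) for p in self.ppm)
        object.__setattr__(self, "times_min", times)
        object.__setattr__(self, "ppm", vals)
        if len(times) != len(vals) or len(times) < 1:
            raise ValueError(
                f"{self.sample_id}: need equal-length, non-empty times and ppm"
            )
        if times[0] <= 0 or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.sample_id}: times must be strictly increasing and > 0")
        if any(p < 0 for p in vals):
            raise ValueError(f"{self.sample_id}: ppm readings must be non-negative")
        if self.detection_limit_ppm <= 0:
            raise ValueError("detection limit must be positive")

    def quantifiable_mask(self) -> np.ndarray:
        """True where a reading is at or above the meter's detection limit."""
        return np.asarray(self.ppm) >= self.detection_limit_ppm


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    species: str
    tissue: str
    mass_g: float
    series: ReadingSeries

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError(f"{self.sample_id}: tissue mass must be positive")
        if self.tissue not in TISSUES:
            raise ValueError(f"{self.sample_id}: unknown tissue {self.tissue!r}")


@dataclass(frozen=True)
class ConcentrationResult:
    """Total HCN release for one sample, raw and calibrated."""

    sample_id: str
    total_micromol: float
    micromol_per_g: float
    calibrated_micromol_per_g: float
    n_positive_readings: int
    acyanogenic: bool  # no reading reached the detection limit


@dataclass(frozen=True)
class DurationResult:
    sample_id: str
    weighted_mean_minutes: float
    n_positive_readings: int


@dataclass(frozen=True)
class DepletionResult:
    time_minutes: float  # NaN when not depleted within the series
    depleted: bool
    peak_ppm: float
    peak_time_minutes: float


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    mean: float
    sd: float  # NaN when n == 1
    range: float
    n: int


def total_release(
    record: SampleRecord, calibration: CalibrationFactor | float = CalibrationFactor()
) -> ConcentrationResult:
    """Sum quantifiable readings into total μmol, per-gram and calibrated values.

    Readings below the detection limit are retained in the series but excluded
    from the total: the protocol stops there and the meter cannot quantify
    them.  Each evacuation is accounted as removing the full chamber contents.
    """
    series = record.series
    mask = series.quantifiable_mask()
    n_pos = int(mask.sum())
    total = float(
        sum(ppm_to_micromol(p, series.chamber) for p, m in zip(series.ppm, mask) if m)
    )
    per_g = total / record.mass_g
    factor = calibration.value if isinstance(calibration, CalibrationFactor) else float(calibration)
    return ConcentrationResult(
        sample_id=record.sample_id,
        total_micromol=total,
        micromol_per_g=per_g,
        calibrated_micromol_per_g=per_g * factor,
        n_positive_readings=n_pos,
        acyanogenic=(n_pos == 0),
    )


class UndefinedDurationError(ValueError):
    """Raised when a series has no quantifiable reading to weight."""


def weighted_mean_duration(series: ReadingSeries) -> DurationResult:
    """ppm-weighted mean time since crushing, over quantifiable readings.

    A single positive reading at the first sampling time yields that time
    itself (the statistic's minimum).  Invariant under uniform scaling of ppm.
    """
    mask = series.quantifiable_mask()
    if not mask.any():
        raise UndefinedDurationError(
            f"{series.sample_id}: all readings below the detection limit; duration undefined"
        )
    t = np.asarray(series.times_min)[mask]
    p = np.asarray(series.ppm)[mask]
    return DurationResult(
        sample_id=series.sample_id,
        weighted_mean_minutes=float(np.sum(t * p) / np.sum(p)),
        n_positive_readings=int(mask.sum()),
    )


def classify_kinetics(duration: DurationResult, threshold_minutes: float = 20.0) -> str:
    """Label a sample 'slow' iff its weighted mean duration exceeds the threshold."""
    return "slow" if duration.weighted_mean_minutes > threshold_minutes else "fast"


def depletion_time(series: ReadingSeries, fraction: float = 0.9) -> DepletionResult:
    """Earliest post-peak time at which ppm falls to (1 - fraction) of the peak.

    Linear interpolation between readings; intended for high-frequency
    closed-jar series where the full rise-and-fall kinetics are resolved.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    t = np.asarray(series.times_min)
    p = np.asarray(series.ppm)
    if p.max() <= 0:
        raise ValueError(f"{series.sample_id}: series has no positive peak")
    i_peak = int(np.argmax(p))
    peak = float(p[i_peak])
    threshold = (1.0 - fraction) * peak
    for j in range(i_peak, len(p) - 1):
        if p[j + 1] <= threshold:
            # crossing within (t_j, t_{j+1}]
            if p[j] == p[j + 1]:
                t_cross = t[j + 1]
            else:
                t_cross = t[j] + (p[j] - threshold) / (p[j] - p[j + 1]) * (t[j + 1] - t[j])
            return DepletionResult(float(t_cross), True, peak, float(t[i_peak]))
    if p[i_peak] <= threshold:  # degenerate: flat zero after a zero-fraction ask
        return DepletionResult(float(t[i_peak]), True, peak, float(t[i_peak]))
    return DepletionResult(math.nan, False, peak, float(t[i_peak]))


def species_summary(values_by_species: pd.DataFrame | dict) -> list[SpeciesSummary]:
    """Per-species mean, sample SD, range (max - min) and n.

    Accepts a DataFrame with columns ``species`` and ``value`` or a mapping
    of species → iterable of values.  Order-independent; empty groups are
    skipped.
    """
    if isinstance(values_by_species, dict):
        rows = [
            {"species": sp, "value": v}
            for sp, vals in values_by_species.items()
            for v in vals
        ]
        df = pd.DataFrame(rows, columns=["species", "value"])
    else:
        df = values_by_species[["species", "value"]]
    out: list[SpeciesSummary] = []
    for sp, grp in df.groupby("species", sort=True):
        v = grp["value"].to_numpy(float)
        if v.size == 0:
            continue
        out.append(
            SpeciesSummary(
                species=str(sp),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else math.nan,
                range=float(v.max() - v.min()),
                n=int(v.size),
            )
        )
    return out
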
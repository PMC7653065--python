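"""Domain types, table readers and normalization shared by all modules.

Time convention
---------------
All clock times are decimal hours of "extended local time": a sleep onset
after midnight is recorded on the previous calendar day's axis, e.g. 01:47
is stored as 25.78. Interval parameters are then plain subtractions with no
modular reduction, which is the convention used throughout the screening
arithmetic (25.78 − 6.57 = 19.21 h).

Expression values are quantities of a clock-gene transcript (Per3, Nr1d1,
Nr1d2) normalized against a reference transcript whose expression is
constant over the day (the 18S rRNA role).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Clock genes recognised by default; the first is the anchor phase marker.
DEFAULT_GENES = ("Per3", "Nr1d2", "Nr1d1")

#: PSQI score above which a subject is assigned to the high-PSQI group.
DEFAULT_PSQI_THRESHOLD = 5

EXPRESSION_COLUMNS = {
    "subject": "subject",
    "gene": "gene",
    "time": "time",
    "replicate": "replicate",
    "value": "value",
    "reference": "reference",
}

SLEEP_COLUMNS = {
    "subject": "subject",
    "guw": "GUw",
    "sow": "SOw",
    "guf": "GUf",
    "sof": "SOf",
    "psqi": "PSQI",
    "meq": "MEQ",
}


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass(frozen=True)
class ExpressionMeasurement:
    """One qPCR readout: a raw transcript quantity plus its reference."""

    subject_id: str
    gene: str
    time_h: float
    replicate: int
    value: float
    reference_value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"value must be >= 0, got {self.value}")
        if self.reference_value <= 0:
            raise ValueError(
                f"reference_value must be > 0, got {self.reference_value}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass
class ExpressionSeries:
    """One subject/gene time course holding exactly the points of one fit.

    ``values`` are reference-normalized; after :func:`standardize_series`
    they are additionally centered and scaled (``loc``/``scale`` retain the
    transform so fitted curves can be mapped back to the data scale).
    """

    subject_id: str
    gene: str
    times_h: np.ndarray
    values: np.ndarray
    standardized: bool = False
    loc: float = 0.0
    scale: float = 1.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_h.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.times_h.size)


@dataclass(frozen=True)
class SleepRecord:
    """Questionnaire-style sleep timing in extended decimal hours.

    guw/guf: get-up time on work (school) / free days; sow/sof: sleep onset
    on work / free days, with values > 24 denoting after midnight.
    """

    subject_id: str
    guw: float
    sow: float
    guf: float
    sof: float
    psqi_total: int
    meq_total: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.psqi_total <= 21:
            raise ValueError(f"PSQI total must be in [0, 21], got {self.psqi_total}")
        for onset, getup, tag in ((self.sow, self.guw, "work"), (self.sof, self.guf, "free")):
            dur = sleep_duration(onset, getup)
            if not 0 < dur < 24:
                raise ValueError(
                    f"implied {tag}-day sleep duration {dur:.2f} h outside (0, 24)"
                )


def sleep_duration(onset_h: float, getup_h: float) -> float:
    """Sleep duration with get-up mapped to the morning after onset."""
    getup = getup_h + 24.0 if getup_h < onset_h else getup_h
    return getup - onset_h


def hhmm_to_decimal(text: str) -> float:
    """Convert 'HH:MM' (HH may exceed 24) to decimal hours."""
    hh, mm = text.strip().split(":")
    return int(hh) + int(mm) / 60.0


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def _require_columns(df: pd.DataFrame, colmap: Mapping[str, str], path) -> None:
    for key, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}' ({key})")


@dataclass(frozen=True)
class RowReject:
    """A rejected input row with its 1-based data line number and reason."""

    line: int
    reason: str


def read_expression_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[ExpressionMeasurement], list[RowReject]]:
    """Read a long-format expression CSV/TSV.

    Returns the parsed measurements and a list of row-level rejects (rows
    with non-numeric fields or invariant violations); every reject is also
    logged at WARNING level.
    """
    colmap = dict(EXPRESSION_COLUMNS)
    if columns:
        colmap.update(columns)
    df = _read_table(path)
    _require_columns(df, colmap, path)

    out: list[ExpressionMeasurement] = []
    rejects: list[RowReject] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            m = ExpressionMeasurement(
                subject_id=str(rec[colmap["subject"]]),
                gene=str(rec[colmap["gene"]]),
                time_h=float(rec[colmap["time"]]),
                replicate=int(rec[colmap["replicate"]]),
                value=float(rec[colmap["value"]]),
                reference_value=float(rec[colmap["reference"]]),
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RowReject(line=i, reason=str(exc)))
            log.warning("%s: row %d rejected: %s", path, i, exc)
            continue
        out.append(m)
    return out, rejects


def write_expression_table(
    measurements: Iterable[ExpressionMeasurement], path: str | Path
) -> None:
    df = pd.DataFrame(
        {
            "subject": [m.subject_id for m in measurements],
            "gene": [m.gene for m in measurements],
            "time": [m.time_h for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "value": [m.value for m in measurements],
            "reference": [m.reference_value for m in measurements],
        }
    )
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def read_sleep_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[SleepRecord], list[RowReject]]:
    """Read a sleep-record CSV/TSV (one subject per row)."""
    colmap = dict(SLEEP_COLUMNS)
    if columns:
        colmap.update(columns)
    df = _read_table(path)
    _require_columns(df, colmap, path)

    out: list[SleepRecord] = []
    rejects: list[RowReject] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            meq_raw = rec.get(colmap["meq"])
            r = SleepRecord(
                subject_id=str(rec[colmap["subject"]]),
                guw=float(rec[colmap["guw"]]),
                sow=float(rec[colmap["sow"]]),
                guf=float(rec[colmap["guf"]]),
                sof=float(rec[colmap["sof"]]),
                psqi_total=int(rec[colmap["psqi"]]),
                meq_total=None if pd.isna(meq_raw) else int(meq_raw),
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RowReject(line=i, reason=str(exc)))
            log.warning("%s: row %d rejected: %s", path, i, exc)
            continue
        out.append(r)
    return out, rejects


def write_sleep_table(records: Iterable[SleepRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "GUw": [r.guw for r in records],
            "SOw": [r.sow for r in records],
            "GUf": [r.guf for r in records],
            "SOf": [r.sof for r in records],
            "PSQI": [r.psqi_total for r in records],
            "MEQ": [r.meq_total for r in records],
        }
    )
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Normalization and series assembly
# ---------------------------------------------------------------------------

def normalize_to_reference(m: ExpressionMeasurement) -> float:
    """Expression value divided by its reference-transcript value."""
    if m.reference_value <= 0:
        raise ValueError("reference_value must be > 0")
    return m.value / m.reference_value


def collapse_replicates(values: Sequence[float]) -> tuple[float, int]:
    """Arithmetic mean of replicate values; returns (mean, count)."""
    values = list(values)
    if not values:
        raise ValueError("cannot collapse an empty replicate set")
    return float(np.mean(values)), len(values)


def build_series(
    measurements: Iterable[ExpressionMeasurement],
    subject_id: str,
    gene: str,
    replicate_choice: Mapping[float, int] | None = None,
) -> ExpressionSeries:
    """Assemble one subject/gene series from long-format measurements.

    By default replicates at each time point are collapsed to their mean;
    ``replicate_choice`` maps time -> replicate index to pick exactly one
    replicate per time point (combination-enumeration workflow).
    """
    by_time: dict[float, list[ExpressionMeasurement]] = {}
    for m in measurements:
        if m.subject_id == subject_id and m.gene == gene:
            by_time.setdefault(m.time_h, []).append(m)
    if not by_time:
        raise ValueError(f"no measurements for subject {subject_id!r} gene {gene!r}")
    times = sorted(by_time)
    vals = []
    for t in times:
        ms = by_time[t]
        if replicate_choice is not None:
            wanted = replicate_choice[t]
            picked = [m for m in ms if m.replicate == wanted]
            if not picked:
                raise ValueError(
                    f"replicate {wanted} absent at t={t} for {subject_id}/{gene}"
                )
            vals.append(normalize_to_reference(picked[0]))
        else:
            vals.append(collapse_replicates([normalize_to_reference(m) for m in ms])[0])
    return ExpressionSeries(subject_id=subject_id, gene=gene,
                            times_h=np.array(times), values=np.array(vals))


def standardize_series(s: ExpressionSeries) -> ExpressionSeries:
    """Center to zero mean and scale to unit sample SD (ddof=1), per gene.

    A constant series cannot be scaled: it is returned centered with scale 1
    and flagged ``degenerate``. Idempotent on already-standardized series.
    """
    mu = float(np.mean(s.values))
    sd = float(np.std(s.values, ddof=1)) if s.n_points > 1 else 0.0
    if sd < 1e-12:
        log.warning("constant expression series %s/%s: zero variance",
                    s.subject_id, s.gene)
        return replace(s, values=s.values - mu, standardized=True,
                       loc=mu, scale=1.0, degenerate=True)
    return replace(s, values=(s.values - mu) / sd, standardized=True,
                   loc=mu, scale=sd, degenerate=False)


def assign_group(psqi_total: int, threshold: int = DEFAULT_PSQI_THRESHOLD) -> str:
    """'control' iff PSQI ≤ threshold, else 'high_psqi'."""
    return "control" if psqi_total <= threshold else "high_psqi"
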
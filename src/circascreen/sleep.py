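"""Derived sleep/circadian interval parameters.

All intervals are plain subtractions of extended-hour clock times (sleep
onsets after midnight stored as hours > 24, the circadian peak time in
[0, 24)); no modular reduction is applied, so e.g. SOw − P3PT for a typical
adult lands near 18-19 h.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datamodel import SleepRecord, sleep_duration
from .phasefit import PhaseFitResult

__all__ = ["DerivedParams", "derive_params", "midsleep_and_jetlag"]

#: Interval parameters screened against the control reference band.
BAND_PARAMS = (
    "p3pt",
    "guw_minus_p3pt",
    "sow_minus_p3pt",
    "guf_minus_p3pt",
    "sof_minus_p3pt",
    "guf_minus_guw",
    "sof_minus_sow",
)


@dataclass(frozen=True)
class DerivedParams:
    """Interval parameters for one subject and one phase estimator (2G/3G)."""

    subject_id: str
    estimator_tag: str
    p3pt: float
    guf_minus_guw: float
    sof_minus_sow: float
    guw_minus_p3pt: float
    sow_minus_p3pt: float
    guf_minus_p3pt: float
    sof_minus_p3pt: float
    midsleep_w: float | None = None
    midsleep_f: float | None = None
    social_jetlag: float | None = None


def derive_params(
    s: SleepRecord,
    fit: PhaseFitResult,
    estimator_tag: str = "2G",
    with_midsleep: bool = True,
) -> DerivedParams:
    """All interval parameters from one sleep record and one phase fit."""
    if not 0.0 <= fit.p3pt_h < 24.0:
        raise ValueError("fit.p3pt_h must lie in [0, 24)")
    p = fit.p3pt_h
    ms_w = ms_f = sjl = None
    if with_midsleep:
        ms_w, ms_f, sjl = midsleep_and_jetlag(s)
    return DerivedParams(
        subject_id=s.subject_id,
        estimator_tag=estimator_tag,
        p3pt=p,
        guf_minus_guw=s.guf - s.guw,
        sof_minus_sow=s.sof - s.sow,
        guw_minus_p3pt=s.guw - p,
        sow_minus_p3pt=s.sow - p,
        guf_minus_p3pt=s.guf - p,
        sof_minus_p3pt=s.sof - p,
        midsleep_w=ms_w,
        midsleep_f=ms_f,
        social_jetlag=sjl,
    )


def midsleep_and_jetlag(s: SleepRecord) -> tuple[float, float, float]:
    """Mid-sleep on work and free days and their difference (social jetlag).

    Mid-sleep = (onset + next-morning get-up)/2 on the extended-hour axis;
    social jetlag = midsleep_free − midsleep_work.
    """
    for onset, getup, tag in ((s.sow, s.guw, "work"), (s.sof, s.guf, "free")):
        if not 0 < sleep_duration(onset, getup) < 24:
            raise ValueError(f"non-positive implied {tag}-day sleep duration")
    gu_w = s.guw + 24.0 if s.guw < s.sow else s.guw
    gu_f = s.guf + 24.0 if s.guf < s.sof else s.guf
    ms_w = (s.sow + gu_w) / 2.0
    ms_f = (s.sof + gu_f) / 2.0
    return ms_w, ms_f, ms_f - ms_w
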
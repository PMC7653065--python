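"""Control reference bands and the two-criterion LCRSWD screen.

A candidate for latent circadian rhythm sleep-wake disorder (delayed
circadian-driven sleepiness) must show both

  A. a large work/free-day wake-time gap: GUf − GUw ≥ threshold
     (default 3 h), and
  B. a short interval between circadian phase and work-day get-up:
     GUw − P3PT below the control group's mean − SD (or below a fixed
     ROC-derived cutoff when a preset is selected),

with an exception path: criterion A together with an unreliable phase
estimate (markedly low CD, wide 95% CI, or arrhythmic expression) also
flags a candidate, since severe circadian dysfunction may defeat the phase
estimate itself. Subjects in the advanced tail (GUw − P3PT above
mean + SD) are flagged informationally but never classified as candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_PSQI_THRESHOLD,
    SleepRecord,
    assign_group,
)
from .phasefit import PhaseFitResult
from .sleep import BAND_PARAMS, DerivedParams, derive_params

__all__ = [
    "ControlReference",
    "ScreeningThresholds",
    "ScreeningResult",
    "ChangeReport",
    "assemble_cohort",
    "build_control_reference",
    "screen_subject",
    "screen_cohort",
    "compare_assessments",
]


@dataclass(frozen=True)
class ControlReference:
    """Per-parameter control-group mean and SD defining the 1-SD band."""

    estimator_tag: str
    means: Mapping[str, float]
    sds: Mapping[str, float]
    n_control: int

    def band(self, param: str) -> tuple[float, float]:
        m, s = self.means[param], self.sds[param]
        return (m - s, m + s)


@dataclass(frozen=True)
class ScreeningThresholds:
    """Screen configuration, echoed into every result for auditability.

    criterion_b_cutoff=None uses the control band (mean − SD of
    GUw − P3PT); a number replaces the band with a fixed cutoff, as with
    the ROC-derived presets (0.15 h for the two-gene estimator, 0.16 h for
    the three-gene one).
    """

    guf_guw_min_h: float = 3.0
    criterion_b_cutoff_h: float | None = None
    cd_min: float = 0.95
    ci_width_max_h: float = 4.0

    @classmethod
    def preset(cls, name: str) -> "ScreeningThresholds":
        presets = {
            "band": cls(),
            "roc2g": cls(criterion_b_cutoff_h=0.15),
            "roc3g": cls(criterion_b_cutoff_h=0.16),
        }
        try:
            return presets[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}") from None


@dataclass(frozen=True)
class ScreeningResult:
    """Per-subject criterion values, exception flags and classification."""

    subject_id: str
    estimator_tag: str
    criterion_a_value_h: float
    criterion_a_met: bool
    criterion_b_value_h: float
    criterion_b_cutoff_h: float
    criterion_b_met: bool
    low_cd: bool
    wide_ci: bool
    arrhythmic: bool
    advanced_phase: bool
    is_candidate: bool
    cd: float
    ci_width_h: float | None
    psqi_total: int | None
    thresholds: ScreeningThresholds

    @property
    def exception_flag(self) -> bool:
        return self.low_cd or self.wide_ci or self.arrhythmic


def assemble_cohort(
    sleep_records: Sequence[SleepRecord],
    fits: Mapping[str, PhaseFitResult],
    estimator_tag: str = "2G",
    psqi_threshold: int = DEFAULT_PSQI_THRESHOLD,
) -> pd.DataFrame:
    """Join sleep records with fit results into one tidy cohort table.

    One row per subject with the raw sleep times, PSQI/MEQ totals, group
    label (control iff PSQI ≤ threshold), phase-fit diagnostics and all
    derived interval parameters.
    """
    rows = []
    for s in sleep_records:
        if s.subject_id not in fits:
            continue
        fit = fits[s.subject_id]
        d = derive_params(s, fit, estimator_tag=estimator_tag)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": assign_group(s.psqi_total, psqi_threshold),
                "psqi": s.psqi_total,
                "meq": s.meq_total,
                "guw": s.guw,
                "sow": s.sow,
                "guf": s.guf,
                "sof": s.sof,
                "cd": fit.cd,
                "ci_width_h": fit.ci95_width_h,
                "degenerate": fit.degenerate,
                **{p: getattr(d, p) for p in BAND_PARAMS},
                "social_jetlag": d.social_jetlag,
                "estimator_tag": estimator_tag,
            }
        )
    return pd.DataFrame(rows)


def build_control_reference(
    cohort: pd.DataFrame, estimator_tag: str = "2G"
) -> ControlReference:
    """Sample mean and SD (n−1) of each band parameter over control subjects."""
    ctrl = cohort[cohort["group"] == "control"]
    if len(ctrl) < 2:
        raise ValueError(
            f"need at least 2 control subjects to build a reference, got {len(ctrl)}"
        )
    means, sds = {}, {}
    for p in BAND_PARAMS:
        means[p] = float(ctrl[p].mean())
        sd = float(ctrl[p].std(ddof=1))
        sds[p] = sd
        if sd == 0.0:
            import logging

            logging.getLogger(__name__).warning(
                "degenerate control band for %s: SD is 0", p
            )
    return ControlReference(
        estimator_tag=estimator_tag, means=means, sds=sds, n_control=len(ctrl)
    )


def screen_subject(
    d: DerivedParams,
    fit: PhaseFitResult,
    ref: ControlReference,
    thresholds: ScreeningThresholds | None = None,
) -> ScreeningResult:
    """Apply the two detection criteria and exception flags to one subject."""
    thresholds = thresholds or ScreeningThresholds()
    if d.estimator_tag != ref.estimator_tag:
        raise ValueError(
            f"estimator tag mismatch: params {d.estimator_tag!r} "
            f"vs reference {ref.estimator_tag!r}"
        )
    a_val = d.guf_minus_guw
    a_met = a_val >= thresholds.guf_guw_min_h

    lower, upper = ref.band("guw_minus_p3pt")
    b_cut = (
        thresholds.criterion_b_cutoff_h
        if thresholds.criterion_b_cutoff_h is not None
        else lower
    )
    b_val = d.guw_minus_p3pt
    arrhythmic = fit.degenerate
    b_met = (not arrhythmic) and b_val < b_cut

    low_cd = (not arrhythmic) and fit.cd < thresholds.cd_min
    wide_ci = (
        fit.ci95_width_h is not None and fit.ci95_width_h > thresholds.ci_width_max_h
    )
    advanced = (not arrhythmic) and b_val > upper

    candidate = (a_met and b_met) or (a_met and (low_cd or wide_ci or arrhythmic))
    return ScreeningResult(
        subject_id=d.subject_id,
        estimator_tag=d.estimator_tag,
        criterion_a_value_h=a_val,
        criterion_a_met=a_met,
        criterion_b_value_h=b_val,
        criterion_b_cutoff_h=float(b_cut),
        criterion_b_met=b_met,
        low_cd=low_cd,
        wide_ci=wide_ci,
        arrhythmic=arrhythmic,
        advanced_phase=advanced,
        is_candidate=candidate,
        cd=fit.cd,
        ci_width_h=fit.ci95_width_h,
        psqi_total=None,
        thresholds=thresholds,
    )


def screen_cohort(
    sleep_records: Sequence[SleepRecord],
    fits: Mapping[str, PhaseFitResult],
    ref: ControlReference | None = None,
    thresholds: ScreeningThresholds | None = None,
    estimator_tag: str = "2G",
    psqi_threshold: int = DEFAULT_PSQI_THRESHOLD,
) -> list[ScreeningResult]:
    """Screen every subject; the reference is built from the cohort's
    control subjects (PSQI ≤ threshold) when not supplied."""
    cohort = assemble_cohort(sleep_records, fits, estimator_tag, psqi_threshold)
    if ref is None:
        if (cohort["group"] == "control").sum() < 2:
            raise ValueError(
                "no control reference supplied and fewer than 2 control "
                "subjects (PSQI <= threshold) in the cohort"
            )
        ref = build_control_reference(cohort, estimator_tag)
    out = []
    by_subject = {s.subject_id: s for s in sleep_records}
    for s in sleep_records:
        if s.subject_id not in fits:
            continue
        d = derive_params(s, fits[s.subject_id], estimator_tag=estimator_tag)
        res = screen_subject(d, fits[s.subject_id], ref, thresholds)
        out.append(
            ScreeningResult(**{**asdict(res), "psqi_total": s.psqi_total,
                               "thresholds": res.thresholds})
        )
    return out


@dataclass(frozen=True)
class ChangeReport:
    """Follow-up comparison of two screens of the same subject."""

    subject_id: str
    delta_criterion_a_h: float
    delta_criterion_b_h: float
    delta_psqi: int | None
    band_reentry: bool
    newly_arrhythmic: bool
    status: str  # "improved" | "unchanged" | "deteriorated/arrhythmic"


def compare_assessments(before: ScreeningResult, after: ScreeningResult) -> ChangeReport:
    """Per-criterion deltas and a coarse status for a re-screen.

    "improved": was a candidate, now is not, with the phase-wake interval
    back inside the control band and/or a lower PSQI. "deteriorated/
    arrhythmic": a new exception flag or a new candidate classification.
    """
    if before.subject_id != after.subject_id:
        raise ValueError("assessments belong to different subjects")
    band_reentry = (not after.criterion_b_met) and before.criterion_b_met
    newly_arr = after.arrhythmic and not before.arrhythmic
    d_psqi = (
        after.psqi_total - before.psqi_total
        if after.psqi_total is not None and before.psqi_total is not None
        else None
    )
    if newly_arr or (after.is_candidate and not before.is_candidate):
        status = "deteriorated/arrhythmic"
    elif before.is_candidate and not after.is_candidate and (
        band_reentry or (d_psqi is not None and d_psqi < 0)
    ):
        status = "improved"
    else:
        status = "unchanged"
    return ChangeReport(
        subject_id=before.subject_id,
        delta_criterion_a_h=after.criterion_a_value_h - before.criterion_a_value_h,
        delta_criterion_b_h=after.criterion_b_value_h - before.criterion_b_value_h,
        delta_psqi=d_psqi,
        band_reentry=band_reentry,
        newly_arrhythmic=newly_arr,
        status=status,
    )
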
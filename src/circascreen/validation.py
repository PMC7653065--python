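"""Replicate-combination validation of the phase estimator.

With r independent samples at each of the three collection times, one phase
can be estimated from every combination of one sample per time point
(4 replicates -> 4^3 = 64 combinations). The circular mean of the ensemble
defines the reference ("real") phase; the spread of the per-combination
estimates around it characterizes estimation error, and stratifying the
absolute error by the fit's coefficient of determination shows how CD acts
as a reliability indicator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .circular import circular_diff_hours, circular_mean_hours, circular_sd_hours
from .datamodel import ExpressionMeasurement, build_series, standardize_series
from .phasefit import CosineFitConfig, fit_shared_phase

__all__ = [
    "CombinationEnsemble",
    "enumerate_combinations",
    "circular_mean_phase",
    "circular_error",
    "build_ensemble",
    "error_vs_cd_summary",
    "ErrorCdSummary",
]


def enumerate_combinations(replicate_counts: Sequence[int]) -> list[tuple[int, ...]]:
    """All ways to pick one replicate index (1-based) per time point.

    Deterministic lexicographic order; the list has Π_t counts[t] entries.
    """
    counts = list(replicate_counts)
    if any(c < 1 for c in counts):
        raise ValueError("every time point needs at least one replicate")
    return list(itertools.product(*(range(1, c + 1) for c in counts)))


def circular_mean_phase(phases_h: Iterable[float], period: float = 24.0) -> float:
    """Resultant-vector mean of 24-h phases, in [0, period)."""
    return circular_mean_hours(list(phases_h), period)


def circular_error(estimate_h: float, reference_h: float) -> float:
    """Signed wrapped deviation estimate − reference in (−12, +12]."""
    return float(circular_diff_hours(estimate_h, reference_h))


@dataclass
class CombinationEnsemble:
    """Phase estimates over every replicate combination for one subject."""

    subject_id: str
    combinations: list[tuple[int, ...]]
    phases_h: np.ndarray
    cds: np.ndarray
    real_phase_h: float
    errors_h: np.ndarray
    sd_h: float

    def __len__(self) -> int:
        return len(self.combinations)


def build_ensemble(
    measurements: Iterable[ExpressionMeasurement],
    subject_id: str,
    genes: Sequence[str] = ("Per3", "Nr1d2"),
    cfg: CosineFitConfig | None = None,
    anchor: str = "Per3",
) -> CombinationEnsemble:
    """Fit every replicate combination and summarize the phase ensemble.

    A combination chooses one sample (replicate index) at each time point;
    the chosen sample supplies all genes simultaneously, matching a design
    where each sample is assayed for every transcript.
    """
    cfg = cfg or CosineFitConfig()
    ms = [m for m in measurements if m.subject_id == subject_id and m.gene in genes]
    if not ms:
        raise ValueError(f"no measurements for subject {subject_id!r}")
    times = sorted({m.time_h for m in ms})
    counts = []
    for t in times:
        reps = {m.replicate for m in ms if m.time_h == t}
        counts.append(len(reps))
    combos = enumerate_combinations(counts)

    phases, cds = [], []
    for combo in combos:
        choice = dict(zip(times, combo))
        series = [
            standardize_series(build_series(ms, subject_id, g, replicate_choice=choice))
            for g in genes
        ]
        fit = fit_shared_phase(series, cfg, anchor=anchor)
        phases.append(fit.p3pt_h)
        cds.append(fit.cd)

    phases = np.asarray(phases)
    cds = np.asarray(cds)
    real = circular_mean_phase(phases)
    errors = np.asarray(circular_diff_hours(phases, real))
    return CombinationEnsemble(
        subject_id=subject_id,
        combinations=combos,
        phases_h=phases,
        cds=cds,
        real_phase_h=real,
        errors_h=np.atleast_1d(errors),
        sd_h=circular_sd_hours(phases),
    )


@dataclass
class ErrorCdSummary:
    """Mean |error| and counts in the high/low-CD strata of an ensemble."""

    cd_threshold: float
    n_high: int
    n_low: int
    mean_abs_error_high_h: float | None
    mean_abs_error_low_h: float | None


def error_vs_cd_summary(
    ensembles: CombinationEnsemble | Sequence[CombinationEnsemble],
    cd_threshold: float = 0.95,
) -> ErrorCdSummary:
    """Pool combinations across ensembles and stratify |error| by CD.

    An empty stratum reports count 0 and an undefined (None) mean.
    """
    if isinstance(ensembles, CombinationEnsemble):
        ensembles = [ensembles]
    if not ensembles:
        raise ValueError("need at least one ensemble")
    errs = np.concatenate([e.errors_h for e in ensembles])
    cds = np.concatenate([e.cds for e in ensembles])
    hi = cds >= cd_threshold
    n_hi, n_lo = int(hi.sum()), int((~hi).sum())
    return ErrorCdSummary(
        cd_threshold=cd_threshold,
        n_high=n_hi,
        n_low=n_lo,
        mean_abs_error_high_h=float(np.abs(errs[hi]).mean()) if n_hi else None,
        mean_abs_error_low_h=float(np.abs(errs[~hi]).mean()) if n_lo else None,
    )
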
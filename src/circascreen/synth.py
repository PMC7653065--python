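"""Synthetic cohort generator.

Emulates the data-generating structure the screen assumes: each subject has
a circadian phase (the clock time of peak Per3 expression); clock-gene
expression follows a 24-h cosine around that phase, with the Rev-erb genes
(Nr1d1/Nr1d2) peaking about 2 h earlier than Per3; hair samples are taken
at three times (~8 h apart, anchored to wake time) with additive noise; and
sleep timing is coupled to phase. Control subjects wake near the social
schedule with their phase aligned to it, while case subjects (latent
circadian misalignment) carry a delayed phase but a socially fixed work-day
wake time, so their free-day wake time drifts late with their phase — the
work/free wake gap (GUf − GUw) grows while the phase-to-wake interval
(GUw − P3PT) shrinks below the control band.

Defaults echo the control-group sleep pattern of a typical young-adult
cohort (GUw ≈ 8, SOw ≈ 24.5, GUf ≈ phase + 2.76, P3PT ≈ 6.4) without
claiming to match any observed cohort numerically. Everything is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .datamodel import ExpressionMeasurement, SleepRecord

__all__ = ["SimulationConfig", "generate_cohort", "make_fig2_style_dataset"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Noise is additive Gaussian on the standardized (unit-amplitude) scale,
    so noise_sd is directly interpretable against the cosine amplitude.
    gene_offsets_h give how many hours each gene peaks *before* the anchor
    (Per3), matching the fitted phase-offset constraint.
    """

    n_control: int = 24
    n_case: int = 23
    phase_mean_control_h: float = 6.4
    case_phase_delay_h: float = 4.0
    phase_sd_h: float = 1.0
    gene_offsets_h: Mapping[str, float] = field(
        default_factory=lambda: {"Per3": 0.0, "Nr1d2": 2.0, "Nr1d1": 2.0}
    )
    amplitude: float = 1.0
    baseline: float = 2.0
    noise_sd: float = 0.2
    sampling_offsets_h: tuple[float, ...] = (0.0, 8.0, 16.0)
    replicates: int = 1
    social_wake_h: float = 8.0
    guw_sd_h: float = 0.4
    free_offset_h: float = 2.76
    guf_sd_h: float = 0.4
    sleep_duration_work_h: float = 7.5
    sleep_duration_free_h: float = 8.1
    duration_sd_h: float = 0.3
    reference_value: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phase_sd_h", "noise_sd", "guw_sd_h", "guf_sd_h", "duration_sd_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_control < 0 or self.n_case < 0:
            raise ValueError("subject counts must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _expression_for_subject(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    subject_id: str,
    phase_h: float,
    wake_h: float,
) -> list[ExpressionMeasurement]:
    omega = 2.0 * np.pi / 24.0
    out = []
    times = [wake_h + dt for dt in cfg.sampling_offsets_h]
    for gene, off in cfg.gene_offsets_h.items():
        peak = phase_h - off  # earlier peak for the Rev-erb genes
        for t in times:
            for r in range(1, cfg.replicates + 1):
                clean = cfg.baseline + cfg.amplitude * np.cos(omega * (t - peak))
                val = clean + rng.normal(0.0, cfg.noise_sd * cfg.amplitude)
                out.append(
                    ExpressionMeasurement(
                        subject_id=subject_id,
                        gene=gene,
                        time_h=float(t),
                        replicate=r,
                        value=float(max(val, 0.0)),
                        reference_value=cfg.reference_value,
                    )
                )
    return out


def generate_cohort(
    cfg: SimulationConfig | None = None, seed: int | np.random.Generator | None = None
) -> tuple[list[ExpressionMeasurement], list[SleepRecord], dict[str, float]]:
    """Generate expression measurements, sleep records and ground truth.

    Returns (measurements, sleep_records, true_phase_by_subject) where the
    true phase is the clock time at which the subject's Per3 expression
    peaks (the cosine argmax). Zero subjects yield empty tables.
    """
    cfg = cfg or SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    measurements: list[ExpressionMeasurement] = []
    records: list[SleepRecord] = []
    truth: dict[str, float] = {}

    groups = [("ctrl", cfg.n_control, 0.0), ("case", cfg.n_case, cfg.case_phase_delay_h)]
    for prefix, n, delay in groups:
        for i in range(1, n + 1):
            sid = f"{prefix}{i:03d}"
            phase = rng.normal(cfg.phase_mean_control_h + delay, cfg.phase_sd_h)
            guw = cfg.social_wake_h + rng.normal(0.0, cfg.guw_sd_h)
            guf = phase + cfg.free_offset_h + rng.normal(0.0, cfg.guf_sd_h)
            dur_w = np.clip(
                cfg.sleep_duration_work_h + rng.normal(0.0, cfg.duration_sd_h), 4.0, 12.0
            )
            dur_f = np.clip(
                cfg.sleep_duration_free_h + rng.normal(0.0, cfg.duration_sd_h), 4.0, 12.0
            )
            sow = guw + 24.0 - dur_w
            sof = guf + 24.0 - dur_f
            psqi = int(rng.integers(1, 6)) if prefix == "ctrl" else int(rng.integers(6, 16))
            meq = int(np.clip(rng.normal(54 if prefix == "ctrl" else 42, 8), 16, 86))
            records.append(
                SleepRecord(
                    subject_id=sid, guw=float(guw), sow=float(sow),
                    guf=float(guf), sof=float(sof), psqi_total=psqi, meq_total=meq,
                )
            )
            truth[sid] = float(phase % 24.0)
            measurements.extend(
                _expression_for_subject(cfg, rng, sid, phase, guw)
            )
    return measurements, records, truth


def make_fig2_style_dataset(
    cfg: SimulationConfig | None = None,
    seed: int | np.random.Generator | None = None,
    n_subjects: int = 4,
) -> tuple[list[ExpressionMeasurement], dict[str, float]]:
    """Replicated expression table for the combination-validation workflow.

    Defaults to 4 replicates at each of 3 time points for 4 subjects, so
    each subject yields a 64-combination phase ensemble downstream.
    """
    cfg = cfg or SimulationConfig(replicates=4)
    if cfg.replicates < 2:
        raise ValueError("validation design needs >= 2 replicates per time point")
    cfg = replace(cfg, n_control=n_subjects, n_case=0)
    measurements, _, truth = generate_cohort(cfg, seed)
    return measurements, truth
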
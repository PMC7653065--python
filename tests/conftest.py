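import numpy as np
import pytest

from circascreen import (
    CosineFitConfig,
    ExpressionSeries,
    standardize_series,
)

OMEGA = 2.0 * np.pi / 24.0


def cosine_series(
    gene: str,
    peak_h: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    subject: str = "s1",
) -> ExpressionSeries:
    """Raw series whose expression peaks at peak_h (cosine argmax)."""
    v = np.cos(OMEGA * (times - peak_h))
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=times.shape)
    return ExpressionSeries(subject_id=subject, gene=gene, times_h=times, values=v)


def two_gene_pair(
    peak_h: float,
    offset_h: float = 2.0,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Standardized Per3/Nr1d2 pair; the second gene peaks offset_h earlier."""
    if times is None:
        times = np.array([0.0, 8.0, 16.0])
    return [
        standardize_series(cosine_series("Per3", peak_h, times, noise_sd, rng)),
        standardize_series(cosine_series("Nr1d2", peak_h - offset_h, times, noise_sd, rng)),
    ]


@pytest.fixture
def argmax_cfg() -> CosineFitConfig:
    """Fit config whose reported peak equals the generating cosine argmax."""
    return CosineFitConfig(convention="curve-argmax")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
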
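"""Amplitude damping from enamel maturation and drill-sampling geometry.

Enamel does not mineralize instantaneously: a stretch of crown of length
``maturation_length`` matures simultaneously, so each point of enamel
averages the isotopic input over that stretch.  Drilling a strip of height
``sample_length`` along the growth axis averages again.  Both act as
uniform moving-average windows on the recorded sinusoid, so a seasonal
cycle of wavelength λ is recorded with its amplitude attenuated by

    f = |sinc(maturation_length / λ)| · |sinc(sample_length / λ)|,

with sinc(u) = sin(πu)/(πu).  The measured amplitude must therefore be
divided by ``f`` before converting extremes to temperatures; the mean
annual level is unaffected (uniform averaging preserves the mean of a
sinusoid).  The factor computation sits behind :func:`damping_factor` so a
different published attenuation geometry (e.g. taxon-specific appositional
angle terms) can be substituted via configuration without touching the
correction step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seasonal import SeasonalEstimate, SinusoidFit

__all__ = [
    "DampingError",
    "ResolutionError",
    "DampingModel",
    "damping_factor",
    "forward_convolve",
    "correct_extremes",
]


class DampingError(ValueError):
    """Averaging windows too wide relative to λ for a reliable correction."""


class ResolutionError(ValueError):
    """Signal sampled too coarsely for the forward convolution."""


@dataclass(frozen=True)
class DampingModel:
    """Averaging-window geometry and the resulting attenuation factor.

    maturation_length : mm of enamel maturing simultaneously (0 disables).
    sample_length : height of the drilled strip along the growth axis, mm.
    lam : annual-cycle wavelength along the growth axis, mm.
    f : amplitude attenuation factor in (0, 1].
    """

    maturation_length: float
    sample_length: float
    lam: float
    f: float

    def __post_init__(self) -> None:
        if self.maturation_length < 0:
            raise ValueError("maturation_length must be >= 0")
        if self.sample_length <= 0:
            raise ValueError("sample_length must be > 0")
        if not (0 < self.f <= 1):
            raise ValueError("f must be in (0, 1]")

    @classmethod
    def from_geometry(cls, maturation_length: float, sample_length: float, lam: float) -> "DampingModel":
        return cls(
            maturation_length=maturation_length,
            sample_length=sample_length,
            lam=lam,
            f=damping_factor(maturation_length, sample_length, lam),
        )


def damping_factor(maturation_length: float, sample_length: float, lam: float) -> float:
    """Amplitude attenuation of a sinusoid under two uniform averaging windows.

    Returns ``|sinc(m/λ)|·|sinc(s/λ)|`` (numpy's normalized sinc).  Raises
    :class:`DampingError` when the combined window reaches one wavelength,
    where the response crosses its first zero and the correction becomes
    unreliable.
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if maturation_length < 0 or sample_length < 0:
        raise ValueError("window lengths must be >= 0")
    if maturation_length + sample_length >= lam:
        raise DampingError(
            f"combined averaging window {maturation_length + sample_length} mm >= "
            f"wavelength {lam} mm: amplitude correction unreliable"
        )
    return float(abs(np.sinc(maturation_length / lam)) * abs(np.sinc(sample_length / lam)))


def _moving_average(y: np.ndarray, width: float, dx: float) -> np.ndarray:
    """Uniform moving average of physical width ``width`` on a regular grid."""
    n = int(round(width / dx))
    if n <= 1:
        return y
    kernel = np.ones(n) / n
    # reflect-pad so edge effects do not bias the interior amplitude
    pad = n
    ypad = np.concatenate([y[pad:0:-1], y, y[-2 : -pad - 2 : -1]])
    out = np.convolve(ypad, kernel, mode="same")
    return out[pad : pad + y.size]


def forward_convolve(positions, values, model: DampingModel) -> np.ndarray:
    """Apply the maturation and sampling averaging windows to a dense signal.

    Requires a regular grid with at least 50 points per cycle.  On a dense
    sinusoid the output/input amplitude ratio equals ``model.f`` up to
    discretization error.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValueError("positions and values length mismatch")
    dx = np.diff(x)
    if dx.size == 0 or not np.allclose(dx, dx[0], rtol=1e-6):
        raise ValueError("forward_convolve requires a regular grid")
    step = float(dx[0])
    if step > model.lam / 50.0:
        raise ResolutionError(
            f"grid step {step} mm too coarse for lam={model.lam} mm (need >= 50 points/cycle)"
        )
    out = _moving_average(y, model.maturation_length, step)
    out = _moving_average(out, model.sample_length, step)
    return out


def correct_extremes(
    est: SeasonalEstimate,
    fit: SinusoidFit,
    model: DampingModel,
    min_f: float = 0.3,
) -> SeasonalEstimate:
    """Undo amplitude damping on extracted extremes.

    The recorded amplitude is divided by ``model.f`` and the extremes are
    re-centred on the (damping-invariant) mean annual value:
    peak' = mean + A/f, trough' = mean − A/f.  Partial series anchor on the
    fitted mean level ``fit.M`` instead.  Corrections with f below ``min_f``
    are refused because dividing by a small factor amplifies noise.
    """
    if model.f < min_f:
        raise DampingError(
            f"damping factor {model.f:.3f} below reliability floor {min_f}: refusing correction"
        )
    peak, trough = est.summer_peak, est.winter_trough
    if peak is not None and trough is not None:
        mean = (peak + trough) / 2.0
        amp = (peak - trough) / 2.0 / model.f
        peak, trough = mean + amp, mean - amp
        mean_annual, seasonality = mean, 2.0 * amp
    elif peak is not None:
        peak = fit.M + (peak - fit.M) / model.f
        mean_annual = seasonality = None
    elif trough is not None:
        trough = fit.M + (trough - fit.M) / model.f
        mean_annual = seasonality = None
    else:
        mean_annual = seasonality = None
    return SeasonalEstimate(
        tooth_id=est.tooth_id,
        layer_id=est.layer_id,
        summer_peak=peak,
        winter_trough=trough,
        mean_annual=mean_annual,
        seasonality=seasonality,
        completeness=est.completeness,
        method=est.method,
    )
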
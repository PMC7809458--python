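"""Sinusoidal seasonal model for intra-tooth δ18O series.

A tooth records roughly one to two annual cycles of drinking-water δ18O as
an approximately sinusoidal signal along its growth axis:

    δ(x) = M + A · sin(2π x / λ + φ)

with mean level ``M`` (‰), seasonal amplitude ``A`` (‰), wavelength ``λ``
(mm of enamel per annual cycle) and phase ``φ`` (birth season).  The model
is fitted by nonlinear least squares; because the problem is linear in
``(M, A·cosφ, A·sinφ)`` for fixed λ, initialization scans a wavelength grid
with exact linear solves before the joint refinement, which makes the fit
robust without user-supplied starting values.

Summer-peak and winter-trough extraction replaces the field's traditional
visual curve reading with two reproducible methods: ``"fitted"`` (model
extrema M ± A) and ``"observed"`` (most extreme measured sample near a
fitted extremum; the default, since visual picking tracks measured extreme
samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .io import ToothSeries

__all__ = [
    "SinusoidRegressor",
    "SinusoidFit",
    "SeasonalEstimate",
    "InsufficientDataError",
    "DegenerateSeriesError",
    "fit_sinusoid",
    "classify_series",
    "extract_extremes",
]

TWO_PI = 2.0 * math.pi


class InsufficientDataError(ValueError):
    """Fewer samples than the sinusoid model can be fitted to."""


class DegenerateSeriesError(ValueError):
    """The series has no positional spread (all samples at one position)."""


@dataclass(frozen=True)
class SinusoidFit:
    """Fitted seasonal sinusoid: δ(x) = M + A·sin(2πx/λ + φ).

    ``A_span`` is the amplitude the fitted curve expresses inside the
    sampled span (half its within-span peak-to-peak).  It equals ``A``
    whenever the span covers a full cycle, but stays honest for partial
    series where the model amplitude is an extrapolation.
    """

    A: float  # amplitude, permil; >= 0
    M: float  # series mean level, permil
    lam: float  # wavelength of one annual cycle along the growth axis, mm
    phi: float  # phase in [0, 2*pi)
    resid_sd: float  # residual standard deviation, permil
    converged: bool
    A_span: float = float("nan")

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.M + self.A * np.sin(TWO_PI * x / self.lam + self.phi)


@dataclass
class SeasonalEstimate:
    """Per-tooth summer peak, winter trough and mean-annual δ18O (‰).

    ``mean_annual`` is the average of peak and trough, analogous to how a
    modern mean annual temperature is formed from monthly extremes;
    ``seasonality`` is peak − trough.  ``completeness`` records which
    extremes the sampled span actually covers (``both_extremes``,
    ``peak_only``, ``trough_only`` or ``none``).
    """

    tooth_id: str
    layer_id: str
    summer_peak: float | None
    winter_trough: float | None
    mean_annual: float | None
    seasonality: float | None
    completeness: str
    method: str = "observed"

    def __post_init__(self) -> None:
        if self.summer_peak is not None and self.winter_trough is not None:
            if self.summer_peak < self.winter_trough:
                raise ValueError("summer_peak must be >= winter_trough")


class SinusoidRegressor(BaseEstimator, RegressorMixin):
    """Least-squares sinusoid fit ``y = M + A·sin(2πx/λ + φ)``.

    Parameters
    ----------
    wavelength : float or None
        Fix λ (mm) instead of estimating it.
    min_wavelength_frac, max_wavelength_frac : float
        Bounds of the λ search grid as fractions of the sampled span.
    n_wavelengths : int
        Size of the initialization grid over λ.
    amplitude_snr : float
        ``converged_`` additionally requires A > 0 and a finite fit; the
        signal/noise classification itself lives in :func:`classify_series`
        with this default threshold.

    Attributes
    ----------
    amplitude_, offset_, wavelength_, phase_ : float
        Estimated A (>= 0), M, λ (> 0) and φ in [0, 2π).
    resid_sd_ : float
        Residual standard deviation.
    converged_ : bool
        False when the optimizer failed or the series is degenerate
        (e.g. constant δ18O).
    """

    def __init__(
        self,
        wavelength: float | None = None,
        min_wavelength_frac: float = 0.5,
        max_wavelength_frac: float = 4.0,
        n_wavelengths: int = 120,
        amplitude_snr: float = 2.0,
    ):
        self.wavelength = wavelength
        self.min_wavelength_frac = min_wavelength_frac
        self.max_wavelength_frac = max_wavelength_frac
        self.n_wavelengths = n_wavelengths
        self.amplitude_snr = amplitude_snr

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _validate_xy(X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("X must be a single positional feature")
            X = X[:, 0]
        y = np.asarray(y, dtype=float)
        if X.shape != y.shape:
            raise ValueError("X and y length mismatch")
        if X.size < 5:
            raise InsufficientDataError(
                f"sinusoid fit needs >= 5 samples, got {X.size}"
            )
        if np.ptp(X) <= 0:
            raise DegenerateSeriesError("zero positional spread")
        return X, y

    @staticmethod
    def _linear_fit(x, y, lam):
        """Exact LS for (M, B, C) in y = M + B sin(2πx/λ) + C cos(2πx/λ)."""
        w = TWO_PI * x / lam
        design = np.column_stack([np.ones_like(x), np.sin(w), np.cos(w)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        return coef, float(resid @ resid)

    def fit(self, X, y):
        x, y = self._validate_xy(X, y)
        self.n_features_in_ = 1
        span = float(np.ptp(x))

        if np.ptp(y) == 0.0:
            # constant series: amplitude indistinguishable from zero
            self.amplitude_ = 0.0
            self.offset_ = float(y[0])
            self.wavelength_ = self.wavelength or span
            self.phase_ = 0.0
            self.resid_sd_ = 0.0
            self.converged_ = False
            self.effective_amplitude_ = 0.0
            return self

        if self.wavelength is not None:
            lam_grid = np.array([float(self.wavelength)])
        else:
            lam_grid = np.geomspace(
                self.min_wavelength_frac * span,
                self.max_wavelength_frac * span,
                self.n_wavelengths,
            )

        best = None
        for lam in lam_grid:
            coef, ssr = self._linear_fit(x, y, lam)
            if best is None or ssr < best[2]:
                best = (lam, coef, ssr)
        lam0, (m0, b0, c0), _ = best

        def residuals(theta):
            m, b, c, lam = theta
            w = TWO_PI * x / lam
            return m + b * np.sin(w) + c * np.cos(w) - y

        lam_lo = min(lam0, 0.25 * span)
        lam_hi = max(lam0 * 1.001, self.max_wavelength_frac * span)
        try:
            sol = least_squares(
                residuals,
                x0=[m0, b0, c0, lam0 if self.wavelength is None else float(self.wavelength)],
                bounds=([-np.inf, -np.inf, -np.inf, lam_lo * 0.5], [np.inf, np.inf, np.inf, lam_hi]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            ) if self.wavelength is None else None
            if sol is not None and sol.success:
                m, b, c, lam = sol.x
                resid = sol.fun
                ok = True
            else:
                m, b, c, lam = m0, b0, c0, lam0
                resid = residuals([m, b, c, lam])
                ok = self.wavelength is not None
        except Exception:  # optimizer blow-up: fall back to grid solution
            m, b, c, lam = m0, b0, c0, lam0
            resid = residuals([m, b, c, lam])
            ok = False

        amp = float(math.hypot(b, c))
        phi = float(math.atan2(c, b)) % TWO_PI
        dof = max(x.size - 4, 1)
        self.amplitude_ = amp
        self.offset_ = float(m)
        self.wavelength_ = float(lam)
        self.phase_ = phi
        self.resid_sd_ = float(math.sqrt(float(resid @ resid) / dof))
        self.converged_ = bool(ok and np.isfinite([amp, m, lam, phi]).all() and amp > 0)
        dense = np.linspace(x.min(), x.max(), 512)
        curve = m + amp * np.sin(TWO_PI * dense / lam + phi)
        self.effective_amplitude_ = float(np.ptp(curve) / 2.0)
        return self

    def predict(self, X):
        check_is_fitted(self, "amplitude_")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self.offset_ + self.amplitude_ * np.sin(
            TWO_PI * x / self.wavelength_ + self.phase_
        )

    def to_fit(self) -> SinusoidFit:
        check_is_fitted(self, "amplitude_")
        return SinusoidFit(
            A=self.amplitude_,
            M=self.offset_,
            lam=self.wavelength_,
            phi=self.phase_,
            resid_sd=self.resid_sd_,
            converged=self.converged_,
            A_span=self.effective_amplitude_,
        )


def fit_sinusoid(series: ToothSeries, init: dict | None = None) -> SinusoidFit:
    """Fit the seasonal sinusoid to one intra-tooth series.

    ``init`` may fix ``{"wavelength": λ}``; otherwise λ is estimated from a
    wavelength-grid scan followed by joint nonlinear refinement.
    """
    kwargs = {}
    if init and "wavelength" in init:
        kwargs["wavelength"] = init["wavelength"]
    est = SinusoidRegressor(**kwargs)
    est.fit(series.positions.reshape(-1, 1), series.values)
    return est.to_fit()


def classify_series(fit: SinusoidFit, series: ToothSeries, k: float = 2.0) -> str:
    """Label a series ``"sinusoidal"`` or ``"non_sinusoidal"``.

    A series is non-sinusoidal when the fit failed or the fitted amplitude is
    not distinguishable from residual noise (amplitude < k·resid_sd,
    default k=2) — the reproducible analogue of judging whether a clear
    seasonal cycle is visible.  The within-span amplitude ``A_span`` is
    used when available so that a long-wavelength trend fitted through a
    flat noisy series (large extrapolated A, little movement inside the
    sampled span) is still rejected.  Non-sinusoidal series are excluded
    from downstream seasonal analyses.
    """
    if not fit.converged:
        return "non_sinusoidal"
    amp = fit.A_span if math.isfinite(fit.A_span) else fit.A
    if amp < k * fit.resid_sd:
        return "non_sinusoidal"
    return "sinusoidal"


def _extreme_positions(fit: SinusoidFit, x_lo: float, x_hi: float, kind: str) -> np.ndarray:
    """Positions in [x_lo, x_hi] where the fitted curve attains its peak/trough."""
    # sin(2πx/λ + φ) = ±1  =>  x = λ/(2π) · (±π/2 − φ + 2πk)
    target = math.pi / 2 if kind == "peak" else -math.pi / 2
    k_lo = math.floor((TWO_PI * x_lo / fit.lam + fit.phi - target) / TWO_PI) - 1
    k_hi = math.ceil((TWO_PI * x_hi / fit.lam + fit.phi - target) / TWO_PI) + 1
    ks = np.arange(k_lo, k_hi + 1)
    xs = (target - fit.phi + TWO_PI * ks) * fit.lam / TWO_PI
    return xs[(xs >= x_lo) & (xs <= x_hi)]


def extract_extremes(
    series: ToothSeries,
    fit: SinusoidFit,
    method: str = "observed",
    edge_frac: float = 0.125,
) -> SeasonalEstimate:
    """Extract summer-peak / winter-trough / mean-annual δ18O from one tooth.

    An extreme is reported only when the fitted curve attains it inside the
    sampled span (with a tolerance of ``edge_frac``·λ beyond each end, since
    a peak sitting just off the outermost sample is still constrained by the
    data).  ``method="fitted"`` reports the model extrema M ± A;
    ``method="observed"`` reports the most extreme measured sample within
    λ/4 of a fitted extremum position.  Series spanning several cycles
    contribute their single most extreme peak and trough.  When both
    extremes exist, ``mean_annual = (peak + trough)/2``.
    """
    if method not in ("fitted", "observed"):
        raise ValueError(f"unknown extraction method {method!r}")
    x = series.positions
    y = series.values
    margin = edge_frac * fit.lam
    peak_xs = _extreme_positions(fit, x[0] - margin, x[-1] + margin, "peak")
    trough_xs = _extreme_positions(fit, x[0] - margin, x[-1] + margin, "trough")

    def observed_extreme(xs: np.ndarray, kind: str) -> float | None:
        if xs.size == 0:
            return None
        window = fit.lam / 4.0
        mask = np.zeros_like(x, dtype=bool)
        for xe in xs:
            mask |= np.abs(x - xe) <= window
        if not mask.any():
            return None
        return float(y[mask].max() if kind == "peak" else y[mask].min())

    if method == "fitted":
        peak = fit.M + fit.A if peak_xs.size else None
        trough = fit.M - fit.A if trough_xs.size else None
    else:
        peak = observed_extreme(peak_xs, "peak")
        trough = observed_extreme(trough_xs, "trough")

    if peak is not None and trough is not None:
        completeness = "both_extremes"
        mean_annual = (peak + trough) / 2.0
        seasonality = peak - trough
    elif peak is not None:
        completeness, mean_annual, seasonality = "peak_only", None, None
    elif trough is not None:
        completeness, mean_annual, seasonality = "trough_only", None, None
    else:
        completeness, mean_annual, seasonality = "none", None, None

    return SeasonalEstimate(
        tooth_id=series.tooth_id,
        layer_id=series.layer_id,
        summer_peak=peak,
        winter_trough=trough,
        mean_annual=mean_annual,
        seasonality=seasonality,
        completeness=completeness,
        method=method,
    )
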
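"""Isotope–temperature transfer functions with Monte-Carlo compound error.

Temperature reconstruction chains two affine calibrations:

1. enamel phosphate δ18O → drinking-water δ18O:  δw = a1·δp + b1
2. drinking-water (≈ precipitation) δ18O → air temperature:  T = a2·δw + b2

Stage-1 calibrations are usually published in the opposite direction
(δp = c·δw + d); :meth:`TransferCalibration.from_water_to_phosphate`
inverts them exactly.  Coefficients are never hard-coded: they are loaded
from a YAML calibration file (see ``TransferCalibration.from_yaml``) whose
shipped template documents the fields; tests and simulations use synthetic
coefficients of field-plausible magnitude.

Compound error — the total uncertainty of a reconstructed temperature —
is propagated by Monte Carlo: each draw jointly perturbs the input δ18O
(measurement + fit uncertainty), the calibration coefficients (their
standard errors, with slope–intercept covariance when provided) and adds
the calibrations' residual scatter.  The half-width of the resulting
temperature distribution (1 sd by default) is reported.  For a pure affine
map with only input noise σ this reduces to |a|·σ, which serves as the
analytic cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .seasonal import SeasonalEstimate

__all__ = [
    "CalibrationError",
    "TransferCalibration",
    "TemperatureEstimate",
    "enamel_to_water",
    "water_to_temperature",
    "reconstruct_temperature",
    "compound_error_mc",
]


class CalibrationError(ValueError):
    """Missing or degenerate calibration coefficients."""


@dataclass(frozen=True)
class TransferCalibration:
    """Affine coefficient sets for both transfer stages, with uncertainties.

    ``a1, b1`` map enamel-phosphate δ18O to drinking-water δ18O (‰ → ‰);
    ``a2, b2`` map drinking-water δ18O to air temperature (°C per ‰, °C).
    ``se_*`` are coefficient standard errors, ``resid_se*`` the residual
    standard errors of each regression, and ``cov*`` optional
    slope–intercept covariances.
    """

    a1: float
    b1: float
    a2: float
    b2: float
    se_a1: float = 0.0
    se_b1: float = 0.0
    se_a2: float = 0.0
    se_b2: float = 0.0
    resid_se1: float = 0.0
    resid_se2: float = 0.0
    cov1: float = 0.0
    cov2: float = 0.0
    seasonal_a2: dict = field(default_factory=dict)  # optional {'warm': (a, b), 'cold': (a, b)}

    def __post_init__(self) -> None:
        if self.a1 == 0 or self.a2 == 0:
            raise CalibrationError("calibration slopes must be non-zero")
        for name in ("se_a1", "se_b1", "se_a2", "se_b2", "resid_se1", "resid_se2"):
            if getattr(self, name) < 0:
                raise CalibrationError(f"{name} must be >= 0")

    @classmethod
    def from_water_to_phosphate(
        cls, c: float, d: float, *, a2: float, b2: float, **kw
    ) -> "TransferCalibration":
        """Build from a stage-1 calibration published as δp = c·δw + d.

        The map is inverted exactly: δw = (δp − d)/c, i.e. a1 = 1/c,
        b1 = −d/c.
        """
        if c == 0:
            raise CalibrationError("published slope c must be non-zero")
        return cls(a1=1.0 / c, b1=-d / c, a2=a2, b2=b2, **kw)

    @classmethod
    def from_yaml(cls, path) -> "TransferCalibration":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None or "stage1" not in raw or "stage2" not in raw:
            raise CalibrationError(f"{path}: calibration file needs 'stage1' and 'stage2' blocks")
        s1, s2 = raw["stage1"], raw["stage2"]
        common = dict(
            a2=float(s2["slope"]),
            b2=float(s2["intercept"]),
            se_a2=float(s2.get("se_slope", 0.0)),
            se_b2=float(s2.get("se_intercept", 0.0)),
            resid_se2=float(s2.get("resid_se", 0.0)),
            cov2=float(s2.get("cov_slope_intercept", 0.0)),
        )
        se1 = dict(
            se_a1=float(s1.get("se_slope", 0.0)),
            se_b1=float(s1.get("se_intercept", 0.0)),
            resid_se1=float(s1.get("resid_se", 0.0)),
            cov1=float(s1.get("cov_slope_intercept", 0.0)),
        )
        direction = s1.get("direction", "phosphate_to_water")
        if direction == "water_to_phosphate":
            # coefficient uncertainties refer to the published direction and
            # cannot be inverted exactly; carried through as-is on the
            # inverted slope/intercept scale via first-order rescaling
            c, d = float(s1["slope"]), float(s1["intercept"])
            cal = cls.from_water_to_phosphate(c, d, **common)
            scale = 1.0 / abs(c)
            return cls(
                a1=cal.a1,
                b1=cal.b1,
                se_a1=se1["se_a1"] * scale**2,
                se_b1=(se1["se_b1"] + abs(d) * se1["se_a1"] * scale) * scale,
                resid_se1=se1["resid_se1"] * scale,
                cov1=se1["cov1"] * scale**3,
                **common,
            )
        return cls(
            a1=float(s1["slope"]),
            b1=float(s1["intercept"]),
            **se1,
            **common,
        )

    def stage2_coefficients(self, season: str = "annual") -> tuple[float, float]:
        if season in ("warm_extreme", "cold_extreme"):
            key = "warm" if season == "warm_extreme" else "cold"
            if key in self.seasonal_a2:
                a, b = self.seasonal_a2[key]
                return float(a), float(b)
        elif season != "annual":
            raise ValueError(f"unknown season {season!r}")
        return self.a2, self.b2


@dataclass(frozen=True)
class TemperatureEstimate:
    """Reconstructed warmest-month, coldest-month and mean annual temperature (°C)."""

    label: str
    T_warmest_month: float
    T_coldest_month: float
    MAT: float
    err_warm: float = 0.0
    err_cold: float = 0.0
    err_mat: float = 0.0
    n_mc: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.T_warmest_month < self.T_coldest_month:
            raise ValueError("T_warmest_month must be >= T_coldest_month")
        if not (self.T_coldest_month <= self.MAT <= self.T_warmest_month):
            raise ValueError("MAT must lie between the seasonal extremes")
        for e in (self.err_warm, self.err_cold, self.err_mat):
            if e < 0:
                raise ValueError("compound errors must be >= 0")


def enamel_to_water(d18Op, cal: TransferCalibration):
    """Map enamel-phosphate δ18O (‰ VSMOW) to drinking-water δ18O (‰ VSMOW)."""
    out = cal.a1 * np.asarray(d18Op, dtype=float) + cal.b1
    return float(out) if out.ndim == 0 else out


def water_to_temperature(d18Odw, cal: TransferCalibration, season: str = "annual"):
    """Map drinking-water δ18O (‰) to air temperature (°C).

    By default one annual-scale precipitation–temperature regression is
    applied to all seasons; separate warm/cold regressions apply when the
    calibration defines them.
    """
    a, b = cal.stage2_coefficients(season)
    out = a * np.asarray(d18Odw, dtype=float) + b
    return float(out) if out.ndim == 0 else out


def reconstruct_temperature(
    est: SeasonalEstimate,
    cal: TransferCalibration,
    *,
    measurement_sd: float = 0.0,
    n_mc: int = 10_000,
    seed: int | None = 0,
) -> TemperatureEstimate:
    """Full per-tooth reconstruction with compound error for each quantity.

    Requires both extremes (a partial series has no seasonal temperature
    pair).  MAT is computed from the mean-annual δ18O; because the chained
    maps are affine this equals the mean of the two seasonal temperatures.
    """
    if est.summer_peak is None or est.winter_trough is None:
        raise ValueError(f"tooth {est.tooth_id}: both extremes required for temperatures")
    t_warm = water_to_temperature(enamel_to_water(est.summer_peak, cal), cal, "warm_extreme")
    t_cold = water_to_temperature(enamel_to_water(est.winter_trough, cal), cal, "cold_extreme")
    t_mat = water_to_temperature(enamel_to_water(est.mean_annual, cal), cal, "annual")
    errs = [
        compound_error_mc(v, measurement_sd, cal, season=s, n_mc=n_mc, seed=seed)
        for v, s in (
            (est.summer_peak, "warm_extreme"),
            (est.winter_trough, "cold_extreme"),
            (est.mean_annual, "annual"),
        )
    ]
    return TemperatureEstimate(
        label=est.tooth_id,
        T_warmest_month=t_warm,
        T_coldest_month=t_cold,
        MAT=t_mat,
        err_warm=errs[0],
        err_cold=errs[1],
        err_mat=errs[2],
        n_mc=n_mc,
        seed=seed,
    )


def compound_error_mc(
    d18O_extreme: float,
    measurement_sd: float,
    cal: TransferCalibration,
    *,
    season: str = "annual",
    n_mc: int = 10_000,
    seed: int | None = 0,
    coverage: str = "sd",
) -> float:
    """Monte-Carlo compound error (°C half-width) of one reconstructed value.

    Each draw perturbs the input δ18O by ``measurement_sd``, draws the four
    calibration coefficients from their standard errors (jointly normal with
    the stated slope–intercept covariance) and adds each stage's residual
    scatter.  ``coverage="sd"`` returns the MC standard deviation (the
    default error-bar half-width); ``coverage="ci95"`` returns half the
    central 95% interval.  Deterministic for a fixed seed.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable error estimate")
    if measurement_sd < 0:
        raise ValueError("measurement_sd must be >= 0")
    rng = np.random.default_rng(seed)
    a2, b2 = cal.stage2_coefficients(season)

    dp = d18O_extreme + measurement_sd * rng.standard_normal(n_mc)

    def draw_pair(a, b, se_a, se_b, cov):
        # explicit bivariate-normal factorization; tolerates zero variances
        if abs(cov) > se_a * se_b:
            raise ValueError("slope-intercept covariance exceeds its Cauchy-Schwarz bound")
        z1 = rng.standard_normal(n_mc)
        z2 = rng.standard_normal(n_mc)
        a_s = a + se_a * z1
        if se_a > 0:
            resid_var = max(se_b**2 - (cov / se_a) ** 2, 0.0)
            b_s = b + (cov / se_a) * z1 + np.sqrt(resid_var) * z2
        else:
            b_s = b + se_b * z2
        return a_s, b_s

    a1s, b1s = draw_pair(cal.a1, cal.b1, cal.se_a1, cal.se_b1, cal.cov1)
    a2s, b2s = draw_pair(a2, b2, cal.se_a2, cal.se_b2, cal.cov2)

    dw = a1s * dp + b1s
    if cal.resid_se1 > 0:
        dw = dw + cal.resid_se1 * rng.standard_normal(n_mc)
    t = a2s * dw + b2s
    if cal.resid_se2 > 0:
        t = t + cal.resid_se2 * rng.standard_normal(n_mc)

    if coverage == "sd":
        return float(np.std(t, ddof=1))
    if coverage == "ci95":
        lo, hi = np.percentile(t, [2.5, 97.5])
        return float((hi - lo) / 2.0)
    raise ValueError(f"unknown coverage {coverage!r}")
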
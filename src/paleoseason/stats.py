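"""Inter-layer statistics on seasonal δ18O estimates and collagen values.

Covers the comparison surface of the seasonal analysis: per-layer group
summaries, one-way fixed-effects ANOVA with a Levene equality-of-variances
check and a qqnorm-style normality diagnostic, Tukey HSD pairwise
comparisons (Tukey–Kramer for unbalanced groups), Cohen's d effect sizes,
and the Pearson correlation between layer winter δ18O and collagen δ13C.

Hypothesis tests are delegated to scipy.stats; Cohen's d is computed here
(pooled-sd, (n−1) weights, no small-sample correction) with the contrast
order earlier-layer minus later-layer so that a rise in winter δ18O from an
older to a younger layer prints as a negative d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seasonal import SeasonalEstimate

__all__ = [
    "LayerStats",
    "STRATIGRAPHIC_ORDER",
    "group_summary",
    "anova_oneway",
    "levene_test",
    "tukey_hsd",
    "cohens_d",
    "season_collagen_correlation",
    "normality_check",
    "layer_report",
]

#: default bottom-up stratigraphic ordering (older first)
STRATIGRAPHIC_ORDER = ("1", "2", "3", "4", "5A", "5B")

_SEASON_FIELD = {
    "summer": "summer_peak",
    "winter": "winter_trough",
    "mean_annual": "mean_annual",
}


def _season_values(estimates: list[SeasonalEstimate], season: str) -> dict[str, np.ndarray]:
    """Per-layer arrays of the requested seasonal quantity, ordered stratigraphically."""
    if season not in _SEASON_FIELD:
        raise ValueError(f"unknown season {season!r}")
    field = _SEASON_FIELD[season]
    by_layer: dict[str, list[float]] = {}
    for est in estimates:
        v = getattr(est, field)
        if v is not None:
            by_layer.setdefault(est.layer_id, []).append(float(v))
    order = [l for l in STRATIGRAPHIC_ORDER if l in by_layer]
    order += [l for l in sorted(by_layer) if l not in order]
    return {l: np.asarray(by_layer[l]) for l in order}


def group_summary(estimates: list[SeasonalEstimate], season: str) -> pd.DataFrame:
    """Per-layer n / mean / sd / min / max of one seasonal quantity.

    Partial-series teeth contribute only to seasons they cover.  Layers are
    ordered stratigraphically (2, 5A, 5B, ...).
    """
    groups = _season_values(estimates, season)
    if not groups:
        raise ValueError(f"no estimate carries a {season!r} value")
    rows = []
    for layer, vals in groups.items():
        rows.append(
            {
                "layer_id": layer,
                "season": season,
                "n": vals.size,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows)


def _check_groups(groups: dict[str, np.ndarray]) -> None:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")


def anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA; returns (F, p)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    _check_groups(groups)
    res = sps.f_oneway(*groups.values())
    return float(res.statistic), float(res.pvalue)


def levene_test(groups: dict[str, np.ndarray], center: str = "mean") -> float:
    """Levene equality-of-variances p (center='mean' by default, or 'median')."""
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    _check_groups(groups)
    return float(sps.levene(*groups.values(), center=center).pvalue)


def tukey_hsd(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD adjusted p for every layer pair (Tukey–Kramer when unbalanced)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    _check_groups(groups)
    names = list(groups)
    res = sps.tukey_hsd(*groups.values())
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(groups[names[i]].mean() - groups[names[j]].mean()),
                    "p_adj": float(np.clip(res.pvalue[i, j], 0.0, 1.0)),
                }
            )
    return pd.DataFrame(rows)


def cohens_d(group_a, group_b) -> float:
    """Cohen's d = (mean_a − mean_b) / pooled sd, pooled with (n−1) weights.

    The first-listed group is conventionally the stratigraphically earlier
    (older) layer, so the sign reads as the direction of change through time.
    No small-sample (Hedges) correction is applied.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("pooled sd is zero: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


def season_collagen_correlation(
    estimates: list[SeasonalEstimate],
    collagen: pd.DataFrame,
    *,
    season: str = "winter",
    pairing: str = "per_specimen",
) -> dict:
    """Pearson correlation between layer seasonal δ18O means and collagen δ13C.

    Each collagen specimen is paired with its layer's mean seasonal δ18O.
    ``pairing="per_specimen"`` keeps one pair per collagen specimen (n ≈
    number of specimens in layers with seasonal data);
    ``pairing="per_layer"`` collapses to one pair per layer.  Returns a dict
    with r, R² (= r²), two-sided p and n.
    """
    groups = _season_values(estimates, season)
    layer_means = {l: float(v.mean()) for l, v in groups.items()}
    df = collagen[["layer_id", "d13C"]].copy()
    df["layer_id"] = df["layer_id"].astype(str)
    df = df[df["layer_id"].isin(layer_means)]
    if pairing == "per_layer":
        df = df.groupby("layer_id", as_index=False)["d13C"].mean()
    elif pairing != "per_specimen":
        raise ValueError(f"unknown pairing {pairing!r}")
    x = df["layer_id"].map(layer_means).to_numpy(dtype=float)
    y = df["d13C"].to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = sps.pearsonr(x, y)
    return {"r": float(r), "R2": float(r**2), "p": float(p), "n": int(x.size)}


def normality_check(values) -> dict:
    """QQ-style normality diagnostic plus a Shapiro–Wilk p.

    Returns ``{"qq": DataFrame(theoretical, sample), "shapiro_p": float}``.
    Advisory only: it never gates the pipeline.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need >= 3 values")
    (theo, ordered), _ = sps.probplot(v, dist="norm")
    shapiro_p = float(sps.shapiro(v).pvalue)
    return {
        "qq": pd.DataFrame({"theoretical": theo, "sample": ordered}),
        "shapiro_p": shapiro_p,
    }


@dataclass
class LayerStats:
    """Bundle of all inter-layer statistics for one seasonal quantity."""

    season: str
    summary: pd.DataFrame
    anova_F: float
    anova_p: float
    levene_p: float
    tukey: pd.DataFrame
    effect_sizes: pd.DataFrame
    shapiro_p: float


def layer_report(estimates: list[SeasonalEstimate], season: str = "winter") -> LayerStats:
    """Run the full inter-layer comparison for one seasonal quantity."""
    groups = _season_values(estimates, season)
    summary = group_summary(estimates, season)
    F, p = anova_oneway(groups)
    lev = levene_test(groups)
    tk = tukey_hsd(groups)
    names = list(groups)
    eff = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            eff.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "cohens_d": cohens_d(groups[names[i]], groups[names[j]]),
                }
            )
    pooled = np.concatenate(list(groups.values()))
    shapiro_p = normality_check(pooled)["shapiro_p"] if pooled.size >= 3 else np.nan
    return LayerStats(
        season=season,
        summary=summary,
        anova_F=F,
        anova_p=p,
        levene_p=lev,
        tukey=tk,
        effect_sizes=pd.DataFrame(eff),
        shapiro_p=shapiro_p,
    )
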
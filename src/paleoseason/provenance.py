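"""Strontium locality screening and collagen quality/environment summaries.

87Sr/86Sr in enamel reflects the bedrock where an animal fed while the
enamel formed.  Comparing sequential enamel values against a local
bioavailable baseline (modern plants near the site) screens for non-local
or migratory individuals, which would decouple enamel δ18O from local
precipitation and invalidate it as a site-level climate proxy.  Bone
collagen δ13C/δ15N summarize the plant biome and feeding niche per layer;
standard collagen-integrity criteria (atomic C:N within 2.9–3.6) gate
which specimens count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CollagenSample, SrMeasurement

__all__ = [
    "SrBaseline",
    "sr_screen",
    "sr_seasonal_homogeneity",
    "collagen_qc",
    "collagen_layer_trends",
]

_COLLAGEN_LAYER_ORDER = ("1", "2", "3", "4", "5A", "5B")


@dataclass(frozen=True)
class SrBaseline:
    """Local bioavailable 87Sr/86Sr baseline (e.g. modern plants near the site)."""

    mean: float
    sd: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("baseline sd must be >= 0")


def sr_screen(
    measurements: list[SrMeasurement],
    baseline: SrBaseline,
    k_sd: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Classify each tooth local/nonlocal against the bioavailable baseline.

    A tooth is ``local`` when *all* of its measurements fall within
    baseline mean ± k_sd·sd (default 3 sd).  Returns a per-tooth table and
    an overall summary (mean/sd/min/max across all measurements).
    """
    if not measurements:
        raise ValueError("need >= 1 Sr measurement")
    ratios = np.asarray([m.sr_ratio for m in measurements], dtype=float)
    if baseline.sd == 0 and np.any(ratios != baseline.mean):
        raise ValueError("degenerate baseline: sd = 0 but measurements deviate")
    lo = baseline.mean - k_sd * baseline.sd
    hi = baseline.mean + k_sd * baseline.sd
    rows = []
    for tooth_id in sorted({m.tooth_id for m in measurements}):
        vals = np.asarray([m.sr_ratio for m in measurements if m.tooth_id == tooth_id])
        local = bool(np.all((vals >= lo) & (vals <= hi)))
        rows.append(
            {
                "tooth_id": tooth_id,
                "n": vals.size,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "status": "local" if local else "nonlocal",
            }
        )
    summary = {
        "mean": float(ratios.mean()),
        "sd": float(ratios.std(ddof=1)) if ratios.size > 1 else np.nan,
        "min": float(ratios.min()),
        "max": float(ratios.max()),
        "n": int(ratios.size),
        "baseline_mean": baseline.mean,
        "baseline_sd": baseline.sd,
        "k_sd": k_sd,
    }
    return pd.DataFrame(rows), summary


def sr_seasonal_homogeneity(
    measurements: list[SrMeasurement],
    analytical_sd: float = 0.0001,
    k: float = 3.0,
) -> pd.DataFrame:
    """Intra-tooth Sr range per tooth; flags seasonal heterogeneity.

    A tooth with sequential measurements spanning more than ``k·analytical_sd``
    is flagged (possible seasonal range shift / migration).  Teeth with a
    single measurement are marked not assessable.
    """
    rows = []
    for tooth_id in sorted({m.tooth_id for m in measurements}):
        vals = np.asarray([m.sr_ratio for m in measurements if m.tooth_id == tooth_id])
        if vals.size < 2:
            rows.append(
                {"tooth_id": tooth_id, "n": vals.size, "range": np.nan, "flag": "not_assessable"}
            )
            continue
        rng = float(np.ptp(vals))
        rows.append(
            {
                "tooth_id": tooth_id,
                "n": vals.size,
                "range": rng,
                "flag": "heterogeneous" if rng > k * analytical_sd else "homogeneous",
            }
        )
    return pd.DataFrame(rows)


def collagen_qc(
    samples: list[CollagenSample],
    cn_low: float = 2.9,
    cn_high: float = 3.6,
) -> tuple[list[CollagenSample], pd.DataFrame]:
    """Screen collagen by atomic C:N integrity window (default 2.9–3.6).

    Returns (passed samples, rejection log).  Samples with no C:N pass with
    a warning entry in the log (reason 'missing_CN', rejected=False).
    """
    passed: list[CollagenSample] = []
    log_rows = []
    for s in samples:
        if s.CN_ratio is None:
            passed.append(s)
            log_rows.append(
                {"specimen_id": s.specimen_id, "rejected": False, "reason": "missing_CN"}
            )
        elif cn_low <= s.CN_ratio <= cn_high:
            passed.append(s)
        else:
            side = "below" if s.CN_ratio < cn_low else "above"
            log_rows.append(
                {
                    "specimen_id": s.specimen_id,
                    "rejected": True,
                    "reason": f"CN_ratio {s.CN_ratio} {side} window [{cn_low}, {cn_high}]",
                }
            )
    return passed, pd.DataFrame(log_rows, columns=["specimen_id", "rejected", "reason"])


def collagen_layer_trends(samples: list[CollagenSample]) -> pd.DataFrame:
    """Per-layer δ13C and δ15N mean/sd/n, layers ordered stratigraphically.

    Layers with a single specimen report sd as missing (NaN), not zero.
    """
    if not samples:
        raise ValueError("need >= 1 collagen sample")
    df = pd.DataFrame(
        [{"layer_id": s.layer_id, "d13C": s.d13C, "d15N": s.d15N} for s in samples]
    )
    order = [l for l in _COLLAGEN_LAYER_ORDER if l in set(df["layer_id"])]
    order += [l for l in sorted(set(df["layer_id"])) if l not in order]
    rows = []
    for layer in order:
        sub = df[df["layer_id"] == layer]
        row = {"layer_id": layer, "n": len(sub)}
        for col in ("d13C", "d15N"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sd"] = float(sub[col].std(ddof=1)) if len(sub) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
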
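"""Domain records, CSV readers/writers and scale normalization.

Tables are plain UTF-8 CSV with a header row. One documented schema exists
per table kind (``enamel_o``, ``sr``, ``collagen``); unknown extra columns
are carried through untouched so that richer deposited tables load without
modification.

Position convention
-------------------
``position_mm`` is the distance along the tooth growth axis measured from
the enamel--root junction (ERJ), increasing toward the occlusal surface;
larger positions correspond to earlier-formed enamel.  Tables measured from
the occlusal surface can be loaded with ``flip_positions=True``, which maps
positions to ``max(position) - position`` per tooth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "IsotopeSample",
    "ToothSeries",
    "SrMeasurement",
    "CollagenSample",
    "NormalizationStandards",
    "read_samples",
    "write_enamel_table",
    "write_sr_table",
    "write_collagen_table",
    "series_to_frame",
    "two_point_normalize",
]


class FormatError(ValueError):
    """A table is missing required columns or is otherwise unreadable."""


# required columns per table kind; everything else is passed through
_SCHEMAS = {
    "enamel_o": ("tooth_id", "layer_id", "position_mm", "d18O"),
    "sr": ("tooth_id", "sr_ratio"),
    "collagen": ("specimen_id", "layer_id", "d13C", "d15N"),
}


@dataclass(frozen=True)
class IsotopeSample:
    """One drilled enamel strip: position along the growth axis and its δ18O.

    ``d18O`` is the phosphate δ18O in permil VSMOW; ``replicate_sd`` is the
    analytical standard deviation of replicate measurements when reported.
    """

    tooth_id: str
    layer_id: str
    position_mm: float
    d18O: float
    replicate_sd: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.d18O):
            raise ValueError(f"d18O must be finite, got {self.d18O!r}")
        if self.position_mm < 0:
            raise ValueError(f"position_mm must be >= 0, got {self.position_mm}")
        if self.replicate_sd is not None and not (self.replicate_sd >= 0):
            raise ValueError(f"replicate_sd must be >= 0, got {self.replicate_sd}")


@dataclass
class ToothSeries:
    """Ordered intra-tooth δ18O samples for one tooth: the unit of seasonal inference."""

    tooth_id: str
    layer_id: str
    samples: list[IsotopeSample]
    taxon: str = ""
    tooth_position: str = ""

    def __post_init__(self) -> None:
        if len(self.samples) < 3:
            raise ValueError(
                f"tooth {self.tooth_id}: a series needs >= 3 samples, got {len(self.samples)}"
            )
        pos = np.asarray([s.position_mm for s in self.samples], dtype=float)
        if not np.all(np.diff(pos) > 0):
            raise ValueError(f"tooth {self.tooth_id}: positions must be strictly increasing")
        for s in self.samples:
            if s.tooth_id != self.tooth_id or s.layer_id != self.layer_id:
                raise ValueError(
                    f"tooth {self.tooth_id}: sample {s.tooth_id}/{s.layer_id} does not belong"
                )

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.position_mm for s in self.samples], dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.asarray([s.d18O for s in self.samples], dtype=float)

    @property
    def span_mm(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class SrMeasurement:
    """A single 87Sr/86Sr measurement on enamel (optionally positioned)."""

    tooth_id: str
    sr_ratio: float
    position_mm: float | None = None

    def __post_init__(self) -> None:
        if not (0.70 < self.sr_ratio < 0.74):
            raise ValueError(
                f"sr_ratio {self.sr_ratio} outside plausibility window (0.70, 0.74)"
            )


@dataclass(frozen=True)
class CollagenSample:
    """Bone-collagen δ13C (VPDB) / δ15N (AIR) with elemental QC fields."""

    specimen_id: str
    layer_id: str
    d13C: float
    d15N: float
    pct_C: float | None = None
    pct_N: float | None = None
    CN_ratio: float | None = None
    collagen_yield_pct: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d13C) and np.isfinite(self.d15N)):
            raise ValueError(f"{self.specimen_id}: d13C/d15N must be finite")
        if self.CN_ratio is not None and not (self.CN_ratio > 0):
            raise ValueError(f"{self.specimen_id}: CN_ratio must be > 0")


@dataclass(frozen=True)
class NormalizationStandards:
    """Two matrix-matched standards anchoring the raw scale to VSMOW."""

    accepted: tuple[float, float]
    measured: tuple[float, float]

    def __post_init__(self) -> None:
        if self.measured[0] == self.measured[1]:
            raise ValueError("measured standard values must differ")
        if self.accepted[0] == self.accepted[1]:
            raise ValueError("accepted standard values must differ")

    @property
    def slope(self) -> float:
        return (self.accepted[1] - self.accepted[0]) / (self.measured[1] - self.measured[0])

    @property
    def intercept(self) -> float:
        return self.accepted[0] - self.slope * self.measured[0]


def two_point_normalize(raw, standards: NormalizationStandards):
    """Two-point scale-normalize raw delta values to the target (VSMOW) scale.

    Applies the unique affine map sending the two measured standard values to
    their accepted values.  Accepts scalars or arrays.
    """
    raw = np.asarray(raw, dtype=float)
    out = standards.slope * raw + standards.intercept
    return float(out) if out.ndim == 0 else out


def _numeric(df: pd.DataFrame, col: str) -> pd.Series:
    return pd.to_numeric(df[col], errors="coerce")


def _require_columns(df: pd.DataFrame, kind: str, path) -> None:
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for kind={kind!r}")


def read_samples(
    path,
    kind: str,
    *,
    flip_positions: bool = False,
    on_bad_rows: str = "warn",
):
    """Read a typed sample table from CSV.

    Parameters
    ----------
    path : str or path-like
        CSV file with the documented header for ``kind``.
    kind : {'enamel_o', 'sr', 'collagen'}
        Which schema/record type to load.
    flip_positions : bool
        Re-express positions as distance from the enamel--root junction when
        the table was measured from the occlusal surface (enamel tables only).
    on_bad_rows : {'warn', 'raise'}
        Rows violating record invariants are rejected with a row-level
        diagnostic (0-based row index) and either warned about or fatal.

    Returns
    -------
    list of ToothSeries (kind='enamel_o'), list of SrMeasurement (kind='sr'),
    or list of CollagenSample (kind='collagen').
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_SCHEMAS)}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    _require_columns(df, kind, path)

    problems: list[str] = []

    def reject(idx, msg):
        problems.append(f"row {idx}: {msg}")

    if kind == "enamel_o":
        records = _read_enamel(df, reject, flip_positions)
    elif kind == "sr":
        records = _read_sr(df, reject)
    else:
        records = _read_collagen(df, reject)

    if problems:
        diag = f"{path}: rejected {len(problems)} row(s): " + "; ".join(problems)
        if on_bad_rows == "raise":
            raise FormatError(diag)
        warnings.warn(diag, stacklevel=2)
    return records


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    try:
        x = float(v)
    except (TypeError, ValueError):
        return None
    return x if np.isfinite(x) else None


def _read_enamel(df, reject, flip_positions) -> list[ToothSeries]:
    rows = []
    for idx, row in df.iterrows():
        pos = _opt_float(row["position_mm"])
        val = _opt_float(row["d18O"])
        if pos is None:
            reject(idx, "non-numeric or missing position_mm")
            continue
        if val is None:
            reject(idx, "non-numeric or missing d18O")
            continue
        try:
            rows.append(
                (
                    str(row["tooth_id"]),
                    str(row["layer_id"]),
                    IsotopeSample(
                        tooth_id=str(row["tooth_id"]),
                        layer_id=str(row["layer_id"]),
                        position_mm=pos,
                        d18O=val,
                        replicate_sd=_opt_float(row.get("replicate_sd")),
                    ),
                    str(row.get("taxon", "") or ""),
                    str(row.get("tooth_position", "") or ""),
                )
            )
        except ValueError as exc:
            reject(idx, str(exc))

    series: list[ToothSeries] = []
    by_tooth: dict[str, list] = {}
    for tooth_id, layer_id, sample, taxon, tpos in rows:
        by_tooth.setdefault(tooth_id, []).append((layer_id, sample, taxon, tpos))
    for tooth_id, entries in by_tooth.items():
        layer_id = entries[0][0]
        taxon = next((e[2] for e in entries if e[2]), "")
        tpos = next((e[3] for e in entries if e[3]), "")
        samples = sorted((e[1] for e in entries), key=lambda s: s.position_mm)
        samples = _average_duplicates(tooth_id, samples)
        if flip_positions:
            top = max(s.position_mm for s in samples)
            samples = sorted(
                (
                    IsotopeSample(s.tooth_id, s.layer_id, top - s.position_mm, s.d18O, s.replicate_sd)
                    for s in samples
                ),
                key=lambda s: s.position_mm,
            )
        try:
            series.append(
                ToothSeries(
                    tooth_id=tooth_id,
                    layer_id=layer_id,
                    samples=samples,
                    taxon=taxon,
                    tooth_position=tpos,
                )
            )
        except ValueError as exc:
            reject(f"tooth {tooth_id}", str(exc))
    series.sort(key=lambda s: s.tooth_id)
    return series


def _average_duplicates(tooth_id: str, samples: list[IsotopeSample]) -> list[IsotopeSample]:
    """Average replicate drillings of the same strip (same position)."""
    out: list[IsotopeSample] = []
    i = 0
    had_dups = False
    while i < len(samples):
        group = [samples[i]]
        while i + 1 < len(samples) and samples[i + 1].position_mm == samples[i].position_mm:
            group.append(samples[i + 1])
            i += 1
        if len(group) > 1:
            had_dups = True
            sds = [g.replicate_sd for g in group if g.replicate_sd is not None]
            out.append(
                IsotopeSample(
                    tooth_id=group[0].tooth_id,
                    layer_id=group[0].layer_id,
                    position_mm=group[0].position_mm,
                    d18O=float(np.mean([g.d18O for g in group])),
                    replicate_sd=float(np.mean(sds)) if sds else None,
                )
            )
        else:
            out.append(group[0])
        i += 1
    if had_dups:
        warnings.warn(
            f"tooth {tooth_id}: duplicate (tooth_id, position_mm) rows averaged",
            stacklevel=3,
        )
    return out


def _read_sr(df, reject) -> list[SrMeasurement]:
    out = []
    for idx, row in df.iterrows():
        ratio = _opt_float(row["sr_ratio"])
        if ratio is None:
            reject(idx, "non-numeric or missing sr_ratio")
            continue
        try:
            out.append(
                SrMeasurement(
                    tooth_id=str(row["tooth_id"]),
                    sr_ratio=ratio,
                    position_mm=_opt_float(row.get("position_mm")),
                )
            )
        except ValueError as exc:
            reject(idx, str(exc))
    return out


def _read_collagen(df, reject) -> list[CollagenSample]:
    out = []
    for idx, row in df.iterrows():
        c = _opt_float(row["d13C"])
        n = _opt_float(row["d15N"])
        if c is None or n is None:
            reject(idx, "non-numeric or missing d13C/d15N")
            continue
        try:
            out.append(
                CollagenSample(
                    specimen_id=str(row["specimen_id"]),
                    layer_id=str(row["layer_id"]),
                    d13C=c,
                    d15N=n,
                    pct_C=_opt_float(row.get("pct_C")),
                    pct_N=_opt_float(row.get("pct_N")),
                    CN_ratio=_opt_float(row.get("CN_ratio")),
                    collagen_yield_pct=_opt_float(row.get("collagen_yield_pct")),
                )
            )
        except ValueError as exc:
            reject(idx, str(exc))
    return out


def series_to_frame(series: list[ToothSeries]) -> pd.DataFrame:
    """Flatten ToothSeries records back into the enamel table schema."""
    rows = []
    for ts in series:
        for s in ts.samples:
            rows.append(
                {
                    "tooth_id": ts.tooth_id,
                    "layer_id": ts.layer_id,
                    "position_mm": s.position_mm,
                    "d18O": s.d18O,
                    "replicate_sd": s.replicate_sd,
                    "taxon": ts.taxon,
                    "tooth_position": ts.tooth_position,
                }
            )
    return pd.DataFrame(rows)


def write_enamel_table(series: list[ToothSeries], path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def write_sr_table(measurements: list[SrMeasurement], path) -> None:
    pd.DataFrame(
        [
            {"tooth_id": m.tooth_id, "sr_ratio": m.sr_ratio, "position_mm": m.position_mm}
            for m in measurements
        ]
    ).to_csv(path, index=False)


def write_collagen_table(samples: list[CollagenSample], path) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": s.specimen_id,
                "layer_id": s.layer_id,
                "d13C": s.d13C,
                "d15N": s.d15N,
                "pct_C": s.pct_C,
                "pct_N": s.pct_N,
                "CN_ratio": s.CN_ratio,
                "collagen_yield_pct": s.collagen_yield_pct,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)
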
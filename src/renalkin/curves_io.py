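"""Time–attenuation curves: data model, readers/writers, preprocessing.

A time–attenuation curve (TAC) is the CT attenuation (HU) of a region of
interest sampled over time after contrast injection.  Baseline-subtracted
attenuation is linear in iodine concentration, so these curves stand in for
tracer concentration throughout the package.  Three ROIs per kidney are
required: abdominal aorta (arterial input), renal parenchyma (the fitted
signal) and renal papilla (the tubular outflow forcing term).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TimeAttenuationCurve",
    "KidneyDataset",
    "CurveFormatError",
    "CurveDataError",
    "read_curves",
    "write_curves",
    "subtract_baseline",
    "resample_uniform",
    "truncate",
    "load_config",
    "DEFAULT_CONFIG",
]

# study constants: hematocrit for plasma correction, blood/tissue water
# partition coefficient, interpolation step and fitting window (seconds)
DEFAULT_CONFIG = {
    "hematocrit": 0.45,
    "sigma": 0.9,
    "dt": 0.5,
    "fit_window": [0.0, 120.0],
    "decomposition_tmax": 35.0,
    "injection_time": 0.0,
}


class CurveFormatError(ValueError):
    """Raised when an input file cannot be parsed into curves."""


class CurveDataError(ValueError):
    """Raised when parsed curves violate the data model invariants."""


@dataclass(frozen=True)
class TimeAttenuationCurve:
    """One ROI signal: attenuation above pre-contrast baseline vs time.

    Parameters
    ----------
    times
        Sample times in seconds since the first acquisition, strictly
        increasing, ``times[0] >= 0``.
    values
        Baseline-subtracted attenuation in HU (proxy for iodine
        concentration).  May be negative where noise dips below baseline.
    label
        ROI identifier, conventionally ``aorta``, ``parenchyma`` or
        ``papilla``.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise CurveDataError(
                f"curve {self.label!r}: times and values must be equal-length 1-D arrays"
            )
        if t.size < 4:
            raise CurveDataError(
                f"curve {self.label!r}: at least 4 samples required, got {t.size}"
            )
        if t[0] < 0:
            raise CurveDataError(f"curve {self.label!r}: times must start at >= 0 s")
        bad = np.where(np.diff(t) <= 0)[0]
        if bad.size:
            raise CurveDataError(
                f"curve {self.label!r}: times not strictly increasing at rows {bad.tolist()}"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def interp(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the curve at times ``t`` (no extrapolation)."""
        t = np.asarray(t, dtype=float)
        if t.size and (t.min() < self.times[0] - 1e-12 or t.max() > self.times[-1] + 1e-12):
            raise CurveDataError(
                f"curve {self.label!r}: requested times outside the sampled range "
                f"[{self.times[0]:g}, {self.times[-1]:g}] s; extrapolation is refused"
            )
        return np.interp(t, self.times, self.values)


@dataclass(frozen=True)
class KidneyDataset:
    """The three TACs plus scalar metadata needed to fit one kidney."""

    aorta: TimeAttenuationCurve
    parenchyma: TimeAttenuationCurve
    papilla: TimeAttenuationCurve
    volume: float  # mL, from the 3-D volumetric scan
    hematocrit: float = 0.45
    sigma: float = 0.9  # blood/tissue water partition coefficient, mL/g
    kidney_id: str = ""
    group_label: str = ""  # EH | stenotic | contralateral (data, not inference)

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise CurveDataError(f"kidney {self.kidney_id!r}: volume must be > 0 mL")
        if not 0 <= self.hematocrit < 1:
            raise CurveDataError(f"kidney {self.kidney_id!r}: hematocrit must be in [0, 1)")
        if self.sigma <= 0:
            raise CurveDataError(f"kidney {self.kidney_id!r}: sigma must be > 0")

    def map_curves(self, fn) -> "KidneyDataset":
        """Return a copy with ``fn`` applied to each of the three curves."""
        return replace(
            self, aorta=fn(self.aorta), parenchyma=fn(self.parenchyma), papilla=fn(self.papilla)
        )


# ---------------------------------------------------------------------------
# preprocessing

def subtract_baseline(curve: TimeAttenuationCurve, n_baseline: int) -> TimeAttenuationCurve:
    """Subtract the mean of the first ``n_baseline`` (pre-contrast) samples.

    The signal increase over baseline represents iodine concentration; this
    is the first preprocessing step applied to every raw curve.
    """
    if not 1 <= n_baseline < len(curve):
        raise ValueError(
            f"n_baseline must be in [1, {len(curve) - 1}], got {n_baseline}"
        )
    baseline = float(np.mean(curve.values[:n_baseline]))
    return replace(curve, values=curve.values - baseline)


def resample_uniform(
    curve: TimeAttenuationCurve, dt: float, t_max: float | None = None
) -> TimeAttenuationCurve:
    """Linearly interpolate onto the uniform grid 0, dt, 2·dt, … <= t_max.

    Never extrapolates: ``t_max`` beyond the last sample raises.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_max is None:
        t_max = curve.duration
    if t_max > curve.duration + 1e-9:
        raise CurveDataError(
            f"curve {curve.label!r}: t_max={t_max:g} s exceeds data extent "
            f"{curve.duration:g} s; extrapolation is refused"
        )
    n = int(np.floor(t_max / dt + 1e-9)) + 1
    grid = np.arange(n) * dt
    if curve.times[0] > 1e-12:
        # grid starts at 0; hold the first sample flat back to t=0 only if the
        # first acquisition is within one step of zero, otherwise refuse
        if curve.times[0] > dt + 1e-9:
            raise CurveDataError(
                f"curve {curve.label!r}: first sample at {curve.times[0]:g} s, "
                "cannot resample from t=0 without extrapolating"
            )
        values = np.interp(grid, curve.times, curve.values, left=curve.values[0])
    else:
        values = np.interp(grid, curve.times, curve.values)
    return TimeAttenuationCurve(grid, values, curve.label)


def truncate(curve: TimeAttenuationCurve, t_max: float) -> TimeAttenuationCurve:
    """Retain samples with time <= ``t_max`` (the fitting window cut)."""
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    keep = curve.times <= t_max + 1e-9
    if not keep.any():
        raise CurveDataError(f"curve {curve.label!r}: no samples at or before {t_max:g} s")
    return TimeAttenuationCurve(curve.times[keep], curve.values[keep], curve.label)


# ---------------------------------------------------------------------------
# file I/O
#
# Two dialects ship with the package:
#   "csv"  — RFC 4180 with header time_s, aorta_hu, parenchyma_hu, papilla_hu
#            (one kidney per file; kidney_id/volume supplied separately or in
#            sidecar columns volume_ml, kidney_id, group)
#   "xlsx" — one sheet per kidney, same column layout; sheet name is the
#            kidney id.  A custom mapping may be passed for other layouts.

CSV_COLUMNS = ("time_s", "aorta_hu", "parenchyma_hu", "papilla_hu")


def _dataset_from_table(
    df: pd.DataFrame,
    kidney_id: str,
    volume: float,
    hematocrit: float,
    sigma: float,
    group_label: str = "",
) -> KidneyDataset:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise CurveFormatError(f"table {kidney_id!r}: missing columns {missing}")
    curves = {}
    for col, label in zip(CSV_COLUMNS[1:], ("aorta", "parenchyma", "papilla")):
        sub = df[["time_s", col]].dropna()  # missing cells dropped pairwise
        if len(sub) < 4:
            raise CurveDataError(
                f"kidney {kidney_id!r}: curve {label!r} has only {len(sub)} usable samples"
            )
        curves[label] = TimeAttenuationCurve(
            sub["time_s"].to_numpy(float), sub[col].to_numpy(float), label
        )
    return KidneyDataset(
        aorta=curves["aorta"],
        parenchyma=curves["parenchyma"],
        papilla=curves["papilla"],
        volume=volume,
        hematocrit=hematocrit,
        sigma=sigma,
        kidney_id=kidney_id,
        group_label=group_label,
    )


def read_curves(
    path: str | Path,
    dialect: str = "csv",
    volume: float | dict[str, float] | None = None,
    hematocrit: float = 0.45,
    sigma: float = 0.9,
    group_labels: dict[str, str] | None = None,
) -> list[KidneyDataset]:
    """Read one or more kidney datasets from a CSV or XLSX table.

    Parameters
    ----------
    path
        Input file.  CSV holds one kidney; XLSX holds one sheet per kidney.
    dialect
        ``"csv"`` or ``"xlsx"``.
    volume
        Kidney volume in mL — a scalar (CSV, or applied to every sheet) or a
        ``{kidney_id: volume}`` mapping (XLSX).  A ``volume_ml`` column in
        the table takes precedence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    group_labels = group_labels or {}

    def resolve_volume(df: pd.DataFrame, kidney_id: str) -> float:
        if "volume_ml" in df.columns and df["volume_ml"].notna().any():
            return float(df["volume_ml"].dropna().iloc[0])
        if isinstance(volume, dict):
            if kidney_id not in volume:
                raise CurveDataError(f"no volume provided for kidney {kidney_id!r}")
            return float(volume[kidney_id])
        if volume is None:
            raise CurveDataError(
                f"kidney {kidney_id!r}: volume not in table and not provided"
            )
        return float(volume)

    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # noqa: BLE001 - surface as format error
            raise CurveFormatError(f"cannot parse {path}: {exc}") from exc
        kidney_id = path.stem
        return [
            _dataset_from_table(
                df, kidney_id, resolve_volume(df, kidney_id), hematocrit, sigma,
                group_labels.get(kidney_id, ""),
            )
        ]
    if dialect == "xlsx":
        try:
            sheets = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        except Exception as exc:  # noqa: BLE001
            raise CurveFormatError(f"cannot parse {path}: {exc}") from exc
        out = []
        for name, df in sheets.items():
            out.append(
                _dataset_from_table(
                    df, name, resolve_volume(df, name), hematocrit, sigma,
                    group_labels.get(name, ""),
                )
            )
        return out
    raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'xlsx'")


def write_curves(dataset: KidneyDataset, path: str | Path) -> None:
    """Write one kidney's three curves as the standard CSV schema.

    Curves sampled on different grids are written as a union grid with empty
    cells where a curve has no sample (read_curves drops them pairwise).
    """
    path = Path(path)
    grids = {
        "aorta_hu": dataset.aorta,
        "parenchyma_hu": dataset.parenchyma,
        "papilla_hu": dataset.papilla,
    }
    all_times = np.unique(np.concatenate([c.times for c in grids.values()]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(CSV_COLUMNS) + ["volume_ml"])
        for i, t in enumerate(all_times):
            row: list[object] = [repr(float(t))]
            for curve in grids.values():
                j = np.searchsorted(curve.times, t)
                if j < len(curve) and abs(curve.times[j] - t) < 1e-9:
                    row.append(repr(float(curve.values[j])))
                else:
                    row.append("")
            row.append(repr(float(dataset.volume)) if i == 0 else "")
            writer.writerow(row)


def load_config(path: str | Path | None = None) -> dict:
    """Load the YAML analysis config, filling defaults for missing keys."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise CurveFormatError(f"config {path} must be a YAML mapping")
        cfg.update(user)
    return cfg


def preprocess(
    dataset: KidneyDataset,
    dt: float = 0.5,
    t_max: float = 120.0,
    n_baseline: int | None = None,
) -> KidneyDataset:
    """Standard preprocessing: baseline subtraction (optional), resample to a
    uniform ``dt`` grid, truncate to the fitting window."""

    def one(curve: TimeAttenuationCurve) -> TimeAttenuationCurve:
        c = curve
        if n_baseline is not None:
            c = subtract_baseline(c, n_baseline)
        c = resample_uniform(c, dt, min(t_max, c.duration))
        return truncate(c, t_max)

    return dataset.map_curves(one)
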